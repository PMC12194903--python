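"""Atom-naming conventions.

Which atom is the headgroup phosphorus, which carbons form each acyl
chain, and what every atom weighs are properties of the topology that
produced a trajectory, not of this package.  They are therefore carried
as data (:class:`NamingConvention`), so united-atom and all-atom
namings can both be analysed by supplying the appropriate map.

The default convention is the one used by the synthetic-bilayer
generator: ``P``/``N`` headgroup atoms, sn-1 chain carbons ``C1A`` ..
``C16A``, sn-2 carbons ``C1B`` .. ``C16B`` (head-proximal to terminal),
and water oxygens ``OW``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

# united-atom masses, amu
_DEFAULT_MASSES: dict[str, float] = {
    "P": 30.974,
    "N": 14.007,
    "OW": 18.015,  # SPC-style united water bead carries the full molecule mass
}
_CH2_MASS = 14.027  # united CH2
_CH3_MASS = 15.035  # united CH3


@dataclass(frozen=True)
class NamingConvention:
    """Maps atom names to structural roles.

    Parameters
    ----------
    phosphorus_names, nitrogen_names, water_oxygen_names
        Atom names playing each role.
    chain_patterns
        One regex per acyl chain; the single capture group is the
        carbon position (1 = head-proximal).
    lipid_resnames
        Residue names treated as lipids; ``None`` means any residue
        containing a phosphorus-named atom.
    masses
        Atom name -> mass (amu).  Chain carbons not listed fall back to
        united CH2/CH3 masses (terminal carbon is CH3).
    """

    phosphorus_names: frozenset[str] = frozenset({"P", "P8"})
    nitrogen_names: frozenset[str] = frozenset({"N", "N4"})
    water_oxygen_names: frozenset[str] = frozenset({"OW"})
    chain_patterns: tuple[str, str] = (r"^C(\d+)A$", r"^C(\d+)B$")
    lipid_resnames: frozenset[str] | None = None
    masses: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MASSES))

    def mass_of(self, name: str, *, terminal: bool = False) -> float:
        if name in self.masses:
            return self.masses[name]
        if any(re.match(p, name) for p in self.chain_patterns):
            return _CH3_MASS if terminal else _CH2_MASS
        # fall back on the leading element letter
        for sym, m in (("C", 12.011), ("N", 14.007), ("O", 15.999),
                       ("P", 30.974), ("H", 1.008)):
            if name.startswith(sym):
                return m
        return 0.0

    def chain_position(self, name: str) -> tuple[int, int] | None:
        """Return (chain index, carbon position) or None."""
        for ci, pat in enumerate(self.chain_patterns):
            m = re.match(pat, name)
            if m:
                return ci, int(m.group(1))
        return None

    @classmethod
    def from_dict(cls, d: Mapping) -> "NamingConvention":
        kw = {}
        for key in ("phosphorus_names", "nitrogen_names", "water_oxygen_names"):
            if key in d:
                kw[key] = frozenset(d[key])
        if "chain_patterns" in d:
            pats: Sequence[str] = d["chain_patterns"]
            kw["chain_patterns"] = tuple(pats)
        if "lipid_resnames" in d and d["lipid_resnames"] is not None:
            kw["lipid_resnames"] = frozenset(d["lipid_resnames"])
        if "masses" in d:
            kw["masses"] = dict(d["masses"])
        return cls(**kw)


DEFAULT_CONVENTION = NamingConvention()
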