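"""Region schemes: named residue ranges driving every per-region operation.

The default scheme encodes calmodulin's architecture: two EF-hand lobes
joined by the central linker (residues 69-91), eight helices, and the four
calcium-coordinating EF loops. Two range conventions coexist on purpose:

* ``com_convention`` (5-68 / 69-91 / 92-147) defines the lobe centers of
  mass anchoring the interlobe torsion; the extended crystal structure
  lacks residues 1-4 and 148, so the anchors stay computable on it.
* ``charge_convention`` (5-68 / 69-91 / 92-148) defines the ranges over
  which side-chain formal charges are summed; with two bound Ca2+ per lobe
  this reproduces the canonical net charges -8 (N-lobe), -1 (linker),
  -6 (C-lobe).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySelectionError, UnknownRegionError
from .topology import BACKBONE_NAMES, ConformerSet

__all__ = ["RegionScheme", "default_scheme", "select_region"]

Range = tuple[int, int]


@dataclass
class RegionScheme:
    """Named inclusive residue-number ranges (PDB author numbering)."""

    regions: dict[str, Range]
    helices: dict[str, Range] = field(default_factory=dict)
    ef_loops: dict[str, tuple[int, ...]] = field(default_factory=dict)
    com_convention: dict[str, Range] = field(default_factory=dict)
    charge_convention: dict[str, Range] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in {**self.regions, **self.helices,
                               **self.com_convention, **self.charge_convention}.items():
            if hi < lo:
                raise ValueError(f"range for {name!r} is empty: {lo}-{hi}")
        for conv in (self.com_convention, self.charge_convention):
            seen: set[int] = set()
            for name, (lo, hi) in conv.items():
                rng = set(range(lo, hi + 1))
                if seen & rng:
                    raise ValueError(f"convention ranges overlap at {sorted(seen & rng)[:3]}")
                seen |= rng

    def lookup(self, region: str) -> Range:
        for table in (self.regions, self.com_convention, self.charge_convention, self.helices):
            if region in table:
                return table[region]
        raise UnknownRegionError(
            f"unknown region {region!r}; known: {sorted(set(self.regions) | set(self.helices))}"
        )

    def linker_ends(self) -> tuple[int, int]:
        lo, hi = self.lookup("linker")
        return lo, hi

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "regions": {k: list(v) for k, v in self.regions.items()},
            "helices": {k: list(v) for k, v in self.helices.items()},
            "ef_loops": {k: list(v) for k, v in self.ef_loops.items()},
            "com_convention": {k: list(v) for k, v in self.com_convention.items()},
            "charge_convention": {k: list(v) for k, v in self.charge_convention.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionScheme":
        return cls(
            regions={k: tuple(v) for k, v in d.get("regions", {}).items()},
            helices={k: tuple(v) for k, v in d.get("helices", {}).items()},
            ef_loops={k: tuple(v) for k, v in d.get("ef_loops", {}).items()},
            com_convention={k: tuple(v) for k, v in d.get("com_convention", {}).items()},
            charge_convention={k: tuple(v) for k, v in d.get("charge_convention", {}).items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RegionScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_scheme() -> RegionScheme:
    """Calmodulin's canonical region scheme (author numbering, inclusive)."""
    return RegionScheme(
        regions={"N-lobe": (1, 68), "linker": (69, 91), "C-lobe": (92, 148)},
        helices={
            "I": (5, 17),
            "II": (30, 39),
            "III": (46, 54),
            "IV": (69, 73),
            "V": (83, 91),
            "VI": (101, 110),
            "VII": (119, 129),
            "VIII": (137, 144),
        },
        ef_loops={
            "I": (20, 22, 24, 31),
            "II": (56, 58, 60, 67),
            "III": (93, 95, 97, 104),
            "IV": (129, 131, 133, 140),
        },
        com_convention={"N-lobe": (5, 68), "linker": (69, 91), "C-lobe": (92, 147)},
        charge_convention={"N-lobe": (5, 68), "linker": (69, 91), "C-lobe": (92, 148)},
    )


_FILTERS = ("all", "backbone", "sidechain_heavy", "CA")


def select_region(
    cs: ConformerSet,
    scheme: RegionScheme,
    region: str,
    filter: str = "all",
) -> np.ndarray:
    """Atom indices of a named region, sorted ascending, stable across frames.

    ``filter`` is one of ``all`` (protein heavy+H atoms of the range),
    ``backbone`` (N/CA/C/O/OXT), ``sidechain_heavy``, or ``CA``.
    """
    if filter not in _FILTERS:
        raise ValueError(f"filter must be one of {_FILTERS}, got {filter!r}")
    lo, hi = scheme.lookup(region)
    out = []
    for i, a in enumerate(cs.atoms):
        if a.hetero or not (lo <= a.residue_number <= hi):
            continue
        if filter == "all":
            out.append(i)
        elif filter == "CA" and a.name == "CA":
            out.append(i)
        elif filter == "backbone" and a.name.upper() in BACKBONE_NAMES:
            out.append(i)
        elif filter == "sidechain_heavy" and a.is_sidechain_heavy:
            out.append(i)
    if not out:
        raise EmptySelectionError(
            f"selection {region!r} (residues {lo}-{hi}, filter={filter}) matched no atoms"
        )
    return np.array(sorted(out), dtype=int)
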