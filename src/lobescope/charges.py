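"""Formal-charge accounting under discrete protonation scenarios.

The model is deliberately coarse and fully enumerable: each residue carries
an integer side-chain formal charge (Asp/Glu -1, Lys/Arg +1, His 0 by
default), a protonation scenario flips listed titratable residues by +1
(an acidic goes -1 -> 0, a histidine 0 -> +1), point mutations replace the
residue type, and each structurally bound Ca2+ contributes +2 to the lobe
holding its EF loop. Termini are ignored. Under these conventions the
canonical calmodulin sequence gives net charges of -8 (N-lobe, residues
5-68 + 2 Ca2+), -1 (linker, 69-91), and -6 (C-lobe, 92-148 + 2 Ca2+).

pH enters only through scenario membership: which residues are flipped is
an input (e.g. from a pKa calculation), never inferred here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import LobescopeError, MissingResidueError
from .regions import RegionScheme

__all__ = [
    "CALMODULIN_SEQUENCE",
    "ProtonationScenario",
    "SCENARIO_PRESETS",
    "build_scenario",
    "residue_charge",
    "charge_table",
    "net_region_charge",
    "ionic_strength",
]

#: Canonical 148-residue vertebrate calmodulin sequence (mature chain,
#: one-letter). Identical to the SEQRES of the extended crystal structure.
CALMODULIN_SEQUENCE = (
    "ADQLTEEQIAEFKEAFSLFDKDGDGTITTKELGTVMRSLGQNPTEAELQDMINEVDADGN"
    "GTIDFPEFLTMMARKMKDTDSEEEIREAFRVFDKDGNGYISAAELRHVMTNLGEKLTDEE"
    "VDEMIREADIDGDGQVNYEEFVQMMTAK"
)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

SIDECHAIN_CHARGE = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}
TITRATABLE = frozenset({"ASP", "GLU", "HIS"})

#: Valences of supported monoatomic species for ionic-strength sums.
ION_VALENCE = {"NA": +1, "CL": -1, "K": +1, "MG": +2, "CA": +2}

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class ProtonationScenario:
    """Residue-level charge overrides and point mutations.

    ``protonated_acidics`` lists residue numbers flipped by +1 relative to
    the pH-7.4 reference state (Asp/Glu become neutral; His becomes +1).
    ``his_charge`` sets the resting charge of unlisted histidines.
    """

    name: str = "custom"
    protonated_acidics: frozenset[int] = frozenset()
    mutations: Mapping[int, str] = field(default_factory=dict)
    his_charge: int = 0
    include_ca: bool = True
    include_termini: bool = False
    pka_note: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "protonated_acidics", frozenset(self.protonated_acidics))
        object.__setattr__(self, "mutations", dict(self.mutations))
        if self.his_charge not in (0, 1):
            raise LobescopeError("his_charge must be 0 or +1")


#: Perturbation-scenario presets: physiological / low ionic strength runs,
#: low-pH mimicry (ten residues with upshifted pKa flipped), and single or
#: double point perturbations at residue 31 and partners.
SCENARIO_PRESETS: dict[str, dict] = {
    "IS-p": {},
    "C/IS-p": {},
    "IS-l": {},
    "IS-l+pH-l": {"protonated_acidics": {11, 31, 67, 84, 93, 104, 107, 122, 133, 140}},
    "E31+": {"protonated_acidics": {31}},
    "E31A": {"mutations": {31: "ALA"}},
    "E31/D122+": {"protonated_acidics": {31, 122}},
    "E31/H107+": {"protonated_acidics": {31, 107}},
    "D122+": {"protonated_acidics": {122}},
}


def build_scenario(name_or_spec, **overrides) -> ProtonationScenario:
    """A preset scenario by name, or a custom one from a mapping."""
    if isinstance(name_or_spec, ProtonationScenario):
        return name_or_spec
    if isinstance(name_or_spec, str):
        if name_or_spec not in SCENARIO_PRESETS:
            raise LobescopeError(
                f"unknown scenario {name_or_spec!r}; presets: {sorted(SCENARIO_PRESETS)}"
            )
        spec = dict(SCENARIO_PRESETS[name_or_spec])
        spec["name"] = name_or_spec
    else:
        spec = dict(name_or_spec)
        spec.setdefault("name", "custom")
    spec.update(overrides)
    return ProtonationScenario(**spec)


def normalize_sequence(sequence, start: int = 1) -> dict[int, str]:
    """Accept a one-letter string, a list of 3-letter codes, or a resnum map."""
    if isinstance(sequence, str):
        return {start + i: ONE_TO_THREE[c.upper()] for i, c in enumerate(sequence)}
    if isinstance(sequence, Mapping):
        return {int(k): str(v).upper() for k, v in sequence.items()}
    return {start + i: str(v).upper() for i, v in enumerate(sequence)}


def _apply_scenario(seq: dict[int, str], scenario: ProtonationScenario) -> dict[int, str]:
    out = dict(seq)
    for resnum, newname in scenario.mutations.items():
        if resnum not in out:
            raise MissingResidueError(f"mutation target residue {resnum} not in sequence")
        out[resnum] = newname.upper()
    for resnum in scenario.protonated_acidics:
        if resnum not in out:
            raise MissingResidueError(f"protonated residue {resnum} not in sequence")
        if out[resnum] not in TITRATABLE:
            raise LobescopeError(
                f"residue {resnum} ({out[resnum]}) is not titratable (Asp/Glu/His)"
            )
    return out


def residue_charge(resname: str, resnum: int, scenario: ProtonationScenario) -> int:
    """Side-chain formal charge of one residue under a scenario."""
    resname = resname.upper()
    protonated = resnum in scenario.protonated_acidics
    if resname == "HIS":
        return 1 if protonated else scenario.his_charge
    base = SIDECHAIN_CHARGE.get(resname, 0)
    if protonated and resname in ("ASP", "GLU"):
        return base + 1
    return base


def charge_table(sequence, scenario: ProtonationScenario | str = "IS-p") -> dict[int, int]:
    """Per-residue side-chain formal charges (after mutations)."""
    scenario = build_scenario(scenario)
    seq = _apply_scenario(normalize_sequence(sequence), scenario)
    return {r: residue_charge(n, r, scenario) for r, n in sorted(seq.items())}


def _ca_count_for_region(scheme: RegionScheme, lo: int, hi: int) -> int:
    """Two Ca2+ per lobe: count EF loops whose coordinating residues fall in range."""
    n = 0
    for residues in scheme.ef_loops.values():
        if all(lo <= r <= hi for r in residues):
            n += 1
    return n


def net_region_charge(
    sequence,
    scenario: ProtonationScenario | str,
    scheme: RegionScheme,
    region,
) -> int:
    """Net formal charge (e) of a region under a scenario.

    ``region`` is a name resolved through the scheme's charge_convention
    (falling back to its named regions) or an explicit inclusive
    ``(lo, hi)`` residue-number tuple. Bound Ca2+ ions add +2 each when
    the scenario includes them, assigned by EF-loop membership.
    """
    scenario = build_scenario(scenario)
    seq = _apply_scenario(normalize_sequence(sequence), scenario)
    if isinstance(region, str):
        if region in scheme.charge_convention:
            lo, hi = scheme.charge_convention[region]
        else:
            lo, hi = scheme.lookup(region)
    else:
        lo, hi = region
    missing = [r for r in range(lo, hi + 1) if r not in seq]
    if missing:
        raise MissingResidueError(
            f"region {region!r} residues missing from sequence: {missing[:5]}"
        )
    total = sum(residue_charge(seq[r], r, scenario) for r in range(lo, hi + 1))
    if scenario.include_ca:
        total += 2 * _ca_count_for_region(scheme, lo, hi)
    return int(total)


def ionic_strength(
    ion_counts: Mapping[str, int],
    box_lengths,
    valences: Mapping[str, int] | None = None,
) -> float:
    """Nominal ionic strength in mM: IS = 1/2 sum_i c_i z_i^2.

    Concentrations come from discrete counts in the periodic box,
    c_i = N_i / (N_A * V). Species valences default to the internal table
    (Na+, Cl-, K+, Mg2+, Ca2+); pass ``valences`` to extend it. Which
    species to include (e.g. salt ions only, excluding structurally bound
    ones) is the caller's choice of ``ion_counts``.
    """
    box = np.asarray(box_lengths, dtype=float)
    volume_l = float(np.prod(box)) * 1e-27  # A^3 -> liters
    if volume_l <= 0:
        raise LobescopeError("box volume must be > 0")
    val = dict(ION_VALENCE)
    if valences:
        val.update({k.upper(): int(v) for k, v in valences.items()})
    total = 0.0
    for species, count in ion_counts.items():
        if count < 0:
            raise LobescopeError(f"negative ion count for {species}")
        z = val.get(species.upper())
        if z is None:
            raise LobescopeError(f"unknown valence for species {species!r}")
        c_molar = count / (AVOGADRO * volume_l)
        total += c_molar * z * z
    return 0.5 * total * 1e3  # mol/L -> mM
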