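"""Config-driven analysis runs with reproducible plain-text artifacts.

A :class:`RunConfig` names the inputs, the region scheme, the protonation
scenario, and the analyses to run; :func:`run_pipeline` executes the
stages in order, fails fast on the first invalid one, and writes TSV/JSON
artifacts plus a machine-readable manifest (inputs, parameters, package
version) sufficient to reproduce the run. Outputs are byte-deterministic
for a given config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .charges import build_scenario, net_region_charge
from .errors import ConfigError, LobescopeError
from .geometry import ca_coordination_check, interhelix_angle_series, rmsd_series, salt_bridge_scan
from .ions import compute_rdf, coordination_number, first_minimum, first_peak, ion_indices
from .reduced import classify_by_length, detect_bend, length_labels, project
from .regions import RegionScheme, default_scheme, select_region
from .structure_io import read_pdb_models, read_trajectory

log = logging.getLogger("lobescope")

KNOWN_ANALYSES = (
    "project",
    "classify",
    "charges",
    "rdf",
    "coordination",
    "rmsd",
    "helices",
    "saltbridges",
    "cacheck",
)

_DEFAULT_PARAMS = {
    "thresholds": (30.0, 25.0),
    "phi_sign": 1,
    "bend_window": 4,
    "bend_threshold": 40.0,
    "region": "linker",
    "ion": "NA",
    "dr": 0.1,
    "r_max": 10.0,
    "r_cut": None,          # coordination shell; None -> first minimum of the RDF
    "sb_cutoff": 4.0,
    "sb_min_occupancy": 0.1,
    "ca_cutoff": 3.2,
    "helix_pairs": [["I", "II"]],
    "fit_region": None,     # rmsd: fit selection (None -> all protein atoms)
    "seed": 0,
}


@dataclass
class RunConfig:
    """Validated run description; unknown keys are rejected at load time."""

    analyses: list[str]
    pdb: str | None = None
    topology: str | None = None
    trajectory: str | None = None
    scheme: str | None = None
    scenario: str = "IS-p"
    out_dir: str = "lobescope_out"
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in self.analyses:
            if a not in KNOWN_ANALYSES:
                raise ConfigError(f"unknown analysis {a!r}; known: {KNOWN_ANALYSES}")
        unknown = set(self.params) - set(_DEFAULT_PARAMS)
        if unknown:
            raise ConfigError(f"unknown parameter key(s): {sorted(unknown)}")
        if self.pdb is None and (self.topology is None or self.trajectory is None):
            raise ConfigError("need either 'pdb' or both 'topology' and 'trajectory'")
        for p in (self.pdb, self.topology, self.trajectory, self.scheme):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if not isinstance(d, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(d)

    def param(self, key: str):
        return self.params.get(key, _DEFAULT_PARAMS[key])


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{v:.4f}" if isinstance(v, (float, np.floating)) else str(v)
                    for v in row
                )
                + "\n"
            )


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the configured analyses; return artifact name -> path."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = RegionScheme.from_json(config.scheme) if config.scheme else default_scheme()
    if config.pdb:
        cs = read_pdb_models(config.pdb)
    else:
        cs = read_trajectory(config.topology, config.trajectory)
    artifacts: dict[str, str] = {}
    series = None

    def _series():
        nonlocal series
        if series is None:
            series = project(cs, scheme, phi_sign=config.param("phi_sign"))
        return series

    for stage in config.analyses:
        log.info("stage %s", stage)
        try:
            if stage == "project":
                s = _series()
                labels = length_labels(s, tuple(config.param("thresholds")))
                rows = [
                    (int(s.frame_index[i]), s.l[i], s.phi_raw[i], s.phi_unwrapped[i], labels[i])
                    for i in range(len(s))
                ]
                p = out / "series.tsv"
                _write_tsv(p, ["frame", "l_A", "phi_deg", "phi_unwrapped_deg", "class"], rows)
                artifacts["series"] = str(p)
            elif stage == "classify":
                s = _series()
                thresholds = tuple(config.param("thresholds"))
                counts = classify_by_length(s, thresholds)
                bends = {}
                for i in range(cs.n_frames):
                    if s.l[i] <= thresholds[0]:
                        bends[str(i)] = detect_bend(
                            cs, scheme, i,
                            window=config.param("bend_window"),
                            angle_threshold=config.param("bend_threshold"),
                        )
                p = out / "classification.json"
                with open(p, "w") as fh:
                    json.dump(
                        {"thresholds_A": list(thresholds), "counts": counts, "bend_residue": bends},
                        fh, indent=2, sort_keys=True,
                    )
                artifacts["classification"] = str(p)
            elif stage == "charges":
                scenario = build_scenario(config.scenario)
                seq = cs.sequence()
                charges = {
                    region: net_region_charge(seq, scenario, scheme, region)
                    for region in scheme.charge_convention or scheme.regions
                }
                p = out / "charges.json"
                with open(p, "w") as fh:
                    json.dump({"scenario": scenario.name, "net_charge_e": charges}, fh,
                              indent=2, sort_keys=True)
                artifacts["charges"] = str(p)
            elif stage == "rdf":
                region = config.param("region")
                ion = config.param("ion")
                ref = select_region(cs, scheme, region, "sidechain_heavy")
                profile = compute_rdf(
                    cs, ref, ion, dr=config.param("dr"), r_max=config.param("r_max"),
                    region_label=region, ion_label=ion,
                )
                rows = list(zip(profile.r, profile.g, profile.pair_counts))
                p = out / f"rdf_{region}_{ion}.tsv"
                _write_tsv(p, ["r_A", "g", "pair_count"], rows)
                artifacts["rdf"] = str(p)
                peak = first_peak(profile)
                summary = {
                    "region": region,
                    "ion": ion,
                    "first_peak_r_A": None if peak is None else round(peak[0], 4),
                    "first_peak_g": None if peak is None else round(peak[1], 4),
                    "first_minimum_r_A": first_minimum(profile),
                }
                ps = out / f"rdf_{region}_{ion}_summary.json"
                with open(ps, "w") as fh:
                    json.dump(summary, fh, indent=2, sort_keys=True)
                artifacts["rdf_summary"] = str(ps)
            elif stage == "coordination":
                region = config.param("region")
                ion = config.param("ion")
                ref = select_region(cs, scheme, region, "sidechain_heavy")
                r_cut = config.param("r_cut")
                if r_cut is None:
                    profile = compute_rdf(cs, ref, ion, dr=config.param("dr"),
                                          r_max=config.param("r_max"))
                    r_cut = first_minimum(profile)
                    if r_cut is None:
                        raise ConfigError("no first minimum found; set params.r_cut")
                value = coordination_number(cs, ref, ion_indices(cs, ion), r_cut)
                p = out / f"coordination_{region}_{ion}.json"
                with open(p, "w") as fh:
                    json.dump({"region": region, "ion": ion, "r_cut_A": round(float(r_cut), 4),
                               "mean_ions_per_frame": round(value, 4)}, fh, indent=2, sort_keys=True)
                artifacts["coordination"] = str(p)
            elif stage == "rmsd":
                fit_region = config.param("fit_region")
                if fit_region:
                    fit = select_region(cs, scheme, fit_region, "all")
                else:
                    fit = np.array([i for i, a in enumerate(cs.atoms) if not a.hetero], dtype=int)
                measure = np.array([i for i, a in enumerate(cs.atoms) if not a.hetero], dtype=int)
                values = rmsd_series(cs, 0, fit, measure)
                p = out / "rmsd.tsv"
                _write_tsv(p, ["frame", "rmsd_A"], list(enumerate(values)))
                artifacts["rmsd"] = str(p)
            elif stage == "helices":
                rows = []
                header = ["frame"]
                columns = []
                for pair in config.param("helix_pairs"):
                    a, b = pair
                    header.append(f"angle_{a}_{b}_deg")
                    columns.append(interhelix_angle_series(cs, scheme, a, b))
                for f in range(cs.n_frames):
                    rows.append((f, *[col[f] for col in columns]))
                p = out / "helix_angles.tsv"
                _write_tsv(p, header, rows)
                artifacts["helices"] = str(p)
            elif stage == "saltbridges":
                events = salt_bridge_scan(
                    cs, cutoff=config.param("sb_cutoff"),
                    min_occupancy=config.param("sb_min_occupancy"),
                )
                p = out / "salt_bridges.json"
                with open(p, "w") as fh:
                    json.dump([e.__dict__ for e in events], fh, indent=2, sort_keys=True)
                artifacts["saltbridges"] = str(p)
            elif stage == "cacheck":
                intact, _ = ca_coordination_check(cs, scheme, cutoff=config.param("ca_cutoff"))
                loops = sorted(intact)
                rows = [(f, *[int(intact[lp][f]) for lp in loops]) for f in range(cs.n_frames)]
                p = out / "ca_coordination.tsv"
                _write_tsv(p, ["frame", *[f"loop_{lp}" for lp in loops]], rows)
                artifacts["cacheck"] = str(p)
        except Exception as exc:
            raise LobescopeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "version": _version,
        "inputs": {
            "pdb": config.pdb,
            "topology": config.topology,
            "trajectory": config.trajectory,
            "scheme": config.scheme,
        },
        "scenario": config.scenario,
        "analyses": config.analyses,
        "parameters": {k: config.param(k) for k in sorted(_DEFAULT_PARAMS)},
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
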