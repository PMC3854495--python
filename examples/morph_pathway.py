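"""Geometric-targeting morph between two conformers, in reduced coordinates.

Morphs a dumbbell at interlobe torsion 100 degrees into one at 150 degrees
in fixed-RMSD steps while keeping bonds within 2% of their reference
lengths and atoms un-overlapped, then summarizes an ensemble of seeded
pathways as a median (l, phi) track with standard errors.
"""

import numpy as np

import lobescope as lb
from lobescope.synth import dumbbell_bonds

scheme = lb.default_scheme()
start = lb.build_dumbbell(lb.DumbbellSpec(target_l=None, target_phi=100.0))
target = lb.build_dumbbell(lb.DumbbellSpec(target_l=None, target_phi=150.0))
cs = start.with_frames(np.stack([start.frames[0], target.frames[0]]))
cs._cache["bonds"] = dumbbell_bonds(cs)

results, summary = lb.ensemble_morph(
    cs, lb.MorphSpec(step_rmsd=0.25, seed=11), 0, 1,
    n_paths=4, scheme=scheme, grid_points=11,
)
res = results[0]
print(f"path 0: {res.frames.n_frames} frames, final RMSD to target "
      f"{res.rmsd_to_target[-1]:.3f} A, converged={res.converged}")
# -> the walk stops within one step (0.25 A here) of the target and every
#    intermediate frame satisfies the bond and clash constraints.

grid, med_phi, se_phi = summary["phi"]
print("median torsion along the normalized pathway (deg):")
print("  " + "  ".join(f"{v:6.1f}" for v in med_phi))
print("  standard error: " + "  ".join(f"{v:6.2f}" for v in se_phi))
# -> phi sweeps ~100 -> ~150 while l stays put: the pathway family is wide
#    in torsion but narrow in linker length, as geometric constraints allow.
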