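# Methods

## Reduced coordinates

A conformer of a lobe–linker–lobe protein is summarized by two numbers:
the linker end-to-end length *l* (distance between the Cα atoms of the
outermost linker residues, 69 and 91 in the default calmodulin scheme)
and the interlobe torsion *φ*, the dihedral over the ordered anchors
(N-lobe center of mass, Cα69, Cα91, C-lobe center of mass). The dihedral
uses the standard IUPAC sign convention (the same one MD analysis
packages report); because an unoriented structure determines *φ* only up
to the mirror ambiguity, `project(..., phi_sign=-1)` flips the
convention. *φ* is reported raw in (−180°, 180°] and as an unwrapped
continuous track (±360° added whenever consecutive frames jump by more
than 180°), unwrapping starting from the first frame; concatenated
trajectories should be unwrapped separately.

Centers of mass are mass-weighted over the non-hydrogen protein atoms of
the lobe ranges. Two range conventions coexist deliberately:

- `com_convention` 5–68 / 69–91 / 92–147 anchors the torsion. The
  extended crystal structure lacks residues 1–4 and 148, so these
  anchors stay computable on it.
- `charge_convention` 5–68 / 69–91 / 92–148 is the unique simple range
  assignment for which side-chain-only counting with bound Ca²⁺
  reproduces all three canonical region charges (−8/−1/−6 e); verified
  by direct enumeration over the 148-residue sequence.

Both are plain data on `RegionScheme` and overridable from JSON.

### Length classes and boundaries

Ensembles are binned on *l* at thresholds 30 and 25 Å into
extended (30, ∞), intermediate (25, 30] and compact [0, 25]. Published
class counts cannot distinguish the boundary treatment (no model sits
exactly on a threshold), so boundary values are assigned to the lower
class; both thresholds are parameters.

### Bend detection

For each candidate linker residue *i*, the deviation angle between the
incoming segment Cα(i−w)..Cα(i) and the outgoing segment
Cα(i)..Cα(i+w) (default window w = 4). Raw chord vectors on a helical
trace carry a periodic radial wiggle of up to ~15°, enough to displace
the argmax by two residues, so the trace is first smoothed with a
5-point kernel (1,2,2,2,1)/8 spanning roughly one helical turn, and each
segment direction is the principal axis of its smoothed points, oriented
along the chord. On generated kinks this localizes the bend within one
residue anywhere in the linker. A bend is reported only when the maximal
angle exceeds the threshold (default 40°), chosen so ideal straight
helices (residual ≲ 9°) report none; the windowed, smoothed estimate
attenuates the geometric kink angle by roughly 10–25%, so kinks shallower
than ~60° can fall under the default threshold — raise sensitivity by
lowering the threshold if that regime matters. Candidates are restricted
to residues with both segments inside the linker, which keeps the
operation well defined on linker-only traces and independent of lobe
geometry.

## Charge model

Integer side-chain formal charges: Asp/Glu −1, Lys/Arg +1, His 0 (or +1
when protonated or when `his_charge=1`), everything else 0; termini are
ignored. A protonation scenario is a discrete set of flipped residues —
protonation always adds +1 (acidics become neutral, histidines
cationic) — plus optional point mutations. pH enters *only* through
scenario membership, never through a Henderson–Hasselbalch fraction: the
intended use is MD-style discrete charge states, with the pKa
calculation that motivated a set kept as metadata. Bound Ca²⁺ ions add
+2 each, assigned two per lobe via EF-loop membership of the scheme.

Nominal ionic strength is IS = ½ Σ cᵢzᵢ², cᵢ = Nᵢ/(N_A·V), reported in
mM from discrete counts and box volume. Which species to include (e.g.
excluding the four structurally bound Ca²⁺) is the caller's choice.
Published per-run IS labels in the literature often cannot be reproduced
from printed counts and box sizes by any standard convention; this
package treats such labels as names, not targets.

## Ion analysis

g(r) between reference atoms (side-chain heavy atoms of a region by
default, per the region scheme; an acidic-oxygen-only selector is
provided for coordination work) and an ion species:
g(r) = ⟨pair count in shell⟩ / (N_ref · ρ · V_shell), averaged over
frames, with the minimum-image convention in orthorhombic boxes and the
per-frame bulk density ρ = N_ions/V (NPT boxes fluctuate). Exact shell
volumes 4π/3·(r₂³−r₁³) are used rather than 4πr²dr. Defaults
dr = 0.1 Å, r_max = 10 Å; r_max beyond half the smallest box edge is an
error. Each reference *atom* is a site (not each residue).

First peak: first local maximum above g = 1 within 6 Å on a 3-bin
moving-average smoothed profile (both parameters open — the smoothing a
published peak table used is generally unstated). First minimum: first
local minimum after that peak; it defines the first-coordination-shell
cutoff where the caller does not supply one. Coordination numbers count
each ion at most once per frame regardless of how many reference atoms
it touches: the quantity is "ions in the shell", not contacts.

## Interdomain geometry

Superposition is the least-squares proper rotation (Kabsch, via scipy's
`Rotation.align_vectors`); collinear selections are rejected because the
rotation about the line is undetermined. RMSD series superpose each
frame on a fit selection and measure over a possibly different one:
fit = measure = subunit isolates internal motion, fit = subunit with
measure = all exposes interdomain rearrangement.

Helix axes are principal axes of the Cα positional covariance, oriented
N→C — less sensitive to terminal fraying than end-to-end vectors — with
the same one-turn smoothing as bend detection applied for helices of ≥8
residues (on shorter fragments the truncated kernel hurts more than it
helps; accuracy is ~0.2° at 13 residues, ~2° at 10). Inter-helix angles
are reported oriented in [0°, 180°]: reversing one helix gives the
supplement, and no attempt is made to guess which of θ/180−θ a published
convention meant.

Salt bridges: a (Asp/Glu, Lys/Arg) residue pair is an event when the
minimum distance between carboxylate oxygens (OD1/OD2, OE1/OE2) and
basic nitrogens (NZ; NH1/NH2/NE) is ≤ 4.0 Å — common practice, since no
single criterion is canonical — in at least `min_occupancy` of frames
(default 0.1). EF-hand integrity: each Ca²⁺ is assigned to the nearest
EF loop (frame 0, one ion per loop, greedy by centroid distance); a loop
is intact in a frame iff every listed coordinating residue has a
side-chain oxygen within 3.2 Å of its ion. Backbone-carbonyl
contributions are deliberately not checked — the coordinating-residue
lists name side-chain ligands.

## Geometric-targeting morphs

The morph treats the protein as a geometric system: no energies, only
constraints. Per step: (1) displace all atoms linearly toward the target
so the RMSD drops by `step_rmsd` (default 0.05 Å); (2) optionally add a
small seeded lateral displacement (`wander`, default 0.25·step_rmsd
RMS) — this is what makes different seeds explore genuinely different
pathways through the allowed region; (3) restore constraints by
randomly-ordered Gauss–Seidel projection sweeps (pass limit 500): each
violated bond is set back to its reference length ± 2% by moving both
atoms along the bond, each non-excluded pair closer than
0.8 × (vdW_i + vdW_j) is pushed apart symmetrically. If a step fails to
make net progress it is re-pulled toward the target up to 8 times;
a stall flags the result `converged=False` rather than failing silently.
Recorded `rmsd_to_target` is strictly decreasing, the walk stops within
one step of the target, and identical seeds reproduce paths bitwise.

Bonds come from an explicit list (coarse models carry their pseudo-bond
lists), else a 1.99 Å heavy-atom distance criterion on the start frame;
1-2 and 1-3 pairs are excluded from clash checks; vdW radii from a fixed
internal table (C 1.70, N 1.55, O 1.52, S 1.80, Ca²⁺ 2.31, Na⁺ 2.27 Å,
default 1.70). Ramachandran, hydrogen-bond and hydrophobic-contact
constraints of the full geometric-targeting method are out of scope:
bond + clash constraints are the verifiable core, and the downstream
analysis consumes the path only in (*l*, *φ*). Pathway ensembles are
resampled onto a common normalized arc-length grid (cumulative
inter-frame RMSD) before the per-point median and standard error — the
alignment any cross-path statistic needs, since paths differ in length.

## Synthetic data

Generators are deliberately coarse: one Cα plus one pseudo side-chain
carbon (CB) per non-glycine residue, carbon masses throughout, and the
canonical 148-residue vertebrate calmodulin sequence (identical to the
SEQRES of the extended crystal structure) as the default identity.

The dumbbell builder places the linker as an ideal helix whose rise is
solved (Brent) so the end-to-end length hits `target_l` exactly; the
helix radius shrinks with rise so consecutive Cα atoms keep their 3.8 Å
spacing — an α-helical linker (rise 1.5 Å) has radius ≈ 2.3 Å, and the
build unwinds continuously toward an extended chain, reaching lengths
from ~17 Å up to near the 22-step contour length (~83 Å; beyond is an
error). A kink inserts a second helical arm rotated by `bend_angle` at
the chosen residue, phase-continuous, so all bond lengths match the
straight build with the same rise — which is what lets a morph connect
straight and kinked builds under bond constraints. Lobes are rigid
snake-ordered lattices (3.8 Å spacing) translated so their mass centers
land exactly on anchors constructed to realize `target_phi`; recovery of
(*l*, *φ*) by projection is therefore exact up to floating point, and
the 0.5 Å / 2° recovery margins quoted in the tests are dominated by
nothing — they are safety bands, not observed error.

Ion baths place counted ions uniformly in the box, with two refinements:
an excluded-volume radius around reference atoms (default 1.8 Å,
resampling overlapping ions) emulating short-range repulsion — without
it, near-empty low-r bins produce spurious g ≫ 1 spikes that a real
solute's excluded volume forbids — and an optional Gaussian kernel
placing `n_biased` ions at distances ~N(r0, σ) from random reference
atoms to create a controlled first peak. What the generators do *not*
emulate: real side-chain rotamers, water, correlated dynamics,
force-field energetics. Passing recovery tests therefore demonstrates
the *measurement operations* are correct, not that any simulation result
is reproduced.

Fixed study conditions used by the tests and the acceptance script: 100
recovery conformers spanning l ∈ [20, 45] Å and φ ∈ (−180°, 180°];
two-state switch trajectories of 100 + 100 frames at 0.3 Å coordinate
noise; 500-ion baths in 40 Å boxes read over [3, 10] Å with ≥10⁴ pair
observations; 20-atom chain morphs at the 0.05 Å step. These sizes give
each check comfortable statistics while keeping the default suite fast.

## Known limitations

- Orthorhombic boxes only (minimum image); triclinic cells are not
  supported.
- The bend estimator under-reports shallow kinks (see above).
- The morph explores no backbone-dihedral chemistry; its pathways are
  geometrically viable, not mechanistically timed.
- Charge accounting is formal and integer-valued; no partial charges,
  no conformation-dependent pKa.
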