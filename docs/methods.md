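# Methods

`dcplan` models single-energy-layer, dynamically collimated PBS proton
treatments in the 2D plane at the treatment depth. This note records the
models, their parameters and assumptions, the numerical choices, and what
the synthetic setting does and does not demonstrate.

## Beamlet kernel model

An uncollimated beamlet is a radially symmetric double Gaussian in the
lateral plane,

    f(r) = w · G(r; σ_core) + (1 − w) · G(r; σ_halo),

with core weight `w = 0.95`, halo sigma `σ_halo = 3 σ_core`, and each `G`
a normalized 2D Gaussian. The kernel is sampled on a node-centered 1 mm
isotropic lattice and normalized so the central-axis node equals the
Gy/proton peak calibration (default `1e-9` Gy/proton; absolute
calibration is machine-specific and configurable). The light halo stands
in for the low-dose envelope (large-angle scatter, secondaries) that real
beamlets carry; without it, rind doses would be negligibly small and
collimation benefits unmeasurable.

The in-water core sigma at evaluation depth `d` (cm) broadens as

    σ_core = sqrt(σ_air² + (k·d)²),   k = 0.35 mm/cm (default),

where `σ_air` is the tabulated in-air spot sigma at isocenter for each
machine beam (energies 78.3–184.6 MeV, treatment depths 2–22.5 cm, with
and without the upstream range shifter). The linear-in-depth broadening is
a deliberate simplification; it slightly overestimates lateral spread for
the deepest beams, which makes the uniformity protocol *harder* to meet
there, not easier.

### Collimation

An engaged trimmer blade multiplies the kernel by an erf transmission
edge — a unit step at the blade edge convolved with a Gaussian of
edge-spread sigma

    σ_edge = sqrt((θ_eff · (TSD + d_w))² + (k·d_w)²),

with `θ_eff = 2 mrad` for unshifted (NRS) and `12 mrad` for range-shifted
(RS) beams, `TSD` the trimmer-to-surface distance and `d_w` the in-water
depth (both converted to mm inside the formula). Applying the blur to the
transmission function rather than to the collimated dose keeps the
collimated kernel pointwise ≤ the open kernel — the physically required
property that a passive absorber only removes dose — while producing the
erf-like collimated edges seen in measured and Monte Carlo profiles. The
two-parameter angular model is chosen so that RS fields show a strong TSD
dependence of the penumbra and NRS fields almost none, the qualitative
contrast the hardware exhibits. The `2` blades (X2, Y2) collimate from
the positive-coordinate side with the edge at `+offset` from the beamlet
axis; the `1` blades mirror them. Engaged trimmers fully attenuate
(transmission beyond the blurred edge → 0); blade thickness has no
further analytic consequence.

### Library expansion

The machine's offset table defines nine base states (four two-blade
combinations at 1/2 mm offsets, two single-X, two single-Y, one open) in
the X2/Y2 convention. Applying the four axis flips (identity, mirror-X,
mirror-Y, both) to the eight collimated states yields the conventional
count of 32 trimmed kernels plus the open kernel. Single-blade entries
are pairwise mirror-degenerate, so the *distinct*-configuration count is
24; deduplication is off by default to preserve the conventional count,
and `KernelLibrary.configs()` exposes the 24 distinct states.

## Targets and rinds

Analysis masks live on a 0.5 mm node-centered lattice (kernels are
interpolated from their 1 mm lattice on demand). Circles of 3/5/8 cm
diameter include a node iff its center lies within the radius. The
kidney-bean crescents follow the concave test-shape archetype from
treatment-planning QA practice: an outer ellipse with 45×25 mm semi-axes
minus an inner 40×22 mm ellipse displaced 15 mm along the minor axis
(large variant); the small variant scales all lengths by 0.4 and is
planned at 1 mm spot spacing. These dimensions are declared, not derived
from any published figure. Rinds of width `w` are Euclidean
distance-transform dilations of the target minus the target, so the rind
width is isotropic rather than axis-aligned; rind generation refuses
grids too small to contain the dilation.

## Plan construction

Spots are placed on a rectangular lattice (2.5 mm default) covering the
target bounding box expanded by a 10 mm margin, aligned so one node falls
on the target centroid; the margin keeps edge candidates outside the
target available to the optimizer. Each candidate spot is scored by the
conformity dose ratio `DR = 100%·D_in/D_out` integrated over the analysis
grid; `D_out = 0` (a beamlet fully inside the target) maps to `+inf`,
which passes every selection threshold and is never collimated. Open
plans use `DR_thresh = 30%`, collimated plans `16%` — the looser cut
admits the extra outside-the-target beamlets that the sharper collimated
penumbra needs for coverage.

The collimation level `T_coll` is operationalized as a threshold on the
open-field DR: a selected spot is trimmed iff its open DR is finite and
below `T_coll`, so trimming concentrates at the target edge and the
trimmed-spot count grows monotonically with `T_coll`. The assigned
configuration maximizes the spot's DR over the library, with ties broken
by fewer engaged blades, then smaller offsets. A 1 mm minimum engaged
offset from the beamlet axis is enforced throughout for delivery
robustness.

## Weight optimization and the pairing protocol

Spot weights (protons) minimize

    Σ_target p_i (D_i − Rx)² + λ_rind Σ_rind max(D_i − L, 0)²,  weights ≥ 0,

with prescription `Rx = 5 Gy`, rind limit `L = 0` and default
`λ_rind = 0.05`. With `L = 0` the one-sided term is an ordinary
least-squares block (dose is nonnegative), so a single active-set
nonnegative least-squares solve suffices; `L > 0` is handled by a
deterministic violation-set iteration. Tall systems are compressed
through the normal equations (Cholesky square root with a `1e-12`
relative diagonal lift) before the active-set solve. Optimization samples
every other analysis node (1 mm effective) within the target and the
30 mm rind; all reported metrics use the full 0.5 mm grid.

Plan acceptance requires D98 and D2 over the target area within ±3% of
the prescription ([4.85, 5.15] Gy), and paired open/collimated plans to
agree in D98 and D2 within 1%. Percentiles use linear interpolation on
the sorted dose-area curve. The auto-tuner that enforces this is
deterministic and three-staged:

1. a shared rind weight is halved from its default until both plans meet
   the window and pair;
2. if no rind weight alone reaches the window (the deepest beam's broad
   kernels leave ~3.3% least-squares ripple on the concave target),
   per-node point penalties `p_i` are escalated ×1.25 per iteration
   (capped at 10³) on nodes outside 97.2–102.8% of prescription,
   excluding a fixed 1%-area tail at each extreme — D98/D2 are 2nd/98th
   area percentiles, so the extreme tails need not be driven into the
   window;
3. a residual pairing gap is closed by bisecting the rind weight of the
   plan with the more generous coverage.

Stage 2 is the package's reading of "point- and area-based penalties
tuned to equalize coverage": the tuning loop adjusts penalty weights, not
acceptance thresholds.

## Evaluation and QA

**Rind metrics.** The rind dose summary is the arithmetic mean dose over
rind nodes as a percent of prescription (the area-percentile D50 is
available separately and is not identical for skewed dose
distributions). The collimation-induced reduction is
`100·(mean_open − mean_coll)/Rx`. Depth trends are least-squares linear
or quadratic fits; the zero-crossing depth (where the benefit of
collimation extrapolates to nothing) is the smallest real root within a
30 cm window beyond the last data point.

In this analytic model the 10 mm rind shows a *larger* absolute
(%-of-prescription) reduction than the 30 mm rind, because the benefit is
concentrated in the first ~1 penumbra width outside the target and the
wider annulus dilutes it; expressed relative to the open-field rind dose
the ordering reverses. Monte Carlo beamlets with their long-range nuclear
halo put far more open-field dose into the 10–30 mm band, which is why
measured studies report the absolute ordering the other way. This is a
known, documented divergence of the stand-in kernel from transport
physics.

**Gamma analysis.** Global-normalization gamma: dose differences are
scaled by `criterion% × max(reference)`, nodes below the dose threshold
(default 10% of the reference maximum) are excluded from the pass-rate
denominator, and the spatial search covers a disk of radius 3×DTA on a
fine lattice of one fifth of the grid spacing with bilinear
interpolation. A DTA-independent search lattice (rather than one scaled
to the DTA) keeps pass rates monotone under loosened criteria by
construction: a larger DTA searches a superset of candidates with a
smaller distance penalty. Offsets are scanned in order of increasing
radius with early termination once the distance term alone exceeds every
node's current gamma². Relative (film-style) mode first rescales the
evaluated dose by the least-squares factor over above-threshold nodes.
Depth-direction DTA is reported by re-running gamma against simulated
planes at ±1/±2/±3 mm depth offsets and returning the smallest offset
achieving the best pass rate.

**Registration and chamber dose.** Rigid registration maximizes
normalized cross-correlation over a coarse grid (±10 mm in 2 mm steps,
±5° in 1° steps) refined by Nelder–Mead; it is deterministic and recovers
injected shifts and rotations to well under 0.25 mm / 0.25°. The
central-axis dose averages over a centered disk footprint (default 10 mm
diameter, a nominal plane-parallel chamber aperture — a configuration
parameter, not a vendor datum).

## Delivery files

The extended PLD dialect is documented in `dcplan.pld`: comma-separated
layer blocks and element lines `spot,x,y,MU,T_X1,T_X2,T_Y1,T_Y2`, with
`Out` for parked blades, coordinates in isocenter-plane mm (3 decimals)
and MU to 6 significant digits. Weights convert to MU through a
per-energy protons/MU factor, `(Gy/MU)/(Gy/proton)`, stored alongside a
plain-text calibration table. Parsing is strict: element lines without
the four trimmer fields, unknown records, or negative MU raise errors
naming the offending line. The dialect is self-consistent and
round-trips byte-identically; it does not emulate any vendor's
proprietary syntax.

## Problem sizes and determinism

Default scenarios plan 400–1000 spots against 10⁴–10⁵ analysis nodes;
a full open/collimated pair, including auto-tuning, takes seconds to a
few tens of seconds on one CPU (the deepest beam is slowest because its
kernels are widest and stage-2 tuning engages). The qualitative trend
characterizations use the 8 cm circle (depth trend) and the 5 cm circle
(TSD trend) — shapes whose smooth convex boundaries isolate the edge
physics from concavity effects. Every stage of the pipeline is
deterministic for a fixed configuration; the configuration seed is
recorded in logs for provenance only.

## Limitations

- No particle transport: kernel parameters (halo weight/width, `k`,
  `θ_eff`) are declared model constants, not fitted to any machine, and
  absolute rind-dose magnitudes should not be compared to measured
  values. Passing tests demonstrate the protocol and trend *mechanics*,
  not dosimetric accuracy for real hardware.
- Single energy layer, 2D planes only; no SOBP composition, no 3D
  depth-dose, no robustness/interplay modeling, no trimmer motion
  sequencing.
- The collimation-level rule is an operational definition with the
  documented monotonicity; alternative formulations that yield the same
  qualitative behavior exist.
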