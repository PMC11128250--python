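# dcplan

Desk-scale treatment planning and dosimetric QA for **dynamically
collimated pencil-beam-scanning (PBS) proton therapy**.

In PBS, narrow proton beamlets are magnetically scanned across a target.
A sliding-bar dynamic collimation system (DCS) adds four independently
moving trimmer blades (X1, X2, Y1, Y2) that can sharpen the lateral
penumbra of individual spots at the field edge, sparing the normal tissue
that surrounds a shallow target. `dcplan` implements the complete
computational chain needed to study and deliver such treatments in a 2D
single-energy-layer setting:

1. **Beamlet library** (`dcplan.beamlets`) — analytic double-Gaussian
   beamlet kernels (Gy/proton on a 1 mm lattice) for the tabulated machine
   beams, collimated by erf-shaped trimmer transmission edges and expanded
   by mirror symmetry into the full library of 32 trimmed + 1 open kernels
   per energy.
2. **Targets and rinds** (`dcplan.targets`) — rasterized circular and
   kidney-bean targets with annular 10/30 mm normal-tissue rind regions.
3. **Plan building** (`dcplan.planning`) — spot lattice placement and
   beamlet selection by the conformity dose ratio
   `DR = 100% · D_in / D_out ≥ DR_thresh`, with per-spot trimmer
   assignment governed by the collimation level `T_coll` (a spot is
   trimmed when its open-field DR falls below `T_coll`; the configuration
   maximizing DR is chosen).
4. **Weight optimization** (`dcplan.optimize`) — nonnegative least squares
   on the beamlet influence matrix toward a uniform 5 Gy target dose, with
   a one-sided rind overdose penalty and a deterministic auto-tuner that
   enforces the plan-acceptance protocol: D98 and D2 within ±3% of the
   prescription, and paired open/collimated plans within 1% of each other.
5. **Evaluation & QA** (`dcplan.evaluate`) — dose-area percentiles,
   rind mean-dose reductions and their depth/TSD trends, global 2D
   gamma-index analysis (e.g. 3%/2 mm, 10% threshold), rigid registration
   of measured vs simulated planes, and chamber-footprint central-axis
   dose.
6. **Delivery files** (`dcplan.pld`, `dcplan.cli`) — an extended PLD
   (pencil layer definition) dialect whose element lines carry the four
   trimmer coordinates, with protons↔MU conversion, plus a `dcplan`
   command-line interface over the whole pipeline.

The kernels are generated analytically (no Monte Carlo transport), so the
package reproduces the *protocol and qualitative physics* of dynamically
collimated planning — penumbra sharpening, rind dose reduction shrinking
with depth, strong trimmer-to-surface-distance (TSD) sensitivity only when
a range shifter is present — rather than any machine-specific absolute
dosimetry. See `docs/methods.md` for the model and its limitations.

## Worked example

Build the coverage-matched open/collimated plan pair for the large
kidney-bean target at the 78.3 MeV unshifted beam (5 cm depth, 2.5 mm spot
spacing, `T_coll` = 40%):

```python
from dcplan import pipeline

config = pipeline.PipelineConfig()  # large kidney bean, 78.3 MeV NRS, 5 cm
pair = pipeline.plan_pair(config)

u, c = pair.uncoll.report, pair.coll.report
print(f"open plan:       D98 = {u.d98:.3f} Gy, D2 = {u.d2:.3f} Gy")
print(f"collimated plan: D98 = {c.d98:.3f} Gy, D2 = {c.d2:.3f} Gy")
print(f"trimmed spots:   {pair.coll.plan.n_collimated} of {len(pair.coll.plan.spots)}")
for w in sorted(pair.reductions):
    print(f"{w:.0f} mm rind: mean dose {pair.uncoll_rind_dose[w]:.1f}% -> "
          f"{pair.coll_rind_dose[w]:.1f}% of Rx  (reduction {pair.reductions[w]:.1f}%)")
```

prints

```
open plan:       D98 = 4.852 Gy, D2 = 5.098 Gy
collimated plan: D98 = 4.858 Gy, D2 = 5.130 Gy
trimmed spots:   146 of 527
10 mm rind: mean dose 65.6% -> 49.6% of Rx  (reduction 15.9%)
30 mm rind: mean dose 21.8% -> 14.3% of Rx  (reduction 7.5%)
```

Both plans sit inside the [4.85, 5.15] Gy acceptance window with D98/D2
paired well within 1% of the prescription, so the rind numbers compare
like for like: engaging the trimmers on the 146 edge spots removes dose
equal to 15.9% of the prescription from the 10 mm rind around the target.

The same run from the shell, writing the full artifact bundle (plan
tables, dose grids, criteria report, rind summary, gamma report, PLD
delivery files):

```bash
dcplan -v run-all -o out/kidney_nrs5
```

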