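# Methods

## The model

The package analyses colonies of workers moving in a square enclosure
(side 248 mm) recorded for 30 s at 15 frames s⁻¹, with positions annotated
every 5 frames (90 samples per worker at 3 Hz). From the tracked subset N
of the N\* censused workers it derives, per colony:

- **L** — mean (and median) per-worker path length, the sum of Euclidean
  displacements between consecutive 3 Hz samples. No interpolation to the
  full frame rate is attempted: the displacement between annotated frames
  is the resolution of the data.
- **A** — the number of active workers, average speed > 0.1 mm s⁻¹
  (strictly greater: 3 mm over 30 s is inactive). Partially tracked workers
  are scored over their own observed time span.
- **E** — the time average over frames of the edge count of the proximity
  graph linking workers within d = 6 mm (inclusive comparison; roughly one
  body length). ⟨k⟩ = 2E/N always uses the colony-level tracked count, even
  when some workers are absent from a frame.
- **Area** — the number of cells of a 24×24 occupancy grid visited by any
  sample of any worker, times the cell area.

Three fitted relations connect these to colony size: E = E₀N^βE and
Area = Area₀N^βArea (log-log OLS), and L versus N (raw-variable OLS, whose
slope is statistically null). The activity model balances active–active
contact events ⟨k⟩A²/N against spontaneous activation qN; q is estimated
as the slope of ⟨k⟩A²/N on N (with intercept, matching the reported
procedure; a zero-intercept variant is exposed since the balance relation
itself passes through the origin). Solving the balance under
E = E₀N^βE gives A = √(q/2E₀)·N^((3−βE)/2), hypometric whenever βE > 1.

Metabolic rate is modelled as a degree-one Cobb–Douglas function
B = B₀(A\*)^αB(I\*)^(1−αB) of the whole-colony active and inactive counts
A\* = A·N\*/N, I\* = N\* − A\*. It is fitted by the univariate regression
ln(B/I\*) = ln B₀ + αB·ln(A\*/I\*), which sidesteps the collinearity of A\*
and I\*. Marginal products are αB·B/A\* and (1−αB)·B/I\*; Euler's identity
A\*·MP(A\*) + I\*·MP(I\*) = B holds exactly and is verified numerically.
Composing the Cobb–Douglas function with the predicted A gives a
closed-form B(N) valid where the predicted active fraction
√(q/2E₀)·N^((1−βE)/2) is below 1; smaller colonies raise a domain error
rather than silently clipping, since the balance model has nothing to say
there. With M ∝ N the large-N log-log slope is (1−βE)αB/2 + 1 — the
package's point of contact with Kleiber-style metabolic allometry — and
βE = 1 recovers isometry.

## Parameters that matter

| parameter | default | units | meaning |
|---|---|---|---|
| speed threshold | 0.1 | mm s⁻¹ | active/inactive cut, strict `>` |
| d | 6 | mm | proximity (interaction) distance, inclusive `≤` |
| grid | 24×24 | — | occupancy grid; cell = enclosure/24 ≈ 10.33 mm |
| cell-length override | none | mm | force e.g. 10.6 mm (≈ √(πd²)); the grid then overhangs the 248 mm enclosure, since 24 × 10.6 mm cannot tile it — both modes are provided and neither is asserted as canonical |
| βE, E₀ | 1.47, 0.0944 | — | generator defaults: interaction scaling |
| βArea, Area₀ | 0.51, 3050 mm² | — | generator defaults: area scaling |
| q | 0.519 | — | activation/deactivation rate ratio |
| αB, B₀ | 0.85, 0.0301 mW | — | Cobb–Douglas elasticity and scale |
| noise σ (log) | 0.2 | — | lognormal multiplicative noise, summary mode |

All fits use natural logs; the log base only shifts the intercept and is
normalised out when the prefactor is recovered as exp(intercept).
Confidence intervals are t-based with n − 2 residual degrees of freedom
(14 for the canonical 16-colony design) and are symmetric in log space for
power laws. Zero responses (a colony with A = 0, or a zero scaled count)
are excluded from log-space fits with a warning; a fit needs at least
three surviving points.

## The synthetic world

**Summary mode** draws N\* log-uniform on [40, 400], tracks
N = round(0.85·N\*), then applies the generating laws with independent
lognormal(0, σ) factors on E, Area, and B. The active count solves the
balance relation using the colony's own noisy E (then rounds to an
integer and caps at N), which keeps the q regression internally
consistent. Quantities no published value pins down were fixed once:
colony mean path length lognormal around 77 mm (the value implied by the
steady-motion interaction-area bound 2dL = 924 mm²), wet mass
8 mg·N\* with σ = 0.1 lognormal noise (a realistic per-worker wet mass
including a brood share), and median path length 0.9× the mean (path
lengths are right-skewed). Generated Area is not capped at the enclosure
area; at the top of the size range the scaling law with noise can
nominally exceed it, and truncating would bias the exponent the recovery
tests target.

**Trajectory mode** places `n_clusters` (default 4) attractor sites per
enclosure, assigns workers to sites with Dirichlet(0.7) weights (a few
sites dominate, as around a brood pile or food), and labels workers active
with the balance-predicted fraction (capped at 0.95, overridable).
Inactive workers hold a fixed point near their site with 0.005 mm
per-sample jitter — far below the 3 mm activity cut. Active workers walk
with persistent headings biased toward their current target site,
switching targets at 3% per step, with per-worker total path drawn
lognormal around 77 mm independent of colony size; walls reflect.
Randomness uses one root `SeedSequence` with per-colony spawned child
streams, so appending colonies never changes earlier ones.

What trajectory mode does *not* emulate: activation/deactivation dynamics
within the video (activity labels are static, which is all a 30 s window
resolves), pheromone fields, task structure, or body orientation (so
antennal-contact interaction definitions are out of scope; the distance
threshold d is the only interaction notion, swept for robustness). Its
spatial scaling is emergent, not dialled: with fixed clusters the area
saturates and βE comes out near 2 — reliably hypermetric, but not equal to
the summary-mode target 1.47. Sharp recovery tests therefore run on
summary mode; trajectory mode backs integration and qualitative checks. A
green recovery test establishes that the estimators are unbiased and
correctly scaled on data generated by the stated laws — not that real
colonies obey them.

## Known limitations

- At noise σ = 0.2 the sampling SD of the Cobb–Douglas elasticity
  estimate across 16-colony replicates is ≈ 0.13, because the regressor
  ln(A\*/I\*) spans only ≈ ±0.6 over the generated size range. A ±0.15
  acceptance band around αB therefore captures roughly 80%, not ≥ 90%, of
  replicates; the corresponding calibration test documents this and fails
  honestly. The estimator is unbiased (replicate mean ≈ 0.85).
- The mean-field bound πd² for the interaction area is computed as
  ≈ 113.1 mm² for d = 6 (π·36); a commonly quoted rounded figure of
  110 mm² is not reproduced.
- The q regression's t-based CI is mildly anticonservative on summary-mode
  data because the residuals of ⟨k⟩A²/N on N are dominated by integer
  rounding of A rather than Gaussian noise (measured coverage ≈ 0.90–0.94).
- Eq.-5-style metabolic predictions are undefined below
  N = (2E₀/q)^(1/(1−βE)) ≈ 9 workers, where the predicted active fraction
  reaches 1.
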