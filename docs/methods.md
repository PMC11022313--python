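# Methods

## The model

The package treats the habenula→raphe pathway as a static nonlinear map:
at every timepoint the raphe population response ŷ(t) is a function of the
instantaneous activity x(t) ∈ ℝ⁶ of the six habenula subtypes,

    h(t) = ReLU(x(t)ᵀ W₁ + b₁),   ŷ(t) = ReLU(h(t)·W₂ + b₂),

with W₁ ∈ ℝ^{6×2}, b₁ ∈ ℝ², W₂ ∈ ℝ², b₂ ∈ ℝ — 17 parameters. The two
hidden nodes stand for unobserved intermediates between habenula and raphe;
ReLU on the output enforces a non-negative response. Ablation of a subtype
is modelled as zeroing its input channel, which is how lesion experiments
enter the design: the same six characteristic responses serve all four
experimental conditions (unablated, D-ON, V-ON, V-OFF ablated) with the
condition's ablated channels set to zero. The model is deliberately static
and memoryless; all temporal structure in ŷ comes from temporal structure
in x. Non-uniqueness is inherent (hidden-node permutation, and a gauge
freedom between the output bias and the hidden drives), so interpretation
rests on quantities invariant to those symmetries (see below), not on raw
weights.

## Characteristic responses and the stacked design

Each subtype's characteristic response is built at 1 Hz and refined to a
0.01 s grid:

1. **Cycle averaging.** Habenula traces are averaged over the four aligned
   40 s light/dark cycles, then across the cells of a cluster. Raphe traces
   use only the first cycle (their later cycles are inconsistent) averaged
   across cells.
2. **Smoothing.** A centred rolling mean (default window 3 samples at 1 Hz;
   the window size is not prescribed anywhere, so it is exposed as config)
   is applied to the observed 40 s segment *before* padding. Smoothing the
   padded curve instead would smear the pad boundary and violate the exact-
   baseline invariant below.
3. **Padding and extension.** 20 s of constant baseline are prepended
   (unexcited period); the tail is extended 40 s by PCHIP interpolation
   through the last five observed 1 Hz samples plus one anchor at
   (t = 100 s, baseline). PCHIP is shape-preserving: a tail decaying toward
   baseline is extended monotonically with no overshoot beyond the knot
   range, and the curve ends exactly at baseline. The knot set is a design
   choice (the minimal one consistent with "decays back to baseline").
4. **Resampling.** Linear interpolation onto t = 0, 0.01, …, 99.00 s —
   9901 samples. The 9901-sample convention fixes the grid: it is the
   unique uniform 0.01 s grid of that length starting at 0, so the final
   second of the padded curve (99–100 s, by then at baseline) is not
   sampled. Values at the original 1 s knots are preserved exactly.

Invariants maintained: the first 20 s of every response equal its baseline
constant exactly; subsampling the fine grid at 1 s returns the 1 Hz curve.

Stacking the four condition blocks gives X ∈ ℝ^{39604×6} (column order
D-ON-T, D-OFF-T, D-OFF-P, V-ON-T, V-OFF-T, V-OFF-P; block order unablated,
D-ON, V-ON, V-OFF) and the raphe target y ∈ ℝ^{39604}. The raphe response
is translated additively so its baseline sits at +1 before fitting (the
translation is recorded and invertible): with a baseline of 0 after
z-scoring, an output ReLU could not represent sub-baseline excursions.
Habenula inputs are left on their z-scored scale.

## Preprocessing

Fixed order: median filter (width 3, reflected edges) → background
subtraction → least-squares polynomial detrend (order 2–5; when no order is
configured the order minimising the Gaussian BIC of the fit is chosen per
trace) → z-scoring (population SD; zero-variance traces raise a dedicated
error or are dropped with a log line) → centred rolling mean with shrinking
windows at the edges. All steps preserve trace length, so stimulus
alignment never shifts.

## Clustering and subtype naming

K-means under correlation distance is Lloyd iteration on row-standardised
traces: for zero-mean unit-variance vectors ‖u − v‖² = 2n(1 − r), so the
assignment step uses d = 1 − r directly and the update step re-standardises
the member mean. Initialisation is k-means++ under the same distance with
10 seeded restarts (best by within-cluster distance sum); an emptied
cluster is re-seeded from the farthest point. Seeded choices are keyed to
the sorted cell-id order, making the assignment invariant to input row
permutation. Correlation distance makes clustering invariant to positive
affine rescaling of any trace — appropriate for calcium data where gain is
not meaningful.

The optimal k is supported, not decided, by per-k diagnostics (k = 2…10:
within-cluster distance and mean silhouette under correlation distance);
the default configuration pins k = 3 per region, where the silhouette peaks
on data generated from three kernels.

Cluster→subtype naming was done by inspection in the original workflow; the
package formalises it. ON-index = mean(light windows) − mean(dark windows)
on each centroid; the largest strictly positive value names the ON-Tonic
cluster. For the remaining two, phasic-index = (peak within 5 s after light
offset) / (mean 10–20 s after offset), computed on the centroid shifted to
minimum 0 — z-scored centroids have negative baselines, and an unshifted
ratio can have a negative denominator and flip sign; the shift plus a small
epsilon floor makes the ratio well defined. Larger ratio → OFF-Phasic. Ties
within tolerance raise an explicit ambiguity error rather than guessing.
Thresholds are configurable.

## Fitting

Loss is MSE (RMSE is reported; the minimiser is the same). Full-batch Adam,
learning rate 1e-3, β = (0.9, 0.999), up to 20,000 epochs, subgradient 0 at
ReLU kinks. Weights start uniform(−0.5, 0.5); biases start at +0.1 to
reduce dead-ReLU initialisations. Ten random restarts run simultaneously as
one stacked computation (layer-1 weights concatenated column-wise so a
single matrix product serves all restarts); the best restart by final loss
is returned. A restart stops when its loss plateaus (relative improvement
< 1e-9 over 500 epochs) or falls below the convergence target
`target_loss` = 1e-6 MSE (RMSE 1e-3 on unit-scale targets, an order of
magnitude below any tolerance used downstream), and the whole fit stops
once the best restart has converged. Training runs in single precision
(ample for that target); returned parameters and all reported RMSEs are
double precision. Fits are deterministic given the seed. If every restart
ends predicting identically zero on a nonzero target, a diagnostic error is
raised instead of returning a dead network.

Problem sizes for the heavier analyses are the package's defaults: the
noise-free recovery fit uses the full budget (10 restarts, 20k-epoch cap);
the ten-seed noisy-recovery study uses 3 restarts × 3000 epochs per seed,
and cross-validation 2 restarts × 2000 epochs per fold — enough to reach
the noise floor of those targets, chosen so the complete validation suite
runs in minutes on a single core.

## Interpretation

**Contributions.** For each condition the package exports xᵢ(t)·W₁[i,j]
(input i → hidden j) and hⱼ(t)·W₂[j] (hidden j → output). These satisfy the
exact identities ReLU(Σᵢ contrib(i→Hj) + b₁[j]) = hⱼ and
ReLU(Σⱼ contrib(Hj→R) + b₂) = ŷ at every timepoint; ablated inputs
contribute exactly zero. Tables are exported at 1 s resolution for
readability.

**Sensitivity.** Each of the 17 parameters in turn is scaled by 25
log-spaced factors on [0.1, 10] (the grid density is a design choice; the
grid always contains 1.0). For each (parameter, factor) the forward pass is
re-run over all four conditions, both simulated and observed curves are
translated to a median of 1 over the first 10 s, and the RMSD is pooled
across conditions (per-condition values are also emitted). Normalising the
observed curve identically avoids penalising a pure offset; at factor 1.0
every parameter's entry equals the base model error by construction.

**Cross-validation.** Raphe cells are split per condition into ten
non-overlapping folds (seeded shuffle of the sorted cell ids; fold sizes
differ by at most one). For each fold the training-cell average builds the
target, the model is fitted, and RMSE is reported against both the training
and the held-out average. The habenula input matrix is shared across folds:
habenula and raphe were recorded in different fish, so there is no
one-to-one pairing to respect. Pointwise (row-wise) CV is deliberately not
offered — adjacent 0.01 s rows are near-duplicates, so a random row split
would validate nothing.

**Sign-pattern recovery.** Because of the bias/hidden-drive gauge, the raw
sign of a fitted hidden→output contribution is not identified: a model can
produce the same curve with a negative output bias and positive drive. The
identified, permutation-invariant signature of light-driven inhibition is
the *change* in net hidden→output contribution between the light window and
the unexcited baseline; the recovery tests assert that this drop is
negative, as in the generating circuit.

## The synthetic generator

Subtype kernels are saturating-exponential transients: during the driving
phase the trace relaxes toward baseline + amplitude with time constant
`rise_tau`, and decays back to baseline with `decay_tau`, evaluated in
closed form piecewise (exact at any sample rate). ON cells are driven by
light; OFF cells by darkness — for the whole dark window (tonic) or for a
2 s post-offset burst (phasic), which with a fast decay (≈2–2.5 s) gives
the sharp post-offset spike that returns >90 % of the way to baseline
within 10 s; tonic kernels (decay 25–30 s) do not. Default amplitudes are
order-1 fluorescence units with slightly different kinetics for
dorsal/ventral pairs so all six kernels are mutually distinguishable.

Habenula populations draw 1747 dorsal + 1227 ventral cells (700/600/447 and
500/400/327 per subtype — only the regional totals are constrained by the
experiment; the within-region split is a free choice) as
gain × kernel + iid Gaussian noise (default gain ∈ [0.8, 1.2], noise
sd 0.2 ≈ 20 % of kernel amplitude, a realistic single-cell SNR for
GCaMP at 1 Hz). Raphe populations apply a known ground-truth 6-2-1 circuit
to the kernels (ablated channels zeroed) and add iid noise (default
sd 0.05 on the unit-scale mean; 100 cells per condition — the experiment's
per-condition counts are unreported, and 100 keeps ten-fold CV well
defined). The default ground-truth weights are free configuration chosen so
the simulated raphe reproduces the four qualitative lesion phenotypes
(light-inhibited when intact; light-excited under D-ON ablation; nearly
unresponsive under V-ON ablation; dark-excited under V-OFF ablation), with
one net-inhibitory hidden node dominated by V-ON-Tonic input; they are not
estimates of the biological circuit.

What the generator does *not* emulate: imaging physics (photobleaching,
motion, shot noise), spiking→calcium indicator dynamics, cycle-to-cycle
adaptation, and correlated (population-level) noise. Passing recovery tests
therefore demonstrates that the pipeline's inference machinery is correct
and well-conditioned under the stated noise model — not that the biological
conclusions of any particular recording are right.

## Numerical choices and degenerate inputs

- Population (ddof 0) SD everywhere in standardisation, for determinism.
- Median filter edges by reflection; rolling means shrink their window at
  the edges; both preserve length.
- Zero-variance traces: explicit `DegenerateTraceError` (droppable with a
  log line); zero-variance inputs to correlation distance are an error.
- Identical-trace clustering inputs: diagnostics are flagged degenerate and
  the silhouette is NaN rather than fabricated.
- All seeds fan out from a single master seed via `SeedSequence`
  (per-stage, below 2³¹), so stages are independently reproducible.
- The sensitivity grid pools the four conditions into one number per cell
  (per-condition tables are also emitted).

## Known limitations

- The experiment's printed fit errors depend on the deposited recordings
  and an unreported target scaling, so they cannot be regenerated offline;
  the validation suite substitutes ground-truth-recovery properties on
  synthetic data at matched scales.
- Only a two-node hidden layer is supported by the validation suite (a
  one-node layer is known to be insufficient; wider layers are accepted by
  the class for exploration only).
- The cluster-naming indices formalise what was originally a manual
  judgement; on real data their thresholds may need adjustment, which is
  why they are configuration rather than constants.
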