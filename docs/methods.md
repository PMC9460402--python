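# Methods

This note documents the models, the numerical choices, and what the test
suite does and does not demonstrate about real rheometer data.

## Pipeline and assumptions

The package treats a gel as a thermorheologically simple, entangled,
polydisperse polymer liquid within its linear viscoelastic (LVE) window and
below its denaturation temperature T_d. Under those assumptions:

* moduli measured at different temperatures superpose onto one master curve
  by horizontal frequency shifts a_T (time–temperature superposition);
* the master curve determines a continuous relaxation spectrum H(λ);
* relaxation above the entanglement time is governed by reptation, so the
  double-reptation mixing rule maps H(λ) — via G(t) — to a weight-based
  molecular-weight distribution w(M).

Everything upstream of the mixing rule (QC, repair, TTS, spectrum) is generic
linear viscoelasticity; everything downstream inherits the reptation
assumptions: chains long enough to entangle (M ≫ Mₑ), negligible Rouse
contribution in the analyzed window, a single-exponential relaxation kernel,
and no explicit constraint-release or contour-length-fluctuation corrections.

## Parameters

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| `rel_tol` (LVE) | flatness tolerance of the plateau | – | 0.05 | the conventional ±5% LVE criterion |
| `drop_fraction` (T_d) | viscosity-drop threshold | – | 0.5 | midpoint of the denaturation collapse |
| tan δ smoothing window | moving average before peak pick | points | 3 | wider windows bias sharp transitions |
| `k_flag` | anomaly threshold in robust scale units | – | 4 | conservative: ≈4σ for log-normal noise |
| scale floor | lower bound on the robust residual scale | log units | 0.01 | ≈1% modulus; prevents self-flagging on exact data |
| `max_complexity` | Maxwell modes / poly degree ceiling | – | 4 | AICc chooses below it |
| extrapolation cap | crossover search beyond data | decades | 1 | unbounded extrapolation is unsafe; extrapolated roots are flagged |
| λ grid | spectrum support | s | data window ± 1 decade, 10 pts/decade | absorbs edge effects |
| regularization strengths | L-curve candidates | – | 10⁻⁶…10² (13 log-spaced) | spans under- to over-smoothed |
| `g_n` | plateau modulus G_N | Pa | required input (1000 in synthetic work) | kPa is the concentrated-collagen-gel scale; unknown a priori for a new material |
| `me` | entanglement mass Mₑ (= M_c/2) | g/mol | required input (5×10⁴ synthetic) | well below the ~7×10⁵ fiber scale so truncation at Mₑ is negligible |
| `beta` | mixing exponent β | – | 2 | double reptation |
| `kernel_exponent` α | λ_d ∝ M^α | – | 3.4 | standard reptation scaling |
| `kernel_prefactor` K | λ_d = K·M^α | s·(g/mol)^−α | 10⁻¹⁹ | places λ_d(6.8×10⁵ g/mol) ≈ 7 s, matching gel sweeps in the 10⁻²–10¹ rad/s window |

**K is a calibration, not a constant of nature.** K is exactly degenerate
with the mass scale: multiplying K by c is indistinguishable from shifting
every mass by c^(−1/α). Absolute M_w therefore depends entirely on anchoring
K (e.g. against one sample of known mass, or a literature monomer-friction
value); PDI and all shape information are unaffected. Synthetic validations
use the same K for generation and inversion, so they test the machinery, not
the calibration.

## Synthetic data: what it emulates, what it does not

The generator pushes a known w(M) through the mixing rule to G_r(t), converts
that to a dense discrete Maxwell spectrum (relative-error-weighted
nonnegative least squares, 8 modes/decade), evaluates G′/G″ on per-temperature
frequency windows shifted by planted a_T factors, and applies:

* multiplicative log-normal noise, independent per point and per modulus —
  the simplest model consistent with positive moduli spanning decades;
* a *near-T_d tail* phenotype: the last points of the hottest sweep replaced
  by a flat plateau at 1.4× the last clean value (an instrument-artifact
  jump-and-stall);
* a *gel-like* phenotype: a frequency-independent elastic floor added to G′
  so G′ ∥ G″ with G′ > G″ and no crossover.

Default conditions: single log-normal truth with M_w = 6.8×10⁵ g/mol and
PDI = 2.0, temperatures 23/28/32/36 °C with log₁₀ a_T = (+1, 0, −0.75, −1.5)
about the 28 °C reference, T_d = 38.15 °C, LVE strain boundary 0.1, noise
σ = 0.02, sweeps of 3 decades at 8 points/decade.

Not emulated: correlated noise, drift, inertia and compliance artifacts,
slip, phase separation, water loss, or any real denaturation kinetics. A
passing suite therefore shows the *inversion chain* is correct and stable
under idealized noise — not that a specific instrument's artifacts are
handled. One integer seed controls all randomness.

## Numerical choices

* **Fits operate on logarithms** of moduli vs log ω, weighting every decade
  equally; residual scales are median-absolute-deviation based.
* **Anomaly flagging** grows a trusted prefix from the low-frequency end
  (tail artifacts live at high frequency near T_d). The prefix starts at half
  the sweep — enough to overdetermine any candidate model — and each new point
  is tested against the one-step-ahead prediction at threshold k× the robust
  scale. A point that fails at the frontier of a clean run gets one rescue: a
  cold-started refit including it; if the refit absorbs it to within
  tolerance it was an emerging relaxation mode, not an artifact. Once a point
  is flagged the run is broken and later failures are flagged outright, so a
  contiguous corrupted tail cannot be re-absorbed piecewise.
* **Model complexity** is chosen by small-sample-corrected AIC computed over
  *all* points, with each flagged point charged its threshold residual —
  otherwise a too-simple model that flags the informative tail would win on
  its easier retained subset.
* **Crossover location**: sign-change scan on 2000 log-spaced points of
  log G′ − log G″ over the data window ± the search decades, refined by
  Brent's method; among multiple roots the lowest-frequency root where
  G′ − G″ crosses from below (the physically ordered flow-to-rubber
  transition) wins, and the root count is reported.
* **TTS registration** minimizes the summed squared difference of log G′ and
  log G″ of *fitted* curves over the overlap window (raw points need not share
  abscissae): coarse scan over ±4 decades, then bounded scalar minimization.
  Pairs whose best registration still disagrees by >0.7 decades rms are
  rejected as non-overlapping. Vertical shifts are off by default and opt-in;
  horizontal-only is the parsimonious default for a gel in a 17 °C span.
  The default reference temperature is the sweep with most retained points.
* **Spectrum inversion** solves for h = ln H (positivity by construction) by
  Gauss–Newton least squares on log-moduli residuals with a second-difference
  penalty √α·D₂h, warm-started across the strength ladder from a
  relative-error NNLS initialization. The L-curve corner is the candidate
  minimizing log ρ + log η (closest point to the utopia corner): with noisy
  data the penalty norm blows up at small α and the criterion lands on the
  bend; with effectively noiseless data there is no bend and it degrades
  gracefully to the smallest-residual solution, which the diagnostics flag.
  Spectral mass outside the reciprocal data window is reported as unreliable.
* **Mixing-rule quadrature** is trapezoid on log-spaced grids (the dM/M
  measure is dln M). Inside `invert_mwd` the component mass per grid cell is
  integrated with the normal CDF, so components much narrower than the grid
  spacing remain exactly representable — a density sampled at nodes would
  quantize both the mass and the width. The inversion grid uses 30
  points/decade because the kernel time ratio between adjacent mass nodes is
  10^(α/ppd) and the tail of log G_r is sensitive to it.
* **Multistart** for the w(M) fit is a deterministic grid of initializations
  (location offsets × widths around a mid-decay mass estimate); no random
  starts, so inversion is reproducible without seeds. Fits with best rms
  above 0.5 log units raise instead of returning garbage.
* **Degenerate inputs**: zero moduli invert to H ≡ 0; boundary tan δ maxima
  are rejected as unbracketed rather than reported; zero within-group ANOVA
  variance with equal means returns the p = 1 convention, flagged;
  monodisperse mixing collapses algebraically to G_N·F(M₀,t) for any β and is
  asserted as such.
* Sub-entanglement (Rouse) times t < τₑ = K·Mₑ^α are discarded before the
  w(M) fit; the retained window keeps its absolute Pa scale, since an
  inverted spectrum reproduces absolute moduli and the analyzed signal is
  treated as pure reptation.

## Problem sizes used in the tests

Synthetic sweeps use 3-decade windows at 8 points/decade (25 points per
temperature, 3–4 temperatures); spectrum-inversion checks use 6-decade master
curves (61 points) on 10 points/decade λ grids; round-trip studies use 50
noise seeds (σ = 0.03 on G_r) and the flagging/crossover studies 100 seeds
(σ = 0.05 on moduli); the ANOVA type-I calibration uses 10⁴ simulated
three-group datasets. These sizes put every Monte-Carlo assertion comfortably
past its pass threshold while keeping the full suite to a few minutes.

## Known limitations

* Absolute M_w requires an external anchor for K (above); cross-sample
  *comparisons* with a common K are meaningful regardless.
* w(M) is restricted to ≤3 log-normal components; free-form inversion is
  deliberately excluded as unidentifiable at realistic data quality, so
  sharp or exotic distribution shapes are summarized, not resolved.
* The double-reptation kernel ignores Rouse modes, constraint release and
  contour-length fluctuations; for weakly entangled chains (M ≲ 10 Mₑ) the
  inferred masses are systematically biased.
* TTS assumes thermorheological simplicity; near T_d the material changes
  structurally and shifts stop being meaningful. The crossover-monotonicity
  report exists to catch exactly this.
* The LVE detector assumes the sweep actually reaches the plateau; a sweep
  entirely in the nonlinear regime yields a "no LVE region" diagnostic, not a
  guess.
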