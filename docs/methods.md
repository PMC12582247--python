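# Methods

`stablegait` infers the structure of foot placement control from planar
kinematics of walking animals. This note records the model the package
implements, the estimators and their numerical details, what the synthetic
walker does and does not emulate, and the design decisions taken where the
problem left room for choice.

## The control model

Walking is modeled as the output of a hierarchical two-module controller.

**Feedforward module.** The cycle-averaged movement speed v̂ sets the
nominal gait geometry and timing per leg j:

- step length and step width: linear laws
  f_j^{x,y}(v̂) = β₀ + β₁ v̂,
- cycle duration: exponential decay
  f_j^t(v̂) = β₀ exp(−β₁ (v̂ − β₂)) + β₃,
- the full nominal pattern Q*_v̂(φ): for every gait fraction φ and every
  body-state channel, a linear regression on v̂. Body-state errors are
  deviations from this *velocity-conditioned* pattern, not from the average
  gait — this is what lets velocity-dependent and error-dependent control
  coexist in one model.

Note that length, duration, and speed are not independent: any walker
satisfies v̂ · T = 2L (per cycle, two steps of length L). Fitted forms for
any two of them induce the third; the linear length law and exponential
duration law are compatible descriptive fits of this one constrained
relationship over ordinary speed ranges.

**Feedback module.** Deviations of the body state from the nominal pattern,
ΔQ(φ) = Q(φ) − Q*_v̂(φ), map linearly onto the deviation of the next foot
placement:

ΔP ≈ γ₀ + Σᵢ γᵢ ΔQᵢ(φ),

fitted by multiple OLS at every φ, with explained variance
R² = 1 − Σr²/ΣΔP² (in-sample, uncentered residual form; deviations are
zero-mean regression residuals by construction). The control signature is
this model outperforming a *baseline* regression on the swinging foot's own
kinematic deviations ΔQ̃(φ) well before swing onset; near φ = 1 the baseline
wins for purely geometric reasons (the foot converges on its placement).
The per-individual maximum of R²_body − R²_baseline across φ is the
*control magnitude*.

**Closed loop.** On the gait-cycle clock the lateral body error evolves as

d_n = G e_n + ε_n,   e_{n+1} = a e_n − c d_n + η_n,   c = 1,

so the cycle-to-cycle coefficient is λ = a − G. Three observable
consequences anchor the whole pipeline:

1. the Poincaré return map of cycle-sampled deviations has spectral radius
   |λ| (stable gait for |λ| < 1);
2. lateral placement deviations have autocorrelation r(N) ∝ λ^{N−1}
   (closed-loop algebra gives r(1) = (G²λσ_e² − Gσ_ε²)/Var d — the
   correction subtracts the previous step's execution noise, a negative
   MA(1) term that lowers the amplitude but not the decay rate);
3. the decay time constant is τ = −1/ln|λ| cycles.

**Error reduction.** Per contact, the change in mean |lateral body error|
from the half cycle before to the half cycle after, regressed on |ΔP_y|.
Absolute errors are used (a "reduction" must be sign-free to regress on a
magnitude). The stabilization hypothesis is directional — larger
corrections, larger reductions — so the one-sided p-value for a positive
slope is reported alongside the two-sided one. With c = 1 even a gain-free
walker shows a slight *negative* association (execution noise perturbs the
body), which the directional test correctly ignores.

## Processing pipeline

1. **Straight-bout selection.** Heading is the direction of the body
   velocity smoothed over 0.25 s; maximal segments whose heading range
   stays within 30° are kept, segments shorter than three nominal cycles
   dropped.
2. **Heading alignment.** One rigid rotation per bout brings the mean
   travel direction to +x; inter-marker distances are preserved exactly.
3. **Contact detection.** Default "extrema" method: the *signed* fore-aft
   displacement of the foot relative to the body is low-pass filtered
   (cutoff 5× the cycle frequency); touchdown candidates are maxima,
   liftoff candidates minima (an unsigned distance would make both
   transitions maxima), with prominence ≥ 10 % of the displacement range
   and spacing ≥ half the median cycle. Because a smooth swing ends with
   the foot's speed crossing the body's *before* it stops, each coarse
   extremum is snapped to the first/last frame at which the foot is
   effectively stationary (per-frame displacement < 30 % of the body's).
   The alternative "velocity_threshold" method marks stance wherever foot
   speed stays below a fraction (default 0.25) of the median body speed
   for a minimum dwell. Contact location P is the mean foot position over
   stance.
4. **Segmentation.** Cycles are consecutive contact initiations of the same
   leg (termination-based segmentation available behind a flag); v̂ is the
   mean fore-aft body velocity over the cycle; duration outliers (> 3×
   median) and non-forward cycles are dropped and logged.
5. **Phase normalization.** Positions and velocities are linearly
   interpolated onto M uniform gait fractions (M defaults to ~the average
   frames per cycle; 50 for the built-in profiles). Velocities are computed
   *before* interpolation as the slope of a centered local linear fit
   (Savitzky–Golay, order 1, ±5 frames): exact for locally linear motion
   and far less noise-amplifying than an endpoint difference. A half-cycle
   extension past the predicted contact is attached when frames allow, for
   the error-reduction analysis.
6. **Spatial normalization.** All positions and the placement are expressed
   relative to the last contact of the front limb of the opposite support
   group; step length is p_x, step width |p_y|. Signed p_y deviations feed
   the feedback analyses (the sign carries the correction direction). The
   extension window is referenced to the placed contact itself — the body's
   new support anchor.

## Statistics

- **Chatterjee's ξ** is implemented from first principles: sort by x with
  seeded random tie-breaks; with distinct y,
  ξ = 1 − 3Σ|r_{i+1} − r_i|/(n² − 1); with ties the mid-count rank form
  with the corrected denominator. The independence test is right-tailed
  from √n ξ → N(0, 2/5); a seeded permutation option exists for small n.
  The implementation agrees with `scipy.stats.chatterjeexi` to machine
  precision (cross-checked in the test suite, never used as the
  implementation).
- **Group comparisons** run through one gateway: Shapiro–Wilk gates
  parametric (t tests, ANOVA) versus nonparametric paths (Wilcoxon
  signed-rank, Mann–Whitney, Kruskal–Wallis with a locally implemented
  Dunn's post hoc, Benjamini–Hochberg corrected). Cohen's d accompanies
  every two-group comparison.
- **Return map.** K is fitted forward in time (next cycle's deviation as
  response), so eigenvalue moduli below 1 mean contraction; the literal
  backward map is available behind a flag and is *not* inverted (fitted
  forward and backward maps are not reciprocal under noise). Least-squares
  AR coefficients are biased low in finite samples
  (Kendall/Marriott–Pope, ≈ −(1+3λ)/n); `spectral_radius_corrected`
  applies the scalar first-order correction, appropriate when one real
  eigenvalue dominates.
- **Timescale.** Pearson correlations at integer lags, pairs never
  crossing bout boundaries or cycle gaps; r(N) = r₀ exp(−N/τ) fitted by
  bounded nonlinear least squares (log-slope initialization); CIs by
  resampling whole bouts (default 10,000 draws, 90 % central interval).
  Non-positive r(1) is reported as τ = 0 with a flag (no measurable
  persistence).
- **KS comparison of R² profiles** is one-sided, asking whether the
  body-state R² distribution lies above the baseline's: the direction in
  which feedback control manifests, and the only direction in which the
  late-phase geometric advantage of the baseline cannot masquerade as a
  signature.

## The synthetic walker

The generator is a kinematic rendering of the control model above — not a
mechanical simulation. Per cycle it draws a commanded speed
(truncated normal), sets L from the length law, induces T = 2L/v̂, and
advances the body at exactly v̂, so the measured speed equals the commanded
one and both feedforward laws are recovered by construction. Limb groups
alternate in antiphase (2×1 biped, 2×2 trot, 2×3 tripod); fore-aft leg
stations are fixed morphological constants; lateral placements form a
relative chain — each contact is positioned with respect to the previous
opposite-group front contact, exactly the reference the pipeline subtracts,
so the lateral lane drifts as a random walk the way real overground walking
does.

The lateral error state is step-discrete; its rendered trace is an
event-triggered zero-order hold (it changes when a corrective contact
lands). Every placement's correction reads the error as sensed at the
instant its reference limb touched down (the pre-exchange state). Two
consequences worth knowing:

- for the anchor front limb the regression estimand at late phases equals
  the generative gain G exactly; for the mid-cycle group the fitted gain is
  attenuated by one half-cycle of error decay (the rendered state has moved
  on since sensing) — analyses that quantify gains therefore use the front
  limb;
- feet are constant during stance and follow a cosine ease during swing
  (zero landing velocity), which is why the displacement extremum slightly
  leads touchdown and the detector snaps to foot stationarity.

Observation noise is added per frame; contact-timing jitter perturbs
touchdowns; execution noise perturbs placements; body noise drives the
error chain. Direction-specific (medial/lateral) gains and per-leg gain
scalings are available to generate modular control structures.

**Defaults** (the simulated study conditions; human-scale units):
v_mean = 1.2 m/s, v_sd = 0.2 m/s, length β = (0.2, 0.4), width
β = (0.12, 0) (step width velocity-independent), duty = 0.6, a = 0.9,
G = 0.4 (so λ = 0.5, τ = 1.44 cycles), σ_body = 12 mm/cycle,
σ_foot = 4 mm, σ_obs = 0.5 mm, σ_time = 10 ms, 50 Hz, M = 50. These give
swing-onset lateral R² ≈ 0.6 and lag-1 placement correlations ≈ 0.15,
comparable to published human treadmill values.

**What passing tests do and do not show.** The generator has one lateral
error channel, no mechanics (no masses, forces, or impacts), straight
heading, a single body marker per built-in profile, and stationary
parameters. Recovery of (β, G, λ, τ) here demonstrates that the estimators
are consistent and the pipeline is internally coherent — not that real
animals satisfy the model, nor that the pipeline is robust to pose-tracker
artifacts, turning bouts beyond the straightness filter, or non-stationary
behavior.

## Numerical choices and degenerate inputs

- Rank-deficient regressions fall back to a tiny ridge
  (10⁻⁸ × largest squared singular value) and are flagged.
- The exponential duration fit uses three starts (offset from the
  high-speed quartile, amplitude from the range, rate from the log-slope),
  bounded so the exponent stays finite; β₀ and β₂ trade off through
  β₀e^{β₁β₂}, so the identifiable reduced form (decay amplitude at the
  median speed) is reported alongside the raw parameters. Non-convergence
  flags the fit and duration residuals fall back to the median.
- Tracking gaps up to 5 % per marker are linearly interpolated and logged;
  larger losses reject the bout.
- Constant-y inputs give ξ = 0 with a flag; zero-variance effect sizes and
  degenerate speed ranges raise errors rather than returning numbers.
- Ties in x for ξ are broken at random with a per-call seed, so results
  are reproducible.

## Known limitations

- Sample autocorrelations of short sequences carry the classic negative
  finite-sample bias (≈ −(1 + 2Σρ)/n per lag). At ~300 cycles per bout
  this depresses the lag profile's tail and with it the τ *point*
  estimate by roughly 10–20 % at the default noise levels; the bootstrap
  CI expresses the real uncertainty and is the reported inferential
  object.
- At ~300 cycles the realized cycle-to-cycle coefficient of a single
  cohort has irreducible sampling spread (sd ≈ √((1−λ²)/n) ≈ 0.05 per
  individual), so cohort-level point estimates of ρ and τ scatter around
  the generative values; cross-cohort pooling is how the package's own
  acceptance checks frame the recovery claim.
- In-sample R² inflates by ≈ N/(n−1) under independence; model
  comparisons are always against the equally inflated baseline, never
  against zero. A cross-validated variant exists behind a flag but the
  default matches the closed-form in-sample estimator.
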