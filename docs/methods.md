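# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `fretpaint`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model

A surface-immobilized donor-labeled construct with `n_gtracts` binding
sites is probed by a diffusing acceptor-labeled strand.  The instantaneous
apparent FRET is

- unbound: `E_raw(t) = e_do` — the donor-only baseline caused by donor
  emission leaking into the acceptor channel;
- bound at site i: `E_raw(t) = e_do + (1 − e_do) · E_site[i]`.

This additive-baseline form makes the donor-only correction
`E' = (E − e_do)/(1 − e_do)` exact: it maps the unbound level to 0 and
leaves `E = 1` fixed.  A full gamma/crosstalk matrix is deliberately not
modeled — the analysis corrects only the donor-only offset, and the
simulator generates only what the analysis corrects.

Camera frames integrate the instantaneous signal: the per-frame acceptor
count is `total_intensity · ⟨E_raw⟩_frame` (donor complementary), plus
i.i.d. Gaussian noise per channel.  Sub-frame events are therefore
attenuated exactly as in a real recording, which is the dominant source of
censoring for the fast dwell component.

## Binding kinetics (simulator)

Binding is an alternating-renewal process: unbound gaps are
Exponential(1/k_on), each event draws its site from `site_weights` and its
dwell from the mixture `p_short · Exp(t_short) + (1 − p_short) · Exp(t_long)`.
At most one probe is bound at a time (the assay's imager concentration is
chosen so events are isolated); overlapping events are never generated.
Donor photobleaching is a single exponential hazard that drops both
channels to background; no blinking and no acceptor photophysics.

Defaults are the published operating point of the assay: 100 ms frames,
2000-frame movies, `e_do = 0.1379` (the value implied by the printed
raw/corrected threshold pair 0.25 → 0.13), dwell mixture 0.7 s / 5.0 s at
p = 0.5 (inside the reported fast ≈ 0.7 ± 0.1 s and slow 4.0–8.6 s ranges),
`k_on = 3.2e-3 s⁻¹` (the 4-repeat construct's event rate scale), bleach
hazard 1/150 s⁻¹ (a realistic Cy3 survival under TIR excitation, chosen
once as a realistic value), total intensity 1000 with
per-channel noise SD 35, giving a FRET standard deviation of ≈ 0.03–0.05
depending on level.  Site FRET levels default to an even spread from 0.9
(donor-proximal) down to 0.2; site weights default to uniform, because
positional structure is a *finding*, not an assumption — scenarios inject
it explicitly.

`length_accessibility_profile(n, r, c) = n · r · (1 − c)^max(n−4, 0)` is a
scenario generator for length-dependent compaction (total rate grows with
site count, per-site rate shrinks), not a mechanistic claim.

RNG discipline: a single master seed; molecule *i* uses the *i*-th spawned
child of `numpy.random.SeedSequence(seed)`, with a fixed draw order
(bleach, then gap/site/dwell triplets, then donor noise, then acceptor
noise).  Datasets are bit-reproducible for fixed (seed, n_molecules).

### What the simulator does not emulate

No spectral crosstalk beyond the additive baseline, no gamma factor, no
donor/acceptor blinking, no intensity drift or stage drift, no
heterogeneity of k_on across molecules of a construct (the per-molecule
event-count dispersion of real data is unknown), and no mechanistic model
of G-quadruplex folding.  A green recovery test therefore establishes that
the estimators are correct for this stated world — not that real traces
satisfy the model.

## Step detection

`best_single_step` scans all split positions of a segment and returns the
two-mean split minimizing the residual sum of squares, computed in O(L)
with prefix sums; ties break to the earliest index for determinism.
`fit_steps` applies this greedily (always refining the segment with the
largest available gain) and stops by one of two rules:

- **threshold** (pipeline default): overfit forward to the step cap, then
  backward-eliminate breakpoints whose removal costs less than
  `gain_threshold · σ̂²`, where σ̂² is the noise variance estimated from the
  median squared first difference divided by `2 · 0.4549` (the median of a
  χ²₁ variable — without this factor the estimator understates σ² by ~2.2×).
  The default `gain_threshold = 2 ln L` is a BIC-style penalty for one
  extra mean parameter; measured on pure Gaussian noise it leaves ~99% of
  traces stepless.  Elimination considers breakpoints singly *and in
  adjacent pairs* (against twice the penalty): a noise excursion buys two
  cheap breakpoints that are each expensive to remove alone but cheap to
  remove together, while a genuine event plateau is expensive either way.
  The forward-overfit/backward-prune structure matters because pure greedy
  acceptance misses isolated short events in long traces — the event's
  first boundary alone explains almost no variance (measured: ~13%
  underestimate of binding frequency on realistic traces, dropping to
  0.1–2.6% with elimination).
- **counter_fit**: after the greedy pass, a counter fit places steps at
  the midpoints of the accepted plateaus; the accepted step count
  maximizes the S-curve `S(k) = RSS(counter) / RSS(fit)`, which diverges
  at the true count for clean steps and stays near 1 on stepless data.
  A floor `min_s_ratio = 1.5` reports traces with a flat S-curve as
  stepless.  This mode suits step-rich traces; for event-sparse FRET
  traces the S-curve argmax is ill-defined, hence the pipeline default.

Levels are refit as segment means after breakpoint placement; `min_segment`
defaults to 2 frames (events need 4 frames downstream, so shorter plateaus
are never meaningful).

## Event calling and observation time

The analysis is run on corrected FRET.  Because the correction is affine,
the pipeline step-fits the raw FRET once and transforms the fitted levels,
which is equivalent to refitting the corrected trace.  Events are maximal
runs of consecutive segments with level > 0.13 spanning ≥ 4 frames, with
`τ = (n_frames − 1) · frame_time` — the only convention under which "4
consecutive points" and "τ ≥ 300 ms" agree at 100 ms/frame.  Adjacent
above-threshold segments merge into one event (a mid-event level shift is
probe repositioning, not two bindings); merged events carry a flag.
Events truncated by the observation boundary are kept if they already
satisfy the 4-frame rule and are flagged censored; no censoring correction
is applied.

Photobleaching is detected as the first run of ≥ 10 frames whose total
intensity stays below background + 3 robust SD and whose remainder stays
dark in the median (tolerating rare noise excursions); both parameters are
config-exposed, as no standard values exist for them.  Per-channel
backgrounds use the post-bleach frames when a bleach exists — the cleanest
background sample a trace offers.  Without a bleach the backgrounds are
taken as zero, assuming upstream movie processing already subtracted the
camera/dark level: a channel-wise "robust minimum" would be wrong here,
because both channels carry anticorrelated *signal* at all times, so the
5th percentile of, say, the donor channel is the bound-state level, not
background.

The donor-only peak is estimated from molecules with no events under a
provisional raw-scale screen (threshold 0.25, the pre-correction
equivalent of 0.13); with fewer than 10 such molecules it falls back to
pooling all below-threshold frames.  A Gaussian is fit to the pooled
histogram; for noiseless (point-mass) pools the peak is returned directly.

## Dwell-time kinetics

Dwell histograms start at the minimum accepted dwell (0.3 s) with a
0.3 s bin width (one dwell quantum per the 4-frame rule).  Fits use the decay forms
`y = y₀ + A₁ e^(−(x−x₀)/t₁)` and
`y = y₀ + A₁ e^(−(x−x₀)/t₁) + A₂ e^(−(x−x₀)/t₂)` with `x₀` fixed at the
first bin's left edge, all parameters bounded ≥ 0, multistart
initialization (head/tail log-slopes plus spread-out variants, and for the
double model the single-model solution with vanishing second amplitude —
which also guarantees the nested-model residual ordering).  Components are
reported fast-first (t₁ < t₂).

The least-squares objective is **iteratively reweighted (Pearson)
chi-square** by default: bin variances are taken from the fitted model,
`σᵢ² = max(fit(xᵢ), 1)`, refit twice.  This choice was measured, not
assumed: on 600-dwell mixtures, unweighted least squares over-trusts empty
tail bins and data-weighted (√count) least squares downweights upward
fluctuations; both bias t₂ low in combination with the free offset and
recover t₁ within ±0.2 s only ~80–89% of the time, while Pearson weighting
is unbiased (mean recovery 0.70 s / 5.0 s) and succeeds ~94–96% of the
time.  Unweighted ("none") and data-weighted ("data") modes remain
available for comparison with analyses that used them.

Model comparison uses
`F = [(RSS_s − RSS_d)/(dof_s − dof_d)] / (RSS_d/dof_d)` with
`p = SF_F(F; dof_s − dof_d, dof_d)`; a perfect double fit reports F = ∞,
p = 0.  Type-I error at the p < 0.001 level was measured at ~2–5% per the
test suite's single-exponential null simulation — conservative behavior
driven by the binning.

No correction is applied for frame-integration censoring of sub-frame
events; this biases the fast component's amplitude (an acknowledged limitation of histogram-based dwell fitting).

## Binding frequencies and bootstrap

`f_ave = ΣN_B / ΣT_obs` over all screened molecules, zero-event molecules
included.  Uncertainty: 20 000 bootstrap sets, each resampling N_DNA
molecules with replacement — the (event count, observation time) pair
jointly — and computing its own events/time ratio; the resulting frequency
distribution is histogrammed (Freedman–Diaconis) and fit with a Gaussian
whose peak and SD are reported as f_peak and f_sigma, alongside the sample
mean/SD and the 2.5–97.5 percentile interval (the natural executable
reading of reporting "with a 95% confidence level").  Records are
canonically sorted before resampling, so the seeded distribution is
independent of input order.  The long-dwell filter (τ > 2t₁, removing
candidate partial-hybridization events) recomputes all statistics with
observation times unchanged.

## Topography

Events with mean corrected FRET in [0, 1] are classified into five
segments of width 0.2 (half-open bins, last bin closed).  Per-segment
dwell statistics use mean ± SEM; per-segment frequencies share the
construct's total observation time, so they sum to f_ave exactly, with
uncertainties from the same molecule-level bootstrap restricted to
segment counts.  Dwell comparisons across segments use one-way ANOVA;
frequency comparisons use Welch's t for every unordered pair (unequal
segment sizes and variances), reported both raw and Bonferroni-adjusted, so either convention can be read off.  The
contour view bins events jointly on (FRET, dwell) within a 1–7 s dwell
window by default.

## Numerical conventions

- Frames index from 0; frame *i* spans time [i·Δ, (i+1)·Δ).
- Corrected FRET is clipped to [−0.2, 1] for reporting (negatives stay
  visible); population histograms live on [0, 1] with 0.02 bins.
- Invalid frames (total intensity below a positivity floor, default 5% of
  the 95th-percentile total) are NaN in FRET traces and interpolated over
  before step fitting so breakpoint indices stay frame-aligned.
- Step-split ties break to the earliest index; exact-zero gains terminate
  fitting via an absolute epsilon scaled to the trace's total variance, so
  noiseless traces recover exactly.
- All stochastic estimators take explicit integer seeds and are
  deterministic given them.

## Known limitations

- Events shorter than ~4 frames are invisible by design (the τ ≥ 300 ms
  rule); recovered total frequencies therefore undercount the true event
  rate by the short-dwell mass, and dwell distributions are truncated.
  Detection across the 0.3–0.6 s band is phase-dependent: an event's
  placement relative to frame boundaries decides whether it yields 4
  above-threshold frames.
- Step-fit levels, not raw frames, are thresholded (consistent with
  fitting-based event counting); very brief excursions within a long event
  do not split it.
- The repeated-measures structure of per-segment frequency testing treats
  molecules as subjects and segments as the repeated factor via
  per-molecule segment rates; the source's exact test structure is not
  stated.
- The bootstrap treats molecules as exchangeable; field-of-view or
  channel-level batch effects are outside the model.
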