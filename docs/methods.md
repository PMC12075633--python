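# Methods

## Generative model

A transporter complex is modeled as a two-state continuous-time Markov
chain: *associated* (S-component bound to the ATPase module, FRET
efficiency E_assoc = 0.60) and *dissociated* (subunits apart in the
membrane, E_diss = 0.08). Waiting times are exponential; the association
rate k_assoc is ATP-independent (default 0.05 s⁻¹, a 20 s mean dissociated
dwell), while the dissociation rate follows a single-site rectangular
hyperbola in the ATP concentration,

    k_diss([ATP]) = k_diss_max · [ATP] / (K_ATP + [ATP]),

with k_diss_max = 0.125 s⁻¹ (8 s mean associated dwell at saturation) and
K_ATP = 380 µM. The Hill exponent is fixed at 1: dissociation is driven by
ATP hydrolysis at a single catalytic site pair, and no cooperativity is
modeled. Molecules start associated unless `pre_equilibrated` draws the
initial state from the stationary distribution; `t_activation` delays the
onset of dissociation (ATP arriving in the flow cell).

The observable layer reproduces a two-channel TIRF recording with
alternating laser excitation: 500 frames of 200 ms (25 red / 450 green /
25 red, i.e. 5 s direct acceptor excitation at both ends of a 90 s
donor-excitation window). Per green frame the hidden state is averaged at
sub-frame resolution (occupancy-weighted E), so frames containing a
transition carry intermediate efficiencies, as a camera integrates.
Donor and FRET-acceptor counts derive from a constant total emission rate
(`total_intensity` = 500 counts/frame); the acceptor channel additionally
receives donor crosstalk (leakage 0.10) and direct acceptor excitation
(0.05 of total). Red segments carry the acceptor-excitation signal I_AA.
Photobleaching is single-step and irreversible per dye; blinking is not
modeled (the recordings emulate Trolox-stabilized conditions). Noise is
additive Gaussian per channel (default sd 50, per-channel SNR ≈ 5);
EMCCD excess noise is folded into this single parameter because no
downstream step uses photon statistics of camera frames. Background is
constant-mean per channel (50 counts), with an optional linear drift flag;
the stored background series are the true means, standing in for the
well-averaged annulus estimates of real extractions.

Population structure mirrors a liposome reconstitution: a responsive
fraction of 0.5 (membrane orientation — only complexes exposing their
ATPase subunits to the added ATP can respond), an inactive fraction of
0.2, and donor-only/acceptor-only spot fractions of 0.1 each. All
simulation entry points require an explicit seed; there is no global
random state.

What the generator does **not** emulate: liposome geometry and curvature,
vesicle leakage, anisotropy, triplet blinking, spectral drift,
stage drift, or detection-factor (γ) imbalance — γ is fixed at 1, so all
efficiencies are proximity ratios, which is also how the pipeline reports
them. Tests passing on these synthetics therefore validate the estimators
under the stated noise model, not robustness to every instrumental
artefact of real data.

## Trace processing

Order of operations: 3-frame running median on signals and 7-frame on
background series (centered, windows shrink at edges) → background
subtraction → leakage correction (lk·I_D′) → direct-excitation correction
(dir·⟨I_AA−bg⟩ using the trace's own red segments, which exist precisely to
quantify the acceptor) → E = I_A′/(γI_D′+I_A′). E values are clamped to
[−0.2, 1.2] for reporting; frames with ~zero total intensity are flagged
undefined. Correction factors come from single-dye calibration
populations: lk as the median ⟨I_A−bg⟩/⟨I_D−bg⟩ of donor-only traces, dir
as the median green-to-red acceptor ratio of acceptor-only traces.

Single-pair selection uses the mean background-subtracted I_AA in both red
segments (acceptor present, single, unbleached; a tail/head ratio below
0.5 is rejected as acceptor bleaching) and the mean corrected total green
intensity in the first and last 10 s (single donor, no donor bleach).
Windows default to mean ± 2.5 SD of the calibration populations; the SD is
floored at 2 % of the mean so that noiseless calibrations do not collapse
the window. Every rejection carries a reason code.

The Chung–Kennedy filter is the classical two-predictor form: each point
is a blend of the mean of the K points before it and the K points after it
(K = M = 10), weighted by the inverse p-th power (p = 1) of each
predictor's mean squared prediction error over a trailing/leading
comparison window of the same length; a variance floor of 1e−12 keeps
noiseless segments finite. Edges use truncated windows. The filter is the
identity on constants, preserves noiseless steps to within 2 frames, and
reduces Gaussian noise roughly 3–4-fold.

## Classification

The anticorrelation statistic is

    c = (1/N) Σ_t (I_D−⟨I_D⟩)(I_A−⟨I_A⟩) / ⟨I_D+I_A⟩²,

computed over the green segment on corrected, Chung–Kennedy-filtered
channels. For a two-level trace spending a fraction f of its time
dissociated, c = −f(1−f)·(ΔI)²/⟨T⟩² — it is scale-invariant (numerator and
denominator both scale as s²), which makes the −0.01 threshold
dimensionless; it is *not* invariant under adding a common offset (the
denominator changes), so background subtraction must precede it. Traces
with c < −0.01 (strict) are dynamic; ties and everything else are static,
split at median E = 0.4 into high/low. Under the default SNR the static
null keeps |c| < 0.01 with probability > 0.99, and the benchmark mixture
(30 % static-high, 20 % static-low, 50 % dynamic with 1–5 transitions)
is labeled with ~95 % ground-truth concordance; the residual errors are
dynamic traces whose excursions occupy so little of the window that
f(1−f) falls below the threshold.

Histograms pool per-frame filtered E over selected traces in 0.04 bins
spanning [−0.2, 1.2] (wide enough that corrected-E excursions are visible
rather than clipped). The dissociated/associated population ratio is read
from a two-Gaussian fit with centers initialized at 0.08 and 0.60 and
bounded to ±0.1 of the initialization; the ratio uses peak amplitudes
(areas are available as an option). A population whose fitted amplitude
falls below 1 % of the total is reported as absent (ratio 0 or ∞ with a
flag), never as an exception.

## Change-point detection and dwell-time estimation

Transitions are found by recursive binary segmentation with three
numerical safeguards, each forced by measured failure modes of the naive
two-sample t split:

1. **Step-robust noise scale.** The long-run variance is estimated once
   per trace from differences of adjacent 10-frame block means via the
   median absolute deviation — insensitive both to the autocorrelation
   that median/CK filtering leaves in the noise and to the level changes
   being detected (residual-based estimates are inflated by unmodeled
   steps and destroy sensitivity in multi-transition traces).
2. **Local multi-scale split scores.** A candidate split is scored by the
   mean difference of flanking windows over a geometric ladder of window
   sizes (3…20 frames). Global segment-half means dilute a short dwell in
   a long segment below detectability; local windows keep 3-frame dwells
   visible.
3. **Scan correction.** The best score's t p-value (df from the block
   count) is Bonferroni-corrected for the number of candidates × scales
   and accepted at α = 0.001. Measured false-positive rate on static
   pipeline traces: < 1 in 300.

Both halves of a split must span ≥ 3 frames (`min_dwell`); dwells shorter
than that are unresolvable by construction. Segment means are clustered
into two states by weighted 1-D 2-means with the threshold at the midpoint
of the centers; if the centers are closer than 0.15 (small against the
0.52 state separation) the trace is treated as single-state — this
suppresses spurious two-state readings of noise. Adjacent same-state
segments are merged. In the high-level pipeline, detection runs on the
median-filtered corrected E series (`E_raw`) rather than the CK-filtered
one: CK smoothing buys display quality but suppresses 1–2 s dwells
entirely, which would bias dwell statistics; the detector's own noise
handling replaces the filter here.

Dwell harvesting keeps only interior dwells (first and last dwell of each
trace are censored: their durations are unknown); a trace with fewer than
two transitions contributes none. Exponential fitting is
truncation-aware maximum likelihood: left truncation at the detection
limit, right truncation per dwell at the time remaining in the 90 s window
after the dwell starts (an interior dwell must end before the window
does). On ground-truth segmentations this estimator is unbiased to within
a few percent where the naive mean errs by up to 20 %.

Fits through the real detector face two further artefacts:
a *soft detection floor* (events are found reliably only above ~10 frames
once frame averaging and the 3-frame median have attenuated them) and
*merging* (an undetected short dwell of the opposite state concatenates
its two neighbours). `fit_two_state_rates` therefore (i) discards detected
dwells below 10 frames and left-truncates the likelihood there, and (ii)
applies a standard missed-event correction with an effective dead time of
5 frames: a geometric sum of exponential dwells is again exponential with
rate k·q, q = exp(−k_other·d), so the true rates solve
k = k_obs·exp(k_other·d) jointly, by fixed-point iteration. Both frame
counts are properties of the detector (the scale over which the median
prefilter plus frame integration suppress events), not free parameters.
With them, the full pipeline recovers generating rate pairs
(0.05, 0.125), (0.125, 0.05) and (0.1, 0.1) s⁻¹ within 15 % from
600-trace data sets.

## Survival of the first event, dose–response, statistics

Time-to-first-dissociation curves start at 1 and step down at each event;
traces without an event are right-censored at the window end and enter the
exponential rate as censored exposure (MLE: events / total exposure);
the half-life is ln 2 / rate. Decay rates of two conditions are compared
with a two-tailed unpaired t test on the fitted rates using their standard
errors and Welch degrees of freedom.

Dose–response readouts (percent dynamic traces, or the peak ratio) are fit
with y = floor + (ceiling−floor)·x/(EC50+x), Hill coefficient 1, with a
profile-likelihood CI on EC50. A flat readout returns a
`no_dose_dependence` flag with an unbounded CI. Note a structural property
of the dynamic-fraction readout: a trace is dynamic if *at least one*
transition falls in the window, so P(dynamic) = fr·(1−e^{−k_diss·T}); when
k_diss_max·T ≫ 1 (here ≈ 11) this saturates well below K_ATP and the
readout's EC50 sits far below K_ATP (≈ 25 µM under the defaults). The
hyperbolic fit is therefore phenomenological; parameter-recovery tests
compare the fitted EC50 against the EC50 of this expected-readout curve,
not against K_ATP.

Between-condition comparisons of per-experiment dynamic percentages use
frequency weights (weights = traces per experiment) for the weighted mean
and SD, Welch's heteroscedastic ANOVA from the group summaries
(right-tailed; verified against R's `oneway.test` to 4 decimals), and
Games–Howell-style pairwise comparisons on the studentized range with
Welch per-pair error terms (two-tailed).

## Burst analysis

Background rates are estimated per 30 s window and per detection stream
from the exponential tail of inter-photon delays: delays above the mean
delay are background-dominated, and by memorylessness rate =
1/(mean tail excess). Windows with < 50 photons carry the previous rate
forward with a flag. The burst search is the all-photon sliding-window
convention: photon i is in-burst when the rate of the m = 10 photon window
starting at it exceeds F = 6 × the local all-photon background rate;
maximal runs form bursts. A raw m/F search on pure background
unavoidably flags a few tens of ~10-photon candidate runs per 10 minutes
(the binomial tail of the local rate); the 40-photon minimum of the
selection stage removes them all, which is the sense in which the null
yields zero bursts. E and S use the standard ALEX corrections
(E from leakage/direct-excitation-corrected counts; γ and β omitted, so E
is a corrected proximity ratio); doubly-labeled molecules are selected by
0.25 ≤ S ≤ 0.85 and histogrammed in 0.04 bins, normalized to unit sum.
Leakage and direct excitation can be estimated from the same acquisition's
donor-only (S > 0.9) and acceptor-only (S < 0.1) bursts.

## Auxiliary computations

Förster relation E = 1/(1+(r/R₀)⁶) and its exact inversion (R₀ = 51 Å for
the Alexa 555/647 pair; the sensor's 34 Å Cα separation predicts
E ≈ 0.92 — measured efficiencies are lower, as expected for dye linkers
and a proximity-ratio readout). Cα distances are read from PDB files with
Bio.PDB (first model, altloc A). Growth lags use the modified
(Zwietering) Gompertz form y = A·exp(−exp(µ_m·e/A·(λ−t)+1)) with
multi-start least squares over a lag grid; flat or decreasing curves are
flagged `no_growth`. ATPase turnover converts the A340 slope to NADH
consumption via Beer–Lambert with ε₃₄₀ = 6.22 mM⁻¹cm⁻¹ (stored as
6.22e−3 µM⁻¹cm⁻¹), the plate-well pathlength from (A₉₇₇−A₉₀₀)/0.18, and
divides by the protein amount times an orientation factor of 0.5 (only
right-side-out complexes see the added ATP).

## Problem sizes and runtimes

The test suite simulates at desk scale, chosen so the whole suite runs in
a few minutes on one CPU: 500-trace benchmarks over 5 seeds for
classification, 600 traces × 3 seeds × 3 rate pairs for rate recovery,
3000 state paths per τ for censoring-bias checks, 2000 replicates for the
Welch type-I calibration, and ~1200-burst photon streams for the burst
engine. These sizes give Monte-Carlo error comfortably inside every test
tolerance; the estimators themselves carry no dependence on them.

## Known limitations

- Two states only; no intermediate or multi-state FRET inference (no HMM).
- The dead-time correction assumes a sharp effective dead time; the real
  detection probability ramps over ~3–10 frames, which leaves residual
  rate bias at the few-percent level.
- γ = 1 throughout: efficiencies are proximity ratios, not absolute E.
- The burst background's automatic delay threshold follows the common
  convention (mean delay) but is not guaranteed identical to any specific
  external implementation.
- Selection windows derived from calibration populations assume the
  calibration and measurement share intensity statistics.
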