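# ecfret

Single-molecule FRET analysis of ATP-driven assembly dynamics of modular
membrane transporters, with a forward simulator for validation.

## The problem

Energy-coupling factor (ECF) transporters are bacterial ABC importers in
which a membrane-embedded substrate-binding subunit (the S-component, e.g.
CbrT for vitamin B12) is thought to dissociate from and re-associate with
its ATPase module during the transport cycle. Labeling the two subunits
with a donor/acceptor dye pair turns assembly state into a FRET signal:
the assembled complex sits at high transfer efficiency (E ≈ 0.60 for a
C-terminal sensor), the dissociated state near zero (E ≈ 0.08) because the
subunits diffuse apart in the liposome membrane. TIRF movies of
surface-immobilized proteoliposomes then report, molecule by molecule,
whether ATP drives association/dissociation switching.

This package implements the full trace-analysis chain for such recordings,
and a generative simulator that reproduces the experiment's structure so
every stage can be validated against known ground truth:

- `ecfret.simulate` — two-state continuous-time Markov switching with
  ATP-dependent dissociation, k_diss([ATP]) = k_max·[ATP]/(K_ATP+[ATP]);
  rendering to two-channel ALEX traces (crosstalk, direct excitation,
  photobleaching, background, camera noise, orientation/inactive/single-dye
  populations); dual-view image stacks; confocal PIE photon streams;
  dose–response panels.
- `ecfret.extraction` — spot detection and aperture photometry on dual-view
  stacks.
- `ecfret.tracepipe` — median prefilter, background/leakage/direct-excitation
  corrections, single-pair selection on the red ALEX segments, and the
  Chung–Kennedy edge-preserving filter (K = M = 10, p = 1).
- `ecfret.classify` — the anticorrelation statistic
  c = ⟨δI_D·δI_A⟩ / ⟨I_D+I_A⟩², dynamic/static classification at the −0.01
  threshold with a 0.4 median-E high/low split, 0.04-bin efficiency
  histograms, two-Gaussian peak-ratio fits.
- `ecfret.kinetics` — change-point detection, censoring-aware exponential
  dwell fits (truncated MLE + missed-event correction), time-to-first-event
  survival analysis, EC50 dose–response fits, Welch ANOVA + Tukey-HSD from
  group summaries.
- `ecfret.burst` — confocal all-photon burst search (m = 10, F = 6),
  background estimation every 30 s, E–S selection (≥ 40 photons,
  0.25 ≤ S ≤ 0.85) and normalized FRET histograms.
- `ecfret.auxcalc` — Förster-relation conversions, Cα distances from PDB
  files, Gompertz growth-lag fits, ATPase turnover from NADH absorbance.

## Worked example

Classify a 500-trace synthetic benchmark and fit the switching rates at
saturating ATP:

```python
import numpy as np
import ecfret as ef
from ecfret.kinetics import detect_transitions, harvest_dwells, fit_two_state_rates

cf = ef.CorrectionFactors(lk=0.10, dir=0.05)

traces, truth = ef.simulate_benchmark(n_traces=500, seed=1)
results = [ef.classify_trace(ef.process_trace(t, cf)) for t in traces]
labels = [r.label for r in results]
print(f"dynamic: {labels.count('dynamic')}/500 traces")

sc = ef.KineticScenario()          # 10 mM ATP, k_assoc=0.05/s, k_diss_max=0.125/s
rng = np.random.default_rng(1)
segments = []
for i in range(300):
    tr, _ = ef.simulate_trace(sc, seed=rng, pre_equilibrated=True,
                              spot_class="pair")
    proc = ef.process_trace(tr, cf)
    if ef.classify_trace(proc).label == "dynamic":
        segments.append(detect_transitions(proc.E_raw, trace_id=str(i)))
dwells = harvest_dwells(segments, sc.frame_time)
fit_assoc, fit_diss = fit_two_state_rates(dwells)
print(f"associated dwell:  tau = {fit_assoc.tau:.1f} s")
print(f"dissociated dwell: tau = {fit_diss.tau:.1f} s")
```

Output:

```
dynamic: 246/500 traces
associated dwell:  tau = 8.5 s
dissociated dwell: tau = 18.7 s
```

246/500 matches the benchmark's 50 % dynamic mixture (94.2 % of all labels
agree with the generator's ground truth at this seed). The dwell fits
recover the generating kinetics — a mean associated dwell of 1/0.120 ≈ 8.3 s
at 10 mM ATP and a mean dissociated dwell of 1/0.05 = 20 s — from the
detected transitions alone, after correcting for the 90 s observation
window and for unresolvably short dwells.

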