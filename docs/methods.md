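# Methods

This note documents the models, conventions, and numerical choices behind
`tmseeg`, in the order the pipeline runs them.

## Preprocessing

The nominal analysis band is 0–45 Hz. It is implemented as a 0.5–45 Hz
4th-order Butterworth filter applied forward–backward (zero phase,
`sosfiltfilt`), because a true DC passband keeps slow drift that corrupts
the entropy and moment features; the low cut is configurable. Recordings
are segmented into non-overlapping 1-s epochs (trailing remainder
discarded) and an epoch is flagged non-retained when any channel exceeds
±100 µV peak absolute amplitude. Amplitude-threshold screening is this
package's cleaning step; it flags data and never modifies samples. No
re-referencing, notch filtering, or independent-component decomposition is
performed.

Band decomposition uses the half-open convention δ [1,4), θ [4,8),
α [8,13), β [13,30), γ [30,45] Hz, so shared edges belong to the upper
band; gamma closes at the 45 Hz global low-pass edge. Band filtering
operates on the *concatenated retained signal*, not on individual 1-s
epochs: a delta epoch holds 1–4 cycles and per-epoch filtering would be
dominated by edge transients. The 1-s grid exists for artifact screening,
not spectral estimation. The band-decomposed output therefore covers the
retained epochs only (its retained mask is all-True by construction).

## Features

Eight features per (band, channel): three entropies, Welch band power, and
four distribution moments. Defaults, all exposed in `FeatureParams`:

| parameter | default | meaning |
|---|---|---|
| `m` | 2 | ApEn/SampEn embedding dimension |
| `r` | 0.2 | ApEn/SampEn tolerance, fraction of the signal SD |
| `pe_order` | 3 | ordinal pattern length |
| `pe_delay` | 1 | ordinal embedding delay |
| `welch_window` | 2 s | Welch segment length (Hann, one-sided density) |
| `welch_overlap` | 0.5 | Welch segment overlap fraction |
| `entropy_max_samples` | 2500 | leading samples used for the entropies |
| `per_epoch_mean` | off | per-epoch feature computation, averaged |

Conventions: ApEn is Pincus's Φ_m − Φ_{m+1} with self-matches included;
SampEn is Richman–Moorman −ln(A/B) with self-matches excluded, reported as
missing (NaN) when no template pair matches; both use the Chebyshev
distance and natural logarithms, and both are computed exactly (validated
against naive O(n²) double-loop oracles in the test suite). Permutation
entropy breaks rank ties by order of appearance (stable sort) and is
normalized by ln(order!). The tolerance r is recomputed per (band,
channel) from that band-limited signal's own SD, since band amplitudes
differ by orders of magnitude. Skewness is the biased population moment
ratio m₃/m₂^1.5 and kurtosis is excess kurtosis m₄/m₂² − 3 (configurable
in the sense that the raw moments are trivially recoverable); both are
missing on zero-variance input.

Features are computed on the concatenated clean band-limited signal rather
than averaged over 1-s epochs (unstable for delta); `per_epoch_mean=True`
offers the per-epoch variant for sensitivity analysis. The entropies cost
O(n²) in series length, so they are evaluated on the leading
`entropy_max_samples` samples of the concatenated signal (10 s at 250 Hz by
default) — band power and moments always use the full signal. The "PSD"
feature of an indicator is the trapezoidal integral of the Welch density
over the band, one number per band/channel.

## Group statistics

All differences are Δ = after − before, for features and scales alike;
improvements on PSQI/ISI are negative. Paired t-tests are two-tailed with
n−1 degrees of freedom. Outcome correlations are Pearson r of Δfeature vs
Δscale with two-tailed p. Missing entropy cells are excluded pairwise and
the effective n recorded per cell; cells with fewer than 3 complete pairs
or zero variance are flagged untestable rather than raised. Selection uses
uncorrected p < 0.05 by default — the fidelity choice for a 640-cell
screen of a 15-subject cohort — with Benjamini–Hochberg FDR one flag away.
The responder rate is the fraction of subjects with
(before − after)/before ≥ 0.25, defined only for positive baselines.

## Prognosis

SVR defaults: RBF kernel, C = 1, ε = 0.1, γ = 1/(d·Var(X)) (scikit-learn's
`"scale"`); a linear kernel is available. Leave-one-out refits the
standardizer and the model on each training fold, so the held-out subject
never influences its own scaling (unit-tested). Constant training columns
are dropped with a warning; a fold with no usable predictors falls back to
the training-fold mean of y.

The permutation test shuffles the *rows of X* jointly across subjects with
y fixed — equivalent under exchangeability to permuting y — and reruns the
entire LOO procedure per shuffle. The p-value is one-sided toward positive
correlation, (#{r_null ≥ r_obs} + 1)/(N + 1): a useful prognostic model
must predict positively, and the add-one correction keeps p > 0. The
default null size is N = 5000. A permutation whose LOO predictions are
constant (everything inside the ε tube) carries no predictive signal and
scores r = 0 in the null.

`run_prognosis` selects indicators on the full sample by default,
mirroring the original clinical procedure. This is optimistically biased —
the selection has seen every subject's outcome — and on null data the
full-sample route rejects far more often than α. The `nested` mode repeats
the Pearson screening inside every training fold (and inside every
permutation), which removes the leak; it is the mode to trust for honest
effect claims, and the full-sample mode is the one to use when replicating
the original analysis.

## Synthetic cohorts

The generator emulates 5-minute awake, eyes-closed resting EEG at 250 Hz:
per channel, one sinusoidal carrier per band (frequency uniform inside the
band, random phase, both fixed per subject across sessions) riding on
1/f^α Gaussian noise (α = 1, 10 µV RMS). Default band amplitudes are
alpha-dominant — δ 8, θ 6, α 20, β 5, γ 2 µV — a conventional awake
closed-eye profile; none of these were fitted to data, since the source
recordings' amplitude and spectral distributions are unpublished. A cohort
draws per-subject score changes Δs ~ N(−4, 3²), rounds to integers, clips
to the instrument range, and multiplies the post-session amplitude of one
(band, channel) — default alpha at P3 — by 1 + effect_size·Δs. Baseline
scores are uniform integers over plausible insomnia ranges (PSQI 9–19,
ISI 8–28). The second scale's changes are drawn independently.

What the generator does *not* emulate: sleep-stage microstructure,
eye-blink/EMG artifact morphology, volume-conduction correlations between
channels, non-sinusoidal oscillation shape, and stimulation physics.
Passing tests therefore demonstrate that the statistical machinery is
calibrated and recovers planted amplitude effects — not that the specific
clinical findings generalize.

All generators are deterministic: seeds derive from
(cohort seed, subject index, session) via `numpy` seed sequences, so
pre/post recordings of a subject share carriers and phases and differ only
in noise realization and the planted effect.

## Simulation-study problem sizes

Calibration and recovery studies run at reduced sizes chosen once as the
package's simulation conditions: 20-s recordings, a 512-sample entropy
cap, and 200-permutation nulls. Specifically: the null false-positive
calibration averages the 640-cell grid over 20 seeded null cohorts
(n = 15); the permutation-test type-I calibration uses 100 replicates of
Gaussian X ⊥ y (n = 15, d = 3); planted-effect recovery uses 20 seeded
cohorts of n = 30 with effect_size 0.06 on alpha@P3. The acceptance script
runs a fuller demonstration — 60-s recordings, 1024-sample entropy cap,
and the complete 5000-permutation null for both scales.

## Degenerate inputs and tie-breaks

Zero-variance series: skew/kurtosis and the entropies are reported missing
(NaN) and excluded pairwise downstream. SampEn with no matching template
pair is missing, not an error. A constant outcome vector raises a
degenerate-input error before modeling. Permutation-entropy rank ties go
to the earlier sample. Band power over a band containing fewer than two
grid points is 0. EDF export quantizes to 16 bits over the recording's
symmetric amplitude range (round-trip error is pure quantization,
round-trip tested against an independent EDF reader).

## Known limitations

* Full-sample selection (the default, for fidelity) inflates the observed
  LOO correlation and its significance; use `nested` for unbiased claims.
* The entropy cap trades a few percent of estimator variance for
  tractability; entropies of slowly-varying delta signals see relatively
  few cycles in the capped window.
* The schematic topographic maps use non-anatomical coordinates and
  thin-plate-spline interpolation; they are qualitative.
* Uncorrected p < 0.05 across 640 cells implies ~32 false positives under
  the null; this mirrors the replicated procedure and is why the
  permutation test, not the selection, carries the inferential weight.
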