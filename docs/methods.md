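# Methods

## Signal model and picking criterion

An A-scan is modelled as a piecewise locally stationary sequence: segments
of coherent ultrasound (transmitted burst, echoes) alternate with spans
where the wave is drowned by front-end noise. The two-segment AIC criterion

    AIC(k) = k · ln var(s[1..k]) + (N−k+1) · ln var(s[k+1..N]),   k ∈ [2, N−2]

scores every merge point k; its global minimum is the strongest variance
change point. The segment variance uses the unbiased estimator (denominator
j−i over s(i..j)). Three numerical conventions:

* **Admissible range [2, N−2].** Each segment needs at least two samples
  for a defined variance; the criterion itself does not state boundary
  handling.
* **Variance floor.** Variances below `1e-12 · max|s|²` are floored before
  the logarithm; stems produce near-silent spans and the criterion is
  undefined at zero variance. The relative floor keeps the picker invariant
  under amplitude scaling.
* **Log base and second weight.** Natural log (any base rescales the curve
  without moving the argmin). The second-segment weight is implemented as
  printed in the source formulation, `N−k+1`; the common picker form
  `N−k−1` is available as `aic_variant="maeda"`. The argmin is nearly
  insensitive to the choice. Ties at the minimum break to the earliest
  index (first-arrival convention).

On homogeneous media the AIC minimum is the signal onset. On attenuating
stems the deepest contrast is the burst–noise junction, so the classical
pick systematically misses the primary echo — the failure mode the hybrid
picker addresses.

## Hybrid differential pipeline

The echo onset leaves a slope break in the AIC tail after the minimum:
before the onset the second-segment variance grows as quiet samples are
discarded, after it the decaying echo makes it shrink. The pipeline
amplifies that break:

1. tail extraction from the (earliest) global minimum to the end of the
   curve; tails shorter than `2(M+1)` samples are an error rather than a
   silent fallback;
2. M-th order forward difference (default M = 4, the reference order);
   output length shrinks by M;
3. signed envelope: elementwise odd power (default cube) then division by
   the maximum absolute value. The odd power preserves the phase of the
   oscillating differential (both envelope sides are retained; no analytic
   signal or rectification) and sharpens the dominant lobe cubically;
4. mixing: the envelope, zero-padded at the tail to the length of `AICseg`,
   multiplies the tail. Default `shifted` mode uses
   `|envelope| · (AICseg − min AICseg)`; `literal` mode is the plain
   product.
5. the mixed-curve argmax (earliest on ties) plus an optional integer
   `onset_offset` (default 0) is the pick.

**Why `shifted` is the default.** The plain product's argmax is ambiguous
when AIC values are negative (logs of sub-unity variances — routine once
amplitudes are normalised below 1): a negative envelope lobe times a
negative tail value can beat the onset peak. Shifting the tail to
nonnegative and taking the envelope magnitude preserves the intent — peak
at the onset, spurious differential spikes near the minimum suppressed by
the small tail values there — for arbitrary amplitude scales. `literal` is
retained for fidelity experiments with positive-AIC (large-amplitude)
traces.

**Alignment.** The difference value computed from `AICseg[i..i+M]` is
assigned to coordinate *i* (forward convention) and the last M positions are
zero-padded. On the synthetic suite this leaves picks at most 1–2 samples
late, consistent with onset-or-later behaviour expected of an
energy-arrival detector; no group-delay correction is applied by default.

**Error anatomy.** The M-th difference is a high-pass filter: it amplifies
single-sample spikes in the AIC tail (gain ~2^M) roughly 6× more than a
slope break of equal size. The tail of an AIC curve over a noisy segment
carries chi-square estimation noise whose *relative* size is scale
invariant, so spurious lobes do not vanish with higher echo amplitude alone
— they fall only as the echo-to-noise ratio of the *segment variance
estimates* improves, and residual misses land on later carrier lobes at
multiples of the half carrier period (5 samples at the default 0.1
cycles/sample). This is why pick errors are quantised (±1, then ~6, then
~11 samples) rather than smoothly distributed.

## Synthetic A-scans

`simulate_ascan` builds the canonical three-segment trace:

| segment | content |
|---|---|
| 1..burst_end | decaying gated sinusoid (excitation) + white Gaussian noise |
| burst_end+1..echo_onset−1 | noise + sub-noise echo energy at `drowned_snr_db` |
| echo_onset..N | decaying gated sinusoid (echo) + noise |

Parameters and defaults (chosen once, as the study conditions of the
package):

* `n_samples=200`, `burst_end=100`, `echo_onset=153` — the reference
  display window (2.00 du with the echo at 1.53 du);
* `carrier_cycles_per_sample=0.1` — 1 MHz probe sampled at 10 MHz;
* `noise_sigma=0.003`, `echo_amplitude=1.0`, `burst_amplitude=2.0`;
* `drowned_snr_db=−6` — the mid-span echo energy sits 6 dB below the noise,
  scaled with the noise so the zero-noise limit silences the span;
* `decay_rate=0.05`/sample for the echo; `burst_decay_rate=0.5/burst_end`
  for the excitation. The two rates differ for a structural reason: the
  burst must stay well above the noise floor all the way to the junction so
  the classical minimum anchors there (slow decay over a long burst), while
  the echo's first cycle must dominate the differential response (fast decay
  over its 48 samples). A single shared rate cannot satisfy both, which
  measurably destroys either the failure-mode reproduction or the pick
  accuracy.

Wavelets are deterministic given the spec; only the additive noise is drawn
from the seeded generator, so segment SNRs are exact in expectation and the
whole trace is a pure function of the spec.

The benchmark suite (`simulate_benchmark_suite`) crosses onsets 153/253/351
with echo-segment SNR levels 41/38/35 dB (onset-major order; burst end at
onset−52, trace end at onset+47, preserving the 52-sample drowned span).
The SNR levels are a calibration of this package: they were set so the
pick-error spread across the suite brackets the 0–6 sample range
characteristic of the method at its three difficulty levels, giving a mean
absolute error of ~0.015 du. At much lower segment SNR (tens of dB less)
the chi-square noise lobes described above dominate the differential and
the picker degrades sharply; the suite deliberately probes the usable
regime, not the breakdown.

**What the simulator does not emulate:** multiple scattered arrivals
between burst and echo, frequency-dependent attenuation and dispersion,
probe ringing, coherent reverberation, or baseline drift. Passing the
synthetic suite therefore demonstrates correct onset recovery under the
stated segment model, not performance on arbitrary field data.

## Display units

Picks are reported as 1-based sample indices and in display units
(1 du = 100 samples), matching the reference acquisition display where
sample 153 reads 1.53. At the actual 10 MHz sampling rate one sample is
0.1 µs, so physical time (`index_to_seconds`) is reported separately; the
display unit is a plotting convention, not an SI time.

## Water-content analytics

* Longitudinal velocity from elastic constants diverges as Poisson's ratio
  approaches 0.5; the domain is restricted to [0, 0.5).
* Volumetric moisture θ = (m_A − m_B)/(βV) with water density β defaulting
  to 1.0 g/cm³. Mass moisture is **wet-basis** (m_A − m_B)/m_A — the
  convention that reproduces the bundled dataset's published derived row
  cell-for-cell (dry-basis does not).
* Sample geometry "6 cm × 6 cm" is read as diameter × height of a cylinder;
  validated by reproducing the published density row.
* The bundled dataset's measured velocities are treated as inputs and never
  recomputed: the acoustic path length of those measurements is not part of
  the dataset.
* The velocity–moisture relation is fitted per sample with a degree-2
  polynomial by least squares; fit quality is the Pearson correlation
  between fitted and observed velocities (the square root of R² for a
  least-squares fit), averaged unweighted across samples. A degree-2 fit
  needs ≥ 4 points; samples with fewer velocity points are excluded with a
  warning.
* Published derived rows are printed to 2 decimals with ties rounded away
  from zero; the test comparisons use half-up rounding accordingly (one
  cell, 0.305, distinguishes the rules).
* `track_correlation` aligns series by exact timestamp match (no
  interpolation) and requires ≥ 3 aligned pairs with nonzero variance.

## Known limitations

* Single onset per trace; no multi-echo decomposition, attenuation/Q
  estimation, or frequency-domain analysis.
* The shift-equivariance of the pick under a prepended quiet lead-in holds
  for short prepends (≲ 15 samples at the default geometry). A long quiet
  lead-in creates a deeper two-segment split at its own boundary, the AIC
  minimum relocates there, and the extracted tail no longer brackets the
  echo. Physical A-scans start at pulse emission, so the regime matters
  mainly for windowed re-analysis.
* The AIC tail's last few merge points rest on 2–3 sample variances and are
  intrinsically noisy; the differential can spike there. The mixing stage
  usually, but not always, suppresses these end lobes — at low segment SNR
  they are the dominant failure mode.
* `mixed_peak_value` is comparable between traces only under the same
  mixing mode and amplitude convention.
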