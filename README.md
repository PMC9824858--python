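# stemecho

Primary-echo picking in ultrasonic A-scans of plant stems, with stem
water-content analytics and a seeded benchmark simulator.

## The problem

Stem water content is a key index of plant water status, and pulse-echo
ultrasound can track it non-destructively: water uptake raises the stem's
density ρ, and for roughly constant elastic constants the longitudinal
velocity

    v_l = sqrt( (E/ρ) · (1−σ) / ((1+σ)(1−2σ)) )

falls. Measuring v_l = 2D/t needs the round-trip time *t* of the **primary
echo** — the first reflection from the far side of the stem. Stems are
heterogeneous and anisotropic, so the RF record contains multiple scattered
arrivals and strong attenuation, and the echo onset is hard to localise.

The classical AIC onset picker models the trace s(1..N) as two locally
stationary segments joined at a merge point *k*:

    AIC(k) = k · ln var(s[1..k]) + (N−k+1) · ln var(s[k+1..N])

and takes the global minimum as the onset. On strongly attenuating stems
this fails characteristically: the deepest variance contrast is the junction
between the transmitted burst and the noise floor, so the minimum marks the
*end of the excitation*, not the echo.

## The hybrid differential AIC picker

`stemecho` implements a hybrid pipeline that recovers the echo from the AIC
curve's tail:

1. compute AIC(k) over k ∈ [2, N−2];
2. extract the tail `AICseg(i)` from the global minimum to the end;
3. take the M-th order forward difference (default M = 4), which responds to
   the slope break the echo onset leaves in the tail;
4. cube the differential and normalise to unit peak (a signed "envelope":
   the odd power sharpens the dominant lobe without rectifying it);
5. mix the envelope back into the tail (elementwise product); the default
   `shifted` mode uses |envelope| · (AICseg − min AICseg), which is
   amplitude-scale invariant and sign-safe; `literal` mode is the plain
   product;
6. the maximum of the mixed curve is the primary-echo onset.

Mixing suppresses spurious differential spikes near the minimum, where the
tail is flat, while keeping the onset response.

Onsets are reported as 1-based sample indices, in display units
(du, 1 du = 100 samples; sample 153 ⇔ 1.53 du — the convention of the
reference acquisition display) and in physical seconds via the sampling rate
(default 10 MHz).

## Worked example

```python
from stemecho import AscanSpec, simulate_ascan, pick_primary_echo

trace, truth = simulate_ascan(AscanSpec(seed=42))
pick = pick_primary_echo(trace)
print(f"true echo onset:   sample {truth.echo_onset} ({truth.echo_onset/100:.2f} du)")
print(f"classical AIC min: sample {pick.classic_min_index} ({pick.classic_min_index/100:.2f} du)")
print(f"hybrid pick:       sample {pick.onset_index} ({pick.onset_du:.2f} du)")
```

prints

```
true echo onset:   sample 153 (1.53 du)
classical AIC min: sample 100 (1.00 du)
hybrid pick:       sample 154 (1.54 du)
```

The simulated A-scan has the canonical three-segment structure: excitation
burst to sample 100, a 52-sample span where reverberation is drowned by
noise, and the primary echo from sample 153. The classical minimum lands at
the burst–noise junction (1.00 du — the failure mode described above); the
hybrid pick recovers the echo onset to within one sample.

The same API scales to the nine-signal benchmark
(`simulate_benchmark_suite`: onsets 153/253/351 × three SNR levels) and to
file-based workflows through the CLI:

```sh
stemecho simulate --suite benchmark --seed 7 --out sim/
stemecho pick sim/trace_*.csv --out picks.csv --dump-curves curves/
stemecho immersion <table.csv> --beta 1.0 --out derived.csv
stemecho track picks.csv soil_moisture.csv --window 12 18
```

## Water-content analytics

The `hydro` module carries the physics around the picker: longitudinal
velocity from elastic constants, velocity from echo time (v = 2D/t),
volumetric moisture θ = (m_A − m_B)/(βV) and wet-basis mass moisture
(m_A − m_B)/m_A. A bundled immersion dataset (three cylindrical stem
samples, 15 soaking timepoints each, with measured velocities) demonstrates
the full analysis: `immersion_analysis` derives density and both moisture
measures per timepoint and fits velocity against volumetric moisture with a
quadratic per sample — the mean fitted–observed correlation on the bundled
data is 0.99. `track_correlation` aligns picked echo positions with an
environmental covariate (e.g. soil moisture) by timestamp and reports the
Pearson correlation.

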