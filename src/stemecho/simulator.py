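"""Seeded generator of synthetic pulse-echo A-scans with known ground truth.

The generated trace has the three-segment structure of a reflection
measurement on an attenuating stem:

* segment 1 (samples ``1..burst_end``): the transmitted excitation burst —
  a decaying gated sinusoid at the probe carrier — plus white Gaussian noise;
* segment 2 (``burst_end+1..echo_onset-1``): the span where reverberating
  ultrasound is drowned by noise — white noise plus sub-noise echo energy at
  ``drowned_snr_db``;
* segment 3 (``echo_onset..n_samples``): the primary echo — a decaying gated
  sinusoid — plus noise.

Defaults emulate the reference display window: 200 samples (2.00 display
units), burst to sample 100, echo onset at sample 153, 1 MHz carrier sampled
at 10 MHz (0.1 cycles/sample). The same seed always yields a bit-identical
trace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .traces import UltrasonicTrace

__all__ = [
    "AscanSpec",
    "SimulationTruth",
    "simulate_ascan",
    "simulate_benchmark_suite",
    "echo_amplitude_for_snr",
    "DEFAULT_SUITE_ONSETS",
    "DEFAULT_SUITE_SNR_DB",
]

#: Benchmark-suite onsets (echo positions 1.53 / 2.53 / 3.51 display units).
DEFAULT_SUITE_ONSETS = (153, 253, 351)

#: Echo-segment SNR levels of the benchmark suite, in dB, decreasing
#: difficulty-wise. Calibrated so that pick errors span roughly 0-6 samples
#: across the suite (see docs/methods.md).
DEFAULT_SUITE_SNR_DB = (41.0, 38.0, 35.0)


@dataclass(frozen=True)
class AscanSpec:
    """Full parameterisation of one synthetic A-scan.

    ``decay_rate`` is the exponential amplitude decay per sample of the echo
    wavelet; the excitation burst uses ``burst_decay_rate`` (default
    ``0.5 / burst_end``, i.e. the burst falls to ``e^-0.5`` of its initial
    amplitude at the burst-noise junction, keeping the junction sharp for
    any burst length).
    """

    n_samples: int = 200
    burst_end: int = 100
    echo_onset: int = 153
    carrier_cycles_per_sample: float = 0.1
    burst_amplitude: float = 2.0
    echo_amplitude: float = 1.0
    noise_sigma: float = 0.003
    drowned_snr_db: float = -6.0
    decay_rate: float = 0.05
    burst_decay_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 < self.burst_end < self.echo_onset <= self.n_samples:
            raise ValueError(
                "need 1 < burst_end < echo_onset <= n_samples, got "
                f"burst_end={self.burst_end}, echo_onset={self.echo_onset}, "
                f"n_samples={self.n_samples}"
            )
        if self.burst_amplitude <= 0 or self.echo_amplitude <= 0:
            raise ValueError("amplitudes must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be nonnegative")
        if self.carrier_cycles_per_sample <= 0:
            raise ValueError("carrier_cycles_per_sample must be positive")

    @property
    def effective_burst_decay(self) -> float:
        if self.burst_decay_rate is not None:
            return self.burst_decay_rate
        return 0.5 / self.burst_end


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for one simulated trace."""

    echo_onset: int
    burst_end: int
    spec: AscanSpec


def _wavelet(n: int, cycles_per_sample: float, decay: float, amplitude: float) -> np.ndarray:
    """Decaying gated sinusoid of length n (phase 0 at the gate)."""
    t = np.arange(n)
    return amplitude * np.exp(-decay * t) * np.sin(2.0 * np.pi * cycles_per_sample * t)


def mean_wavelet_power(decay: float, n: int) -> float:
    """Mean power of a unit-amplitude decaying sinusoid over n samples."""
    t = np.arange(n)
    return float(0.5 * np.mean(np.exp(-2.0 * decay * t)))


def echo_amplitude_for_snr(
    snr_db: float,
    noise_sigma: float,
    decay_rate: float = 0.05,
    n_echo: int = 48,
) -> float:
    """Echo amplitude giving the requested echo-segment SNR.

    SNR is the ratio of the echo wavelet's mean power over its segment to the
    noise power ``noise_sigma**2``, in dB.
    """
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be positive to set an SNR")
    target_power = noise_sigma**2 * 10.0 ** (snr_db / 10.0)
    return float(np.sqrt(target_power / mean_wavelet_power(decay_rate, n_echo)))


def simulate_ascan(spec: AscanSpec) -> tuple[UltrasonicTrace, SimulationTruth]:
    """Generate one A-scan and its ground truth (pure function of ``spec``)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    s = rng.normal(0.0, spec.noise_sigma, n) if spec.noise_sigma > 0 else np.zeros(n)

    cps = spec.carrier_cycles_per_sample
    s[: spec.burst_end] += _wavelet(
        spec.burst_end, cps, spec.effective_burst_decay, spec.burst_amplitude
    )

    mid = spec.echo_onset - 1 - spec.burst_end
    if mid > 0:
        w = _wavelet(mid, cps, spec.decay_rate, 1.0)
        power = float(np.mean(w * w))
        if power > 0:
            # sub-noise echo energy: power pinned to noise power at drowned_snr_db
            target = spec.noise_sigma**2 * 10.0 ** (spec.drowned_snr_db / 10.0)
            s[spec.burst_end : spec.echo_onset - 1] += w * np.sqrt(target / power)

    n_echo = n - spec.echo_onset + 1
    s[spec.echo_onset - 1 :] += _wavelet(n_echo, cps, spec.decay_rate, spec.echo_amplitude)

    trace = UltrasonicTrace(s, trace_id=f"sim-seed{spec.seed}")
    return trace, SimulationTruth(spec.echo_onset, spec.burst_end, spec)


def simulate_benchmark_suite(
    onsets: Sequence[int] = DEFAULT_SUITE_ONSETS,
    snr_levels_db: Sequence[float] = DEFAULT_SUITE_SNR_DB,
    seed: int = 0,
    noise_sigma: float = 0.003,
) -> list[tuple[UltrasonicTrace, SimulationTruth]]:
    """Nine-signal benchmark: 3 echo onsets x 3 echo-segment SNR levels.

    For onset ``o`` the burst ends at ``o - 52`` (preserving the 52-sample
    drowned span) and the trace ends 47 samples after the onset. The suite is
    ordered onset-major: signals 1-3 share the first onset at decreasing SNR,
    and so on. The whole suite is a pure function of its arguments.
    """
    if len(onsets) == 0 or len(snr_levels_db) == 0:
        raise ValueError("need at least one onset and one SNR level")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(onsets) * len(snr_levels_db)
    )
    out: list[tuple[UltrasonicTrace, SimulationTruth]] = []
    i = 0
    for onset in onsets:
        for snr_db in snr_levels_db:
            burst_end = onset - 52
            n = onset + 47
            n_echo = n - onset + 1
            spec = AscanSpec(
                n_samples=n,
                burst_end=burst_end,
                echo_onset=onset,
                noise_sigma=noise_sigma,
                echo_amplitude=echo_amplitude_for_snr(
                    snr_db, noise_sigma, decay_rate=0.05, n_echo=n_echo
                ),
                seed=int(child_seeds[i]),
            )
            trace, truth = simulate_ascan(spec)
            trace = UltrasonicTrace(
                trace.samples,
                sampling_rate=trace.sampling_rate,
                trace_id=f"sig{i + 1:02d}-onset{onset}-snr{snr_db:g}dB",
            )
            out.append((trace, truth))
            i += 1
    return out
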