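"""Synthetic RR-interval generators for five rhythm classes.

The generators are statistical stand-ins tuned to reproduce the
qualitative Lorenz-plot morphologies of the rhythms the detector must
separate — they model interval statistics only, never an ECG waveform:

* SINUS — mean RR plus attenuated respiratory sinus arrhythmia (a
  ~10-beat sinusoidal modulation) plus a dominant ~20-beat
  low-frequency baroreflex component and small white jitter; strongly
  autocorrelated, tight Lorenz cloud.
* AF — independent draws from a right-skewed (shifted lognormal)
  distribution; negligible lag-1 autocorrelation, diffuse cloud.
* BIGEMINY — alternating coupled (0.7 * mean) and compensatory
  (1.3 * mean) intervals: regularly irregular, a few discrete clusters.
* HEART_BLOCK — a sinus stream in which a beat is randomly dropped
  (interval doubling) with probability 0.1.
* SINUS_ARRHYTHMIA — sinus with exaggerated respiratory amplitude.

Only AF windows are labeled AF; everything else is non-AF.  A single
spec seed feeds a dedicated numpy substream, so datasets are exactly
reproducible and adding one spec never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .features import FeatureConfig, extract_features
from .rr_io import RhythmLabel, Window

__all__ = ["Rhythm", "RhythmGeneratorSpec", "generate", "generate_stream",
           "build_dataset"]

CLIP_LOW_MS = 250.0
CLIP_HIGH_MS = 2500.0

#: Default interval SD per rhythm, ms.  AF variability is the SD of the
#: i.i.d. interval distribution; for sinus-like rhythms it is the total
#: SD of the modulated stream.
DEFAULT_VARIABILITY = {
    "SINUS": 40.0,
    "AF": 120.0,
    "BIGEMINY": 10.0,
    "HEART_BLOCK": 40.0,
    "SINUS_ARRHYTHMIA": 100.0,
}

# Fixed model shape constants (not exposed per-spec: they define the
# rhythm archetypes, not their intensity).  The sinus spectrum mimics a
# resting elderly profile: attenuated respiratory sinus arrhythmia on
# slow breathing (~7.5 breaths/min at 75 bpm) with the low-frequency
# baroreflex band carrying most of the variance, so beat-to-beat deltas
# stay small relative to the total SD (RMSSD << SDNN).
_RESP_PERIOD_BEATS = 10.0
_LF_PERIOD_BEATS = 20.0
_RESP_VAR_FRACTION = 0.25       # share of variance in the respiratory band
_LF_VAR_FRACTION = 0.73
_JITTER_VAR_FRACTION = 0.02
_AF_LOGNORMAL_SIGMA = 0.5       # shape of the right-skewed AF distribution
_BIGEMINY_COUPLED = 0.7
_BIGEMINY_COMPENSATORY = 1.3
_BLOCK_DROP_PROB = 0.1


class Rhythm(Enum):
    SINUS = "SINUS"
    AF = "AF"
    BIGEMINY = "BIGEMINY"
    HEART_BLOCK = "HEART_BLOCK"
    SINUS_ARRHYTHMIA = "SINUS_ARRHYTHMIA"


@dataclass(frozen=True)
class RhythmGeneratorSpec:
    """What to generate: rhythm class, scale, amount and seed."""

    rhythm: Rhythm
    n_windows: int
    seed: int
    mean_rr: float = 800.0
    variability: float | None = None
    window_length: int = 60

    def __post_init__(self) -> None:
        if isinstance(self.rhythm, str):
            object.__setattr__(self, "rhythm", Rhythm(self.rhythm.upper()))
        if not 300.0 <= self.mean_rr <= 2000.0:
            raise ValueError("mean_rr must be within [300, 2000] ms")
        if self.n_windows < 0:
            raise ValueError("n_windows must be non-negative")
        if self.variability is None:
            object.__setattr__(
                self, "variability", DEFAULT_VARIABILITY[self.rhythm.value]
            )
        if self.variability < 0:
            raise ValueError("variability must be non-negative")
        if self.rhythm is Rhythm.SINUS_ARRHYTHMIA and self.variability < 80.0:
            raise ValueError("sinus arrhythmia needs variability >= 80 ms")

    @property
    def label(self) -> RhythmLabel:
        return (RhythmLabel.AF if self.rhythm is Rhythm.AF
                else RhythmLabel.NON_AF)


def _sinus_stream(n: int, mean: float, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    k = np.arange(n)
    phase_r, phase_m = rng.uniform(0, 2 * np.pi, size=2)
    # a sinusoid of amplitude A has RMS A/sqrt(2); split the variance
    # budget across the two oscillations and the jitter
    amp_r = sd * np.sqrt(2 * _RESP_VAR_FRACTION)
    amp_m = sd * np.sqrt(2 * _LF_VAR_FRACTION)
    jit = sd * np.sqrt(_JITTER_VAR_FRACTION)
    return (mean
            + amp_r * np.sin(2 * np.pi * k / _RESP_PERIOD_BEATS + phase_r)
            + amp_m * np.sin(2 * np.pi * k / _LF_PERIOD_BEATS + phase_m)
            + rng.normal(0.0, jit, size=n))


def _af_stream(n: int, mean: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    # shifted lognormal: scale a unit-median lognormal to the target SD,
    # then shift so the mean lands on mean_rr
    base = rng.lognormal(0.0, _AF_LOGNORMAL_SIGMA, size=n)
    s = _AF_LOGNORMAL_SIGMA
    base_mean = np.exp(s * s / 2)
    base_sd = base_mean * np.sqrt(np.exp(s * s) - 1.0)
    scaled = base * (sd / base_sd)
    return scaled + (mean - base_mean * sd / base_sd)


def _bigeminy_stream(n: int, mean: float, jitter_sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    pattern = np.where(np.arange(n) % 2 == 0,
                       _BIGEMINY_COUPLED * mean,
                       _BIGEMINY_COMPENSATORY * mean)
    return pattern + rng.normal(0.0, jitter_sd, size=n)


def _heart_block_stream(n: int, mean: float, sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    # generate extra sinus beats, then merge dropped beats' intervals
    raw = _sinus_stream(2 * n, mean, sd, rng)
    dropped = rng.random(2 * n) < _BLOCK_DROP_PROB
    out: list[float] = []
    i = 0
    while len(out) < n and i < raw.size - 1:
        if dropped[i]:
            out.append(raw[i] + raw[i + 1])
            i += 2
        else:
            out.append(raw[i])
            i += 1
    while len(out) < n:  # degenerate fallback, keeps length contract
        out.append(mean)
    return np.asarray(out)


def generate_stream(spec: RhythmGeneratorSpec, n_intervals: int,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """A clipped RR stream of ``n_intervals`` for the spec's rhythm."""
    if rng is None:
        rng = _spec_rng(spec)
    r, m, v = spec.rhythm, spec.mean_rr, spec.variability
    if r is Rhythm.AF:
        stream = _af_stream(n_intervals, m, v, rng)
    elif r is Rhythm.BIGEMINY:
        stream = _bigeminy_stream(n_intervals, m, v, rng)
    elif r is Rhythm.HEART_BLOCK:
        stream = _heart_block_stream(n_intervals, m, v, rng)
    else:  # SINUS and SINUS_ARRHYTHMIA share the model, amplitude differs
        stream = _sinus_stream(n_intervals, m, v, rng)
    return np.clip(stream, CLIP_LOW_MS, CLIP_HIGH_MS)


def _spec_rng(spec: RhythmGeneratorSpec) -> np.random.Generator:
    # substream keyed by (seed, rhythm): adding a spec to a dataset
    # never perturbs another spec's draws
    ss = np.random.SeedSequence(
        entropy=spec.seed,
        spawn_key=(list(Rhythm).index(spec.rhythm),),
    )
    return np.random.default_rng(ss)


def generate(spec: RhythmGeneratorSpec) -> list[Window]:
    """``n_windows`` labeled 60-beat windows, deterministic given seed."""
    rng = _spec_rng(spec)
    total = spec.n_windows * spec.window_length
    stream = generate_stream(spec, total, rng)
    label = spec.label
    return [
        Window(stream[i * spec.window_length:(i + 1) * spec.window_length],
               label,
               (f"synthetic:{spec.rhythm.value.lower()}:{spec.seed}",
                i * spec.window_length),
               spec.window_length)
        for i in range(spec.n_windows)
    ]


def build_dataset(
    specs: list[RhythmGeneratorSpec],
    config: FeatureConfig = FeatureConfig(),
) -> tuple[np.ndarray, list[RhythmLabel], list[Window]]:
    """Concatenated feature matrix, labels and windows for all specs."""
    if not specs:
        raise ValueError("need at least one generator spec")
    windows: list[Window] = []
    for spec in specs:
        windows.extend(generate(spec))
    features = np.array([extract_features(w, config) for w in windows])
    labels = [w.label for w in windows]
    return features, labels, windows
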