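"""Population-coding model of temporal numerosity judgment.

A bank of units tuned to numerosity on a log2 axis responds to each
vibration in a sequence with Poisson spike counts; a Gaussian temporal
window centered on the final vibration's onset down-weights responses to
earlier vibrations; the gained counts are summed per unit and the
numerosity is decoded as a weighted geometric mean of the preferred
numerosities (weighted average on the log2 axis).

The decoded value systematically falls below the true count for longer
sequences and shorter onset asynchronies, reproducing the underestimation
seen in human temporal numerosity judgment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateResponseError",
    "PopulationSpec",
    "StimulusCondition",
    "TemporalWindow",
    "ModelParams",
    "tuning_mean_rate",
    "vibration_onsets",
    "window_weights",
    "mean_rate_matrix",
    "sample_spike_matrix",
    "integrate_response",
    "decode_numerosity",
    "simulate_condition",
    "oracle_expected_decode",
]

#: Design constants of the behavioral study this model is fitted to.
DESIGN_SOAS_MS = (100, 150, 200, 250)
DESIGN_NUMBERS = (2, 3, 4, 5, 6)


class DegenerateResponseError(ValueError):
    """Raised when an all-zero population response reaches the decoder."""


@dataclass(frozen=True)
class PopulationSpec:
    """The bank of numerosity-tuned units.

    Parameters
    ----------
    preferred_numerosities
        Strictly increasing positive integers; one unit per value.
        Default 1..10 (population of ten units). Sizes 7..13 are supported.
    sd_tuning
        Tuning-curve standard deviation in log2-numerosity units.
    peak_rate
        Expected spike count of a unit at its preferred numerosity,
        per presentation. The decoder is scale invariant, so this only
        sets the Poisson signal-to-noise ratio.
    """

    preferred_numerosities: tuple[int, ...] = tuple(range(1, 11))
    sd_tuning: float = 0.6
    peak_rate: float = 10.0

    def __post_init__(self) -> None:
        pref = np.asarray(self.preferred_numerosities)
        if pref.ndim != 1 or len(pref) == 0:
            raise ValueError("preferred_numerosities must be a non-empty sequence")
        if not (7 <= len(pref) <= 13):
            raise ValueError(f"population size must be in 7..13, got {len(pref)}")
        if pref[0] < 1 or np.any(np.diff(pref) <= 0):
            raise ValueError("preferred numerosities must be strictly increasing and >= 1")
        if not self.sd_tuning > 0:
            raise ValueError(f"sd_tuning must be > 0, got {self.sd_tuning}")
        if not self.peak_rate > 0:
            raise ValueError(f"peak_rate must be > 0, got {self.peak_rate}")

    @classmethod
    def with_size(cls, n_units: int, sd_tuning: float = 0.6, peak_rate: float = 10.0) -> "PopulationSpec":
        """Population with preferred numerosities 1..n_units."""
        return cls(tuple(range(1, n_units + 1)), sd_tuning, peak_rate)

    @property
    def size(self) -> int:
        return len(self.preferred_numerosities)


@dataclass(frozen=True)
class StimulusCondition:
    """One (number of vibrations, SOA) cell of the design.

    Vibration onsets are mapped onto the time axis so that the last
    vibration starts at 0 ms and earlier ones at negative multiples of
    the SOA.
    """

    n_vibrations: int
    soa_ms: float

    def __post_init__(self) -> None:
        if self.n_vibrations < 1:
            raise ValueError(f"n_vibrations must be >= 1, got {self.n_vibrations}")
        if not self.soa_ms > 0:
            raise ValueError(f"soa_ms must be > 0, got {self.soa_ms}")

    @property
    def onset_times_ms(self) -> np.ndarray:
        return vibration_onsets(self.n_vibrations, self.soa_ms)


@dataclass(frozen=True)
class TemporalWindow:
    """Gaussian gain profile centered at the final vibration's onset (0 ms).

    The weight is exactly 1 at t = 0 and decays as exp(-t^2 / (2 sd^2));
    weights are deliberately not normalized to sum to one — the decoder
    is scale invariant, so normalization is immaterial.
    """

    sd_window_ms: float

    def __post_init__(self) -> None:
        if not self.sd_window_ms > 0:
            raise ValueError(f"sd_window_ms must be > 0, got {self.sd_window_ms}")

    def weights(self, onset_times_ms: np.ndarray) -> np.ndarray:
        return window_weights(onset_times_ms, self.sd_window_ms)


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one model run."""

    population: PopulationSpec = field(default_factory=PopulationSpec)
    window: TemporalWindow = field(default_factory=lambda: TemporalWindow(300.0))
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")


# ---------------------------------------------------------------------------
# Step 1: tuning curves on the log2-numerosity axis


def tuning_mean_rate(i, k, sd_tuning: float, peak_rate: float = 10.0):
    """Mean firing rate of the unit preferring numerosity ``i`` to the
    ``k``-th vibration in a sequence.

    The unit tuned to numerosity i responds to the k-th vibration with a
    Gaussian tuning curve on the log2 axis:

        rate = peak_rate * exp(-(log2 k - log2 i)^2 / (2 sd_tuning^2))

    Accepts scalars or arrays (broadcast).
    """
    i = np.asarray(i, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(i < 1) or np.any(k < 1):
        raise ValueError("preferred numerosity i and signal ordinal k must be >= 1")
    if not sd_tuning > 0:
        raise ValueError(f"sd_tuning must be > 0, got {sd_tuning}")
    if not peak_rate > 0:
        raise ValueError(f"peak_rate must be > 0, got {peak_rate}")
    d = np.log2(k) - np.log2(i)
    out = peak_rate * np.exp(-(d**2) / (2.0 * sd_tuning**2))
    return out if out.ndim else float(out)


def mean_rate_matrix(population: PopulationSpec, condition: StimulusCondition) -> np.ndarray:
    """Mean-rate matrix, shape (population size, n_vibrations)."""
    pref = np.asarray(population.preferred_numerosities, dtype=float)
    ordinals = np.arange(1, condition.n_vibrations + 1, dtype=float)
    return tuning_mean_rate(
        pref[:, None], ordinals[None, :], population.sd_tuning, population.peak_rate
    )


# ---------------------------------------------------------------------------
# Step 2/3 support: timing and window gains


def vibration_onsets(n: int, soa_ms: float) -> np.ndarray:
    """Onset times (ms) of ``n`` vibrations separated by ``soa_ms``.

    The last vibration starts at 0 ms; earlier ones at negative times.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not soa_ms > 0:
        raise ValueError(f"soa_ms must be > 0, got {soa_ms}")
    return soa_ms * (np.arange(n, dtype=float) - (n - 1))


def window_weights(onset_times_ms, sd_window_ms: float) -> np.ndarray:
    """Gaussian window gains at the given onset times; weight 1 at t=0."""
    if not sd_window_ms > 0:
        raise ValueError(f"sd_window_ms must be > 0, got {sd_window_ms}")
    t = np.asarray(onset_times_ms, dtype=float)
    return np.exp(-(t**2) / (2.0 * sd_window_ms**2))


# ---------------------------------------------------------------------------
# Step 2: Poisson population response


def sample_spike_matrix(
    population: PopulationSpec, condition: StimulusCondition, rng: np.random.Generator
) -> np.ndarray:
    """Draw one spike-count matrix, entry (i, k) ~ Poisson(mean rate i,k)."""
    return rng.poisson(mean_rate_matrix(population, condition))


# ---------------------------------------------------------------------------
# Step 3: gain by the temporal window and sum over vibrations


def integrate_response(spikes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-unit gained sums: s_i = sum_k w_k * counts[i, k]."""
    spikes = np.asarray(spikes, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if spikes.ndim != 2 or spikes.shape[-1] != weights.shape[-1]:
        raise ValueError(
            f"weights length {weights.shape[-1]} does not match "
            f"number of vibrations {spikes.shape[-1] if spikes.ndim == 2 else spikes.shape}"
        )
    return spikes @ weights


# ---------------------------------------------------------------------------
# Step 4: weighted-average decoding on the log2 axis


def decode_numerosity(integrated, preferred) -> float:
    """Decode numerosity N = 2^( sum_i (s_i / sum s) * log2 i ).

    Scale invariant in the integrated response; the result always lies
    within [min(preferred), max(preferred)].
    """
    s = np.asarray(integrated, dtype=float)
    pref = np.asarray(preferred, dtype=float)
    if s.shape != pref.shape:
        raise ValueError(f"integrated response shape {s.shape} != preferred shape {pref.shape}")
    if np.any(s < 0):
        raise ValueError("integrated response entries must be non-negative")
    total = s.sum()
    if not total > 0:
        raise DegenerateResponseError("all-zero integrated response cannot be decoded")
    return float(2.0 ** np.dot(s / total, np.log2(pref)))


# ---------------------------------------------------------------------------
# Steps 1-4 assembled: Monte-Carlo simulation and its noise-free oracle


def simulate_condition(
    params: ModelParams, condition: StimulusCondition, rng: np.random.Generator | None = None
) -> float:
    """Simulated numerosity report for one condition.

    Draws ``n_reps`` independent Poisson spike matrices, gains and sums
    each with the temporal window, averages the integrated responses
    element-wise across repetitions, and decodes once.

    Each repetition uses its own deterministic substream spawned from the
    seed, so the result does not depend on evaluation order.
    """
    if condition.n_vibrations < 2:
        raise ValueError("model simulation requires n_vibrations >= 2")
    rates = mean_rate_matrix(params.population, condition)
    w = window_weights(condition.onset_times_ms, params.window.sd_window_ms)
    if rng is None:
        streams = [np.random.default_rng(c) for c in np.random.SeedSequence(params.seed).spawn(params.n_reps)]
    else:
        streams = [rng] * params.n_reps
    acc = np.zeros(params.population.size)
    for stream in streams:
        acc += stream.poisson(rates) @ w
    return decode_numerosity(acc / params.n_reps, params.population.preferred_numerosities)


def oracle_expected_decode(params: ModelParams, condition: StimulusCondition) -> float:
    """Noise-free decoded numerosity: Poisson draws replaced by their means.

    This is the infinite-repetition limit of :func:`simulate_condition`
    and is fully deterministic.
    """
    if condition.n_vibrations < 2:
        raise ValueError("model simulation requires n_vibrations >= 2")
    rates = mean_rate_matrix(params.population, condition)
    w = window_weights(condition.onset_times_ms, params.window.sd_window_ms)
    return decode_numerosity(rates @ w, params.population.preferred_numerosities)
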