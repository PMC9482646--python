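"""Synthetic trial-level behavioral data for the vibration-counting task.

The generator emulates the study design end to end: five age bands, a
96-trial factorial per participant (4 SOAs x {0, 2..6} vibrations x 4
repetitions, the 16 zero-vibration trials acting as catch trials), and
response behavior driven by the population-coding model. Each band has
its own tuning-curve and temporal-window SD; the defaults make the
window broaden with age (largest in the 60s band), so underestimation
grows with the vibration count, shrinks with SOA, and is strongest in
the oldest band. A configurable fraction of participants is
"inattentive" and responds uniformly at random, tripping the catch-trial
and zero-report exclusion filters downstream.

Attentive responses: the model's noise-free decoded numerosity for the
trial's (band, SOA, number) cell, plus Gaussian response noise, rounded
and clipped to the 0..9 keypad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import SOA_LEVELS
from .fitting import ConditionTargets
from .popcode import (
    DESIGN_NUMBERS,
    DESIGN_SOAS_MS,
    ModelParams,
    PopulationSpec,
    StimulusCondition,
    TemporalWindow,
    oracle_expected_decode,
)

__all__ = ["SynthSpec", "generate_dataset", "generate_model_targets", "fixture_small"]

#: Study-like per-band model parameters: both SDs grow with age, the
#: temporal window most sharply in the 60s band.
DEFAULT_BAND_PARAMS: dict[int, tuple[float, float]] = {
    20: (0.45, 200.0),
    30: (0.50, 250.0),
    40: (0.55, 300.0),
    50: (0.60, 350.0),
    60: (0.65, 600.0),
}

#: Per-band sample sizes of the study.
STUDY_PARTICIPANTS: dict[int, int] = {20: 51, 30: 50, 40: 52, 50: 51, 60: 52}


@dataclass(frozen=True)
class SynthSpec:
    """Specification of one synthetic dataset.

    ``band_params`` maps each age band to its (sd_tuning, sd_window_ms).
    ``participants_per_band`` may be an int (same size everywhere) or a
    per-band mapping. ``inattentive_fraction`` — a single fraction or a
    per-band mapping — of each band's participants respond uniformly at
    random on every trial.
    """

    band_params: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_PARAMS)
    )
    participants_per_band: int | dict[int, int] = field(
        default_factory=lambda: dict(STUDY_PARTICIPANTS)
    )
    response_noise_sd: float = 0.5
    catch_correct_prob: float = 0.99
    inattentive_fraction: float | dict[int, float] = 0.14
    population_size: int = 10
    peak_rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.catch_correct_prob <= 1.0:
            raise ValueError("catch_correct_prob must be in [0, 1]")
        for frac in self.inattentive_fractions().values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("inattentive_fraction must be in [0, 1]")
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be >= 0")
        for band, n in self.band_sizes().items():
            if n < 1:
                raise ValueError(f"band {band}: participants per band must be >= 1")

    def band_sizes(self) -> dict[int, int]:
        if isinstance(self.participants_per_band, dict):
            return dict(self.participants_per_band)
        return {band: int(self.participants_per_band) for band in self.band_params}

    def inattentive_fractions(self) -> dict[int, float]:
        if isinstance(self.inattentive_fraction, dict):
            return dict(self.inattentive_fraction)
        return {band: float(self.inattentive_fraction) for band in self.band_params}


def generate_model_targets(
    sd_tuning: float,
    sd_window_ms: float,
    population_size: int = 10,
    peak_rate: float = 10.0,
) -> ConditionTargets:
    """Noise-free decoded numerosity for every cell of the design grid.

    Deterministic; used as ground-truth targets in parameter-recovery
    studies.
    """
    params = ModelParams(
        population=PopulationSpec.with_size(population_size, sd_tuning, peak_rate),
        window=TemporalWindow(sd_window_ms),
    )
    cells = {
        (float(soa), int(n)): oracle_expected_decode(params, StimulusCondition(n, soa))
        for soa in DESIGN_SOAS_MS
        for n in DESIGN_NUMBERS
    }
    return ConditionTargets(cells)


def _trial_list() -> pd.DataFrame:
    """The 96-trial factorial: 4 SOAs x {0, 2..6} x 4 repetitions."""
    rows = [
        {"soa_ms": soa, "n_actual": n}
        for soa in SOA_LEVELS
        for n in (0, *DESIGN_NUMBERS)
        for _ in range(4)
    ]
    return pd.DataFrame(rows)


def generate_dataset(spec: SynthSpec) -> pd.DataFrame:
    """Generate a full synthetic trial table (schema of ``read_trials``).

    A pure function of the spec (including its seed): identical specs
    yield identical tables. Trial order is shuffled per participant.
    """
    rng = np.random.default_rng(spec.seed)
    base = _trial_list()
    frames = []
    for band in sorted(spec.band_params):
        sd_tuning, sd_window = spec.band_params[band]
        decoded = {
            (soa, n): oracle_expected_decode(
                ModelParams(
                    population=PopulationSpec.with_size(
                        spec.population_size, sd_tuning, spec.peak_rate
                    ),
                    window=TemporalWindow(sd_window),
                ),
                StimulusCondition(n, soa),
            )
            for soa in SOA_LEVELS
            for n in DESIGN_NUMBERS
        }
        n_participants = spec.band_sizes()[band]
        n_inattentive = int(round(spec.inattentive_fractions()[band] * n_participants))
        inattentive = np.zeros(n_participants, dtype=bool)
        inattentive[rng.choice(n_participants, n_inattentive, replace=False)] = True
        for p in range(n_participants):
            trials = base.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
            n_trials = len(trials)
            if inattentive[p]:
                reported = rng.integers(0, 10, size=n_trials)
            else:
                mean_n = np.array(
                    [
                        0.0 if r.n_actual == 0 else decoded[(r.soa_ms, r.n_actual)]
                        for r in trials.itertuples()
                    ]
                )
                noisy = mean_n + rng.normal(0.0, spec.response_noise_sd, size=n_trials)
                reported = np.clip(np.rint(noisy), 0, 9).astype(int)
                is_catch = trials["n_actual"].to_numpy() == 0
                catch_ok = rng.random(n_trials) < spec.catch_correct_prob
                reported[is_catch & catch_ok] = 0
                lapse = is_catch & ~catch_ok
                reported[lapse] = rng.integers(1, 10, size=int(lapse.sum()))
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": f"S{band}_{p:03d}",
                        "age_band": band,
                        "trial_index": np.arange(1, n_trials + 1),
                        "soa_ms": trials["soa_ms"].to_numpy(),
                        "n_actual": trials["n_actual"].to_numpy(),
                        "n_reported": reported,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def fixture_small() -> pd.DataFrame:
    """Tiny deterministic trial table exercising every exclusion path.

    Four participants, 96 trials each (384 rows):

    * ``P_ok_a`` and ``P_ok_b`` — perfectly attentive, retained;
    * ``P_catch`` — misses 3 of 16 catch trials (13/16 correct, below
      the 15/16 bar), excluded as catch_fail;
    * ``P_zero`` — reports 0 on 5 of 80 vibration trials (6.25% > 5%),
      excluded as zero_report_fail.
    """
    base = _trial_list()
    frames = []
    for pid, band in (("P_ok_a", 20), ("P_ok_b", 60), ("P_catch", 30), ("P_zero", 40)):
        trials = base.copy()
        reported = trials["n_actual"].to_numpy().copy()  # veridical responding
        if pid == "P_catch":
            catch_idx = np.flatnonzero(trials["n_actual"].to_numpy() == 0)[:3]
            reported[catch_idx] = 1
        elif pid == "P_zero":
            vib_idx = np.flatnonzero(trials["n_actual"].to_numpy() > 0)[:5]
            reported[vib_idx] = 0
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "age_band": band,
                    "trial_index": np.arange(1, len(trials) + 1),
                    "soa_ms": trials["soa_ms"],
                    "n_actual": trials["n_actual"],
                    "n_reported": reported,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
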