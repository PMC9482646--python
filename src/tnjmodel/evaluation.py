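"""Model-data agreement: r², MSE, cross-validation, per-band reports.

Agreement between the 20 human condition means and the 20 simulated
values is summarized by the squared Pearson correlation (r²) and the
mean squared error. Generalization is probed by fivefold
cross-validation over the 20 design cells, iterated with different
random splits; per-age-band reports rerun the behavioral pipeline and
the fit separately for each band.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import apply_exclusions, condition_means
from .fitting import (
    ConditionTargets,
    FitConfig,
    FitFailureError,
    _simulate_cell,
    fit_once,
    objective_loss,
)

__all__ = ["r_squared", "mse", "crossval_5fold", "pooled_targets", "age_band_report"]


def r_squared(human, simulated) -> float:
    """Squared Pearson correlation between the per-cell mean vectors.

    Note this is the squared correlation, not the coefficient of
    determination: a constant offset between the vectors does not reduce
    it (the MSE does). Direction is lost by squaring; residuals preserve
    it.
    """
    x = np.asarray(human, dtype=float)
    y = np.asarray(simulated, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 cells")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def mse(human, simulated) -> float:
    """Mean squared per-cell difference."""
    x = np.asarray(human, dtype=float)
    y = np.asarray(simulated, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def pooled_targets(cond_means: pd.DataFrame) -> ConditionTargets:
    """Condition targets: mean over participants of the per-cell mean report."""
    pooled = cond_means.groupby(["soa_ms", "n_actual"])["mean_reported"].mean().reset_index()
    pooled = pooled.rename(columns={"mean_reported": "target_mean_reported"})
    return ConditionTargets.from_frame(pooled)


def crossval_5fold(
    targets: ConditionTargets,
    config: FitConfig,
    n_iterations: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fivefold cross-validation over the 20 design cells.

    Each iteration randomly partitions the cells into 5 folds of 4,
    fits the model on the 16 held-in cells (one optimization run per
    fold) and evaluates the held-out loss and, where defined, held-out
    r². Returns one row per (iteration, fold) with columns
    iteration, fold, train_loss, test_loss, test_r2. A failed fold fit
    yields NaN metrics for that fold; the CV continues.
    """
    keys = sorted(targets.cells)
    if len(keys) != 20:
        raise ValueError(f"cross-validation expects the full 20-cell design, got {len(keys)}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        perm = rng.permutation(len(keys))
        for fold in range(5):
            test_keys = [keys[i] for i in perm[fold * 4 : (fold + 1) * 4]]
            train_keys = [k for k in keys if k not in test_keys]
            run_seed = int(rng.integers(2**31))
            try:
                run = fit_once(targets.subset(train_keys), config, run_seed)
            except FitFailureError:
                rows.append(
                    {"iteration": it, "fold": fold, "train_loss": math.nan,
                     "test_loss": math.nan, "test_r2": math.nan}
                )
                continue
            test = targets.subset(test_keys)
            test_loss = objective_loss(run.sd_tuning, run.sd_window_ms, test, config, sim_seed=run_seed)
            sims, wants = [], []
            for (soa, n), t in test.cells.items():
                # same per-cell seed convention as objective_loss (common random numbers)
                cell_seed = (run_seed * 701 + int(soa) * 31 + n) % (2**31)
                sims.append(_simulate_cell(run.sd_tuning, run.sd_window_ms, soa, n, config, cell_seed))
                wants.append(t)
            try:
                test_r2 = r_squared(wants, sims)
            except ValueError:
                test_r2 = math.nan
            rows.append(
                {"iteration": it, "fold": fold, "train_loss": run.loss,
                 "test_loss": test_loss, "test_r2": test_r2}
            )
    return pd.DataFrame(rows)


def age_band_report(trials: pd.DataFrame, config: FitConfig) -> pd.DataFrame:
    """Exclusions, pooled targets and model fit per age band.

    Bands with fewer than 2 retained participants are skipped (reported
    with NaN metrics). Returns one row per band with fitted parameter
    summaries, r² and MSE between the band's human and simulated means.
    """
    from .fitting import fit_ensemble, predict_grid

    retained, report = apply_exclusions(trials)
    rows = []
    for band in sorted(retained["age_band"].unique()):
        band_trials = retained[retained["age_band"] == band]
        n_retained = band_trials["participant_id"].nunique()
        if n_retained < 2:
            rows.append({"age_band": band, "n_retained": n_retained})
            continue
        means = condition_means(band_trials)
        targets = pooled_targets(means)
        fit = fit_ensemble(targets, config)
        pred = predict_grid(fit.mean_sd_tuning, fit.mean_sd_window_ms, config)
        merged = targets.to_frame().merge(pred, on=["soa_ms", "n_actual"])
        rows.append(
            {
                "age_band": band,
                "n_retained": n_retained,
                "sd_tuning": fit.mean_sd_tuning,
                "sd_window_ms": fit.mean_sd_window_ms,
                "ci95_sd_tuning_low": fit.ci95_sd_tuning[0],
                "ci95_sd_tuning_high": fit.ci95_sd_tuning[1],
                "ci95_sd_window_low": fit.ci95_sd_window_ms[0],
                "ci95_sd_window_high": fit.ci95_sd_window_ms[1],
                "r_squared": r_squared(merged["target_mean_reported"], merged["n_simulated"]),
                "mse": mse(merged["target_mean_reported"], merged["n_simulated"]),
            }
        )
    return pd.DataFrame(rows)
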