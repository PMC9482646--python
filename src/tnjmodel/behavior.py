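"""Behavioral analysis of the temporal numerosity judgment experiment.

Trial-level data: each participant performs 96 trials — 4 SOAs (100, 150,
200, 250 ms) x 6 numbers of vibrations (0, 2, 3, 4, 5, 6) x 4 repetitions
— and reports the felt count on a ten-digit (0..9) keypad. Zero-vibration
trials are catch trials used to screen out inattentive participants.

This module ingests the trial table, applies the attention-based
exclusion filters, computes per-participant condition means and the
difference scores (reported - actual; negative = underestimation), runs
Holm-corrected one-sample t-tests with Cohen's d, and fits the three-way
mixed ANOVA (age band between; SOA and number within) with
Greenhouse-Geisser correction and generalized eta squared.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SchemaError",
    "DesignError",
    "TRIAL_COLUMNS",
    "AGE_BANDS",
    "SOA_LEVELS",
    "NUMBER_LEVELS",
    "read_trials",
    "validate_trials",
    "apply_exclusions",
    "condition_means",
    "one_sample_tests",
    "cohens_d_one_sample",
    "holm_adjust",
    "mixed_anova",
    "summarize_underestimation",
]

TRIAL_COLUMNS = ("participant_id", "age_band", "trial_index", "soa_ms", "n_actual", "n_reported")
AGE_BANDS = (20, 30, 40, 50, 60)
SOA_LEVELS = (100, 150, 200, 250)
NUMBER_LEVELS = (0, 2, 3, 4, 5, 6)  # 0 = catch trial
ANALYSIS_NUMBERS = (2, 3, 4, 5, 6)

TRIALS_PER_PARTICIPANT = 96  # 4 SOA x 6 numbers x 4 repetitions
CATCH_TRIALS = 16
VIBRATION_TRIALS = 80
MIN_CATCH_CORRECT = 15  # < 93.75% correct (15/16) excludes
MAX_ZERO_REPORTS = 4  # more than 5% (> 4/80) zero reports excludes


class SchemaError(ValueError):
    """Input table violates the trial schema."""


class DesignError(ValueError):
    """Data do not form the balanced design an operation requires."""


# ---------------------------------------------------------------------------
# Ingestion and validation


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    Expected columns: participant_id, age_band, trial_index, soa_ms,
    n_actual, n_reported. Malformed rows are reported with their
    (1-based, header-exclusive) line numbers.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    return validate_trials(df)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise SchemaError("trial table contains no rows")
    df = df.loc[:, list(TRIAL_COLUMNS)].copy()

    problems = []
    for col in ("age_band", "trial_index", "soa_ms", "n_actual", "n_reported"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            problems += [f"row {i + 1}: non-numeric {col}={df[col].iloc[i]!r}" for i in np.where(bad)[0][:5]]
        df[col] = vals

    checks = {
        "age_band": ~df["age_band"].isin(AGE_BANDS),
        "soa_ms": ~df["soa_ms"].isin(SOA_LEVELS),
        "n_actual": ~df["n_actual"].isin(NUMBER_LEVELS),
        "n_reported": ~df["n_reported"].isin(range(10)),
        "trial_index": ~df["trial_index"].between(1, TRIALS_PER_PARTICIPANT),
    }
    for col, bad in checks.items():
        bad = bad.fillna(False)
        if bad.any():
            problems += [
                f"row {i + 1}: {col}={df[col].iloc[i]!r} outside the design range"
                for i in np.where(bad.to_numpy())[0][:5]
            ]
    if problems:
        raise SchemaError("invalid trial rows:\n  " + "\n  ".join(problems))
    for col in ("age_band", "trial_index", "soa_ms", "n_actual", "n_reported"):
        df[col] = df[col].astype(int)
    return df


# ---------------------------------------------------------------------------
# Exclusions


def apply_exclusions(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the attention filters; return (retained trials, report).

    A participant is retained iff all of:

    * exactly 96 trials (otherwise reason ``incomplete``);
    * at least 15 of 16 catch trials answered exactly 0
      (otherwise ``catch_fail`` — catch accuracy below 93.75%);
    * at most 4 of the 80 vibration trials answered 0
      (otherwise ``zero_report_fail`` — zero reports on more than 5%
      of vibration trials; 4/80 = 5% exactly is still retained).

    The report has one row per participant: catch_correct, zero_reports,
    retained flag and reason (empty when retained).
    """
    rows = []
    for pid, grp in trials.groupby("participant_id", sort=False):
        catch = grp[grp["n_actual"] == 0]
        vib = grp[grp["n_actual"] > 0]
        catch_correct = int((catch["n_reported"] == 0).sum())
        zero_reports = int((vib["n_reported"] == 0).sum())
        if len(grp) != TRIALS_PER_PARTICIPANT:
            reason = "incomplete"
        elif catch_correct < MIN_CATCH_CORRECT:
            reason = "catch_fail"
        elif zero_reports > MAX_ZERO_REPORTS:
            reason = "zero_report_fail"
        else:
            reason = ""
        rows.append(
            {
                "participant_id": pid,
                "age_band": int(grp["age_band"].iloc[0]),
                "n_trials": len(grp),
                "catch_correct": catch_correct,
                "zero_reports": zero_reports,
                "retained": reason == "",
                "reason": reason,
            }
        )
    report = pd.DataFrame(rows)
    keep = set(report.loc[report["retained"], "participant_id"])
    retained = trials[trials["participant_id"].isin(keep)].copy()
    return retained, report


# ---------------------------------------------------------------------------
# Condition means and difference scores


def condition_means(retained: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean reported number in each of the 20 design cells.

    Catch trials are dropped; each (SOA, number) cell averages the 4
    repetitions. Columns: participant_id, age_band, soa_ms, n_actual,
    mean_reported, diff (= mean_reported - n_actual).
    """
    vib = retained[retained["n_actual"] > 0]
    means = (
        vib.groupby(["participant_id", "age_band", "soa_ms", "n_actual"], sort=True)["n_reported"]
        .mean()
        .rename("mean_reported")
        .reset_index()
    )
    counts = means.groupby("participant_id").size()
    bad = counts[counts != 20]
    if len(bad):
        raise DesignError(
            f"participants with incomplete condition grids (expected 20 cells): {dict(bad)}"
        )
    means["diff"] = means["mean_reported"] - means["n_actual"]
    return means


# ---------------------------------------------------------------------------
# One-sample tests, Cohen's d, Holm correction


def cohens_d_one_sample(sample: np.ndarray, mu: float = 0.0) -> float:
    """Cohen's d = (m - mu) / s with the sample SD on n-1 degrees of freedom."""
    sample = np.asarray(sample, dtype=float)
    s = sample.std(ddof=1)
    if s == 0:
        raise ZeroDivisionError("zero sample SD: Cohen's d undefined")
    return float((sample.mean() - mu) / s)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (wraps the standard implementation)."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def one_sample_tests(cond_means: pd.DataFrame, by_age_band: bool = False) -> pd.DataFrame:
    """Two-sided one-sample t-tests of the difference scores against 0.

    One test per design cell; the Holm family is the 20 cells of one
    panel — the whole sample, or each age band separately when
    ``by_age_band`` is set. Cells whose sample SD is zero get a
    ``degenerate`` flag (t, p, d undefined) and are excluded from the
    Holm family rather than silently dropped from the output.
    """
    group_cols = ["age_band", "soa_ms", "n_actual"] if by_age_band else ["soa_ms", "n_actual"]
    rows = []
    for keys, grp in cond_means.groupby(group_cols, sort=True):
        diffs = grp["diff"].to_numpy(dtype=float)
        if len(diffs) < 2:
            raise DesignError(f"cell {keys}: need >= 2 participants for a t-test")
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        row.update(n=len(diffs), mean_diff=float(diffs.mean()), sd_diff=float(diffs.std(ddof=1)))
        if row["sd_diff"] == 0:
            row.update(cohens_d=np.nan, t=np.nan, df=len(diffs) - 1, p_raw=np.nan, degenerate=True)
        else:
            t, p = stats.ttest_1samp(diffs, 0.0)
            row.update(
                cohens_d=cohens_d_one_sample(diffs),
                t=float(t),
                df=len(diffs) - 1,
                p_raw=float(p),
                degenerate=False,
            )
        rows.append(row)
    result = pd.DataFrame(rows)
    result["p_holm"] = np.nan
    family_cols = ["age_band"] if by_age_band else []
    for _, idx in result.groupby(family_cols)["p_raw"] if family_cols else [(None, result["p_raw"])]:
        ok = idx.notna()
        if ok.any():
            result.loc[idx.index[ok], "p_holm"] = holm_adjust(idx[ok])
    return result


# ---------------------------------------------------------------------------
# Three-way mixed ANOVA (between: age band; within: SOA, number)


def _orthonormal_contrasts(n_levels: int) -> np.ndarray:
    """Orthonormal contrast matrix, shape (n_levels, n_levels-1), columns
    orthogonal to the constant vector (Helmert basis, normalized)."""
    h = np.zeros((n_levels, n_levels - 1))
    for j in range(1, n_levels):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def _gg_epsilon(z_by_group: list[np.ndarray], d: int) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance
    of orthonormal contrast scores (d = effect degrees of freedom)."""
    n_total = sum(len(z) for z in z_by_group)
    pooled = np.zeros((d, d))
    for z in z_by_group:
        dev = z - z.mean(axis=0)
        pooled += dev.T @ dev
    pooled /= n_total - len(z_by_group)
    denom = d * np.trace(pooled @ pooled)
    if denom == 0:  # degenerate (e.g. constant data): no sphericity to correct
        return 1.0
    eps = np.trace(pooled) ** 2 / denom
    return float(min(1.0, eps))


def mixed_anova(cond_means: pd.DataFrame, value: str = "mean_reported") -> pd.DataFrame:
    """Three-way mixed ANOVA: A = age band (between), B = SOA, C = number
    of vibrations (both within).

    Works on the 20-cell condition-mean table (balanced within design;
    unequal group sizes allowed). Within-subject sums of squares are
    computed by projecting each participant's cell vector onto
    orthonormal contrast bases — exact for balanced-within data.
    Greenhouse-Geisser epsilon (from the pooled within-group covariance
    of the contrast scores) rescales the degrees of freedom of within
    effects; F ratios are unchanged by the correction. Generalized eta
    squared uses all subject-stratum error terms in the denominator.

    Returns a table with one row per effect (A, B, C, A x B, A x C,
    B x C, A x B x C) and per error stratum, with columns
    SS, df, df_gg, MS, F, p, eta_g, epsilon.
    """
    pivot = cond_means.pivot_table(
        index=["participant_id", "age_band"], columns=["soa_ms", "n_actual"], values=value
    )
    if pivot.isna().any().any():
        raise DesignError("within-design is unbalanced: missing condition cells")
    b_levels = sorted({c[0] for c in pivot.columns})
    c_levels = sorted({c[1] for c in pivot.columns})
    b, c = len(b_levels), len(c_levels)
    pivot = pivot.loc[:, list(itertools.product(b_levels, c_levels))]
    bands = pivot.index.get_level_values("age_band").to_numpy()
    groups = sorted(set(bands))
    n_g = np.array([(bands == g).sum() for g in groups])
    if (n_g < 2).any():
        raise DesignError("each age band needs >= 2 participants")
    y = pivot.to_numpy(dtype=float)  # (N, b*c), cells ordered B-major
    n_total, n_cells = y.shape

    hb = _orthonormal_contrasts(b)
    hc = _orthonormal_contrasts(c)
    ones_b = np.full((b, 1), b**-0.5)
    ones_c = np.full((c, 1), c**-0.5)
    bases = {
        "B": np.kron(hb, ones_c),
        "C": np.kron(ones_b, hc),
        "B x C": np.kron(hb, hc),
    }

    # between stratum: per-subject scores on the constant direction
    u = y @ np.full(n_cells, n_cells**-0.5)
    grand = u.mean()
    group_means = np.array([u[bands == g].mean() for g in groups])
    ss_a = float(np.sum(n_g * (group_means - grand) ** 2))
    ss_s = float(sum(np.sum((u[bands == g] - gm) ** 2) for g, gm in zip(groups, group_means)))

    effects: dict[str, dict] = {"A": {"ss": ss_a, "df": len(groups) - 1}}
    errors: dict[str, dict] = {"s(A)": {"ss": ss_s, "df": n_total - len(groups)}}
    for name, m in bases.items():
        d = m.shape[1]
        z = y @ m  # (N, d) contrast scores
        zbar = z.mean(axis=0)
        z_groups = [z[bands == g] for g in groups]
        gmeans = np.array([zg.mean(axis=0) for zg in z_groups])
        ss_main = float(n_total * zbar @ zbar)
        ss_inter = float(np.sum(n_g[:, None] * (gmeans - zbar) ** 2))
        ss_err = float(sum(np.sum((zg - gm) ** 2) for zg, gm in zip(z_groups, gmeans)))
        eps = _gg_epsilon(z_groups, d)
        effects[name] = {"ss": ss_main, "df": d, "eps": eps}
        effects[f"A x {name}"] = {"ss": ss_inter, "df": (len(groups) - 1) * d, "eps": eps}
        errors[f"s(A) x {name}"] = {"ss": ss_err, "df": (n_total - len(groups)) * d, "eps": eps}

    error_of = {
        "A": "s(A)",
        "B": "s(A) x B",
        "A x B": "s(A) x B",
        "C": "s(A) x C",
        "A x C": "s(A) x C",
        "B x C": "s(A) x B x C",
        "A x B x C": "s(A) x B x C",
    }
    ss_error_total = sum(e["ss"] for e in errors.values())

    order = ["A", "B", "A x B", "C", "A x C", "B x C", "A x B x C"]
    rows = []
    for name in order:
        eff = effects[name]
        err = errors[error_of[name]]
        eps = eff.get("eps", 1.0)
        df_gg = eff["df"] * eps
        df_err_gg = err["df"] * eps
        ms = eff["ss"] / df_gg
        ms_err = err["ss"] / df_err_gg
        if ms_err == 0:
            f_ratio = 0.0 if ms == 0 else math.inf
        else:
            f_ratio = ms / ms_err
        p = float(stats.f.sf(f_ratio, df_gg, df_err_gg))
        rows.append(
            {
                "effect": name,
                "SS": eff["ss"],
                "df": eff["df"],
                "df_gg": df_gg,
                "MS": ms,
                "F": f_ratio,
                "p": p,
                "eta_g": eff["ss"] / (eff["ss"] + ss_error_total),
                "epsilon": eps,
                "error_term": error_of[name],
            }
        )
        err_key = error_of[name]
        if not any(r["effect"] == err_key for r in rows):
            rows.append(
                {
                    "effect": err_key,
                    "SS": err["ss"],
                    "df": err["df"],
                    "df_gg": df_err_gg,
                    "MS": ms_err,
                    "F": np.nan,
                    "p": np.nan,
                    "eta_g": np.nan,
                    "epsilon": errors[err_key].get("eps", 1.0),
                    "error_term": "",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summary table for the underestimation heatmaps


def summarize_underestimation(cond_means: pd.DataFrame, by_age_band: bool = False) -> pd.DataFrame:
    """Per-cell group mean difference with 95% CI and Cohen's d.

    Single-participant groups get NaN CI bounds and d (flagged via the
    ``n`` column), never a silent drop.
    """
    group_cols = ["age_band", "soa_ms", "n_actual"] if by_age_band else ["soa_ms", "n_actual"]
    rows = []
    for keys, grp in cond_means.groupby(group_cols, sort=True):
        diffs = grp["diff"].to_numpy(dtype=float)
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        row.update(n=len(diffs), mean_diff=float(diffs.mean()))
        if len(diffs) < 2:
            row.update(ci95_low=np.nan, ci95_high=np.nan, cohens_d=np.nan)
        else:
            sem = stats.sem(diffs)
            half = stats.t.ppf(0.975, len(diffs) - 1) * sem if sem > 0 else 0.0
            sd = diffs.std(ddof=1)
            row.update(
                ci95_low=row["mean_diff"] - float(half),
                ci95_high=row["mean_diff"] + float(half),
                cohens_d=float(diffs.mean() / sd) if sd > 0 else np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)
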