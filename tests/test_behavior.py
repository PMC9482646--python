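"""Tests for the behavioral pipeline: ingestion, exclusions, statistics."""

import io

import numpy as np
import pandas as pd
import pytest

from tnjmodel import (
    DesignError,
    SchemaError,
    apply_exclusions,
    cohens_d_one_sample,
    condition_means,
    holm_adjust,
    mixed_anova,
    one_sample_tests,
    read_trials,
    summarize_underestimation,
)
from tnjmodel.behavior import validate_trials


class TestReadTrials:
    def test_row_count_roundtrip(self, small_trials, tmp_path):
        path = tmp_path / "trials.csv"
        small_trials.to_csv(path, index=False)
        df = read_trials(path)
        assert len(df) == 384
        assert df["participant_id"].nunique() == 4

    def test_out_of_range_report_named_in_error(self, small_trials):
        bad = small_trials.copy()
        bad.loc[10, "n_reported"] = 12
        with pytest.raises(SchemaError, match="row 11"):
            validate_trials(bad)

    def test_missing_column(self, small_trials):
        with pytest.raises(SchemaError, match="missing required columns"):
            validate_trials(small_trials.drop(columns=["soa_ms"]))

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError):
            read_trials(path)

    def test_invalid_soa_rejected(self, small_trials):
        bad = small_trials.copy()
        bad.loc[3, "soa_ms"] = 175
        with pytest.raises(SchemaError, match="soa_ms"):
            validate_trials(bad)


class TestExclusions:
    def test_fixture_partition(self, small_trials):
        retained, report = apply_exclusions(small_trials)
        assert len(report) == 4
        assert report["retained"].sum() == 2
        assert retained["participant_id"].nunique() == 2
        # every participant exactly once in retained or excluded
        assert set(report["participant_id"]) == set(small_trials["participant_id"])
        reasons = dict(zip(report["participant_id"], report["reason"]))
        assert reasons["P_catch"] == "catch_fail"
        assert reasons["P_zero"] == "zero_report_fail"
        assert reasons["P_ok_a"] == "" and reasons["P_ok_b"] == ""

    def test_boundary_15_of_16_catch_retained(self, small_trials):
        trials = small_trials[small_trials["participant_id"] == "P_ok_a"].copy()
        catch_idx = trials.index[trials["n_actual"] == 0][:1]
        trials.loc[catch_idx, "n_reported"] = 3  # 15/16 correct: retained
        _, report = apply_exclusions(trials)
        assert bool(report["retained"].iloc[0])

    def test_boundary_14_of_16_catch_excluded(self, small_trials):
        trials = small_trials[small_trials["participant_id"] == "P_ok_a"].copy()
        catch_idx = trials.index[trials["n_actual"] == 0][:2]
        trials.loc[catch_idx, "n_reported"] = 3  # 14/16 = 87.5% correct
        _, report = apply_exclusions(trials)
        assert report["reason"].iloc[0] == "catch_fail"

    def test_boundary_4_of_80_zero_reports_retained(self, small_trials):
        trials = small_trials[small_trials["participant_id"] == "P_ok_a"].copy()
        vib_idx = trials.index[trials["n_actual"] > 0][:4]
        trials.loc[vib_idx, "n_reported"] = 0  # exactly 5%: retained
        _, report = apply_exclusions(trials)
        assert bool(report["retained"].iloc[0])

    def test_boundary_5_of_80_zero_reports_excluded(self, small_trials):
        trials = small_trials[small_trials["participant_id"] == "P_ok_a"].copy()
        vib_idx = trials.index[trials["n_actual"] > 0][:5]
        trials.loc[vib_idx, "n_reported"] = 0  # 6.25% > 5%
        _, report = apply_exclusions(trials)
        assert report["reason"].iloc[0] == "zero_report_fail"

    def test_incomplete_participant(self, small_trials):
        trials = pd.concat(
            [small_trials[small_trials["participant_id"] != "P_ok_a"],
             small_trials[small_trials["participant_id"] == "P_ok_a"].iloc[:95]]
        )
        _, report = apply_exclusions(trials)
        reasons = dict(zip(report["participant_id"], report["reason"]))
        assert reasons["P_ok_a"] == "incomplete"


class TestConditionMeans:
    def test_twenty_cells_per_participant(self, small_trials):
        retained, _ = apply_exclusions(small_trials)
        means = condition_means(retained)
        assert (means.groupby("participant_id").size() == 20).all()

    def test_hand_means_and_difference(self):
        rows = []
        for soa in (100, 150, 200, 250):
            for n in (2, 3, 4, 5, 6):
                for rep, rep_val in enumerate((2, 3, 4, 5)):
                    rows.append(
                        dict(participant_id="p", age_band=20, trial_index=0,
                             soa_ms=soa, n_actual=n, n_reported=rep_val)
                    )
        means = condition_means(pd.DataFrame(rows))
        assert (means["mean_reported"] == 3.5).all()
        cell = means[(means.soa_ms == 100) & (means.n_actual == 5)]
        assert cell["diff"].iloc[0] == pytest.approx(-1.5)

    def test_missing_cell_raises(self, small_trials):
        retained, _ = apply_exclusions(small_trials)
        broken = retained[~((retained.n_actual == 3) & (retained.soa_ms == 150)
                            & (retained.participant_id == "P_ok_a"))]
        with pytest.raises(DesignError):
            condition_means(broken)


class TestTTestsAndEffectSizes:
    def test_cohens_d_hand_example(self):
        assert cohens_d_one_sample(np.array([1.0, 2.0, 3.0])) == pytest.approx(2.0)

    def test_cohens_d_sign_follows_mean(self, rng):
        x = rng.normal(-0.5, 1.0, 50)
        assert np.sign(cohens_d_one_sample(x)) == np.sign(x.mean())

    def test_cohens_d_zero_sd(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d_one_sample(np.array([1.0, 1.0]))

    def test_holm_hand_stepped_sequence(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_holm_properties(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert adj[order[0]] == pytest.approx(min(1.0, p[order[0]] * len(p)))

    def test_symmetric_sample_t_zero(self):
        cm = pd.DataFrame(
            [
                dict(participant_id=p, age_band=20, soa_ms=soa, n_actual=n,
                     mean_reported=n + d, diff=d)
                for p, d in (("a", -1.0), ("b", 1.0))
                for soa in (100, 150)
                for n in (2, 3)
            ]
        )
        res = one_sample_tests(cm)
        np.testing.assert_allclose(res["t"], 0.0)
        np.testing.assert_allclose(res["p_raw"], 1.0)

    def test_family_is_per_panel(self, clean_study_trials):
        retained, _ = apply_exclusions(clean_study_trials)
        means = condition_means(retained)
        pooled = one_sample_tests(means)
        assert len(pooled) == 20
        per_band = one_sample_tests(means, by_age_band=True)
        assert len(per_band) == 100
        # Holm adjustment is applied within each band's 20 cells
        for _, grp in per_band.groupby("age_band"):
            smallest = grp["p_raw"].min()
            assert grp["p_holm"].min() == pytest.approx(min(1.0, smallest * 20))

    def test_zero_sd_cell_flagged_not_dropped(self):
        cm = pd.DataFrame(
            [
                dict(participant_id=p, age_band=20, soa_ms=soa, n_actual=n,
                     mean_reported=float(n), diff=0.0)
                for p in ("a", "b", "c")
                for soa in (100, 150)
                for n in (2, 3)
            ]
        )
        res = one_sample_tests(cm)
        assert res["degenerate"].all()
        assert len(res) == 4


class TestMixedAnova:
    @staticmethod
    def _toy(rng, n_per_group=4, groups=(20, 30, 40), b_levels=(100, 150), c_levels=(2, 3)):
        rows = []
        for gi, band in enumerate(groups):
            for s in range(n_per_group):
                pid = f"g{gi}s{s}"
                base = rng.normal(gi * 0.5, 1.0)
                for bi, soa in enumerate(b_levels):
                    for ci, n in enumerate(c_levels):
                        y = base + 0.8 * bi + 0.4 * ci + 0.3 * bi * ci + rng.normal(0, 0.5)
                        rows.append(dict(participant_id=pid, age_band=band, soa_ms=soa,
                                         n_actual=n, mean_reported=y))
        df = pd.DataFrame(rows)
        df["diff"] = df["mean_reported"] - df["n_actual"]
        return df

    @staticmethod
    def _brute_force_ss(cm):
        """Sums of squares from marginal means, textbook formulas
        (balanced design only)."""
        y = cm.pivot_table(index=["participant_id", "age_band"],
                           columns=["soa_ms", "n_actual"], values="mean_reported")
        bands = y.index.get_level_values("age_band").to_numpy()
        arr = y.to_numpy()
        groups = sorted(set(bands))
        b_levels = sorted({c[0] for c in y.columns})
        c_levels = sorted({c[1] for c in y.columns})
        a, b, c = len(groups), len(b_levels), len(c_levels)
        n = (bands == groups[0]).sum()
        N = len(arr)
        cube = arr.reshape(N, b, c)  # columns are (soa, n) sorted pairs
        grand = cube.mean()
        g_of = np.array([groups.index(x) for x in bands])
        m_g = np.array([cube[g_of == g].mean() for g in range(a)])
        m_b = cube.mean(axis=(0, 2))
        m_c = cube.mean(axis=(0, 1))
        m_gb = np.array([cube[g_of == g].mean(axis=(0, 2)) for g in range(a)])
        m_gc = np.array([cube[g_of == g].mean(axis=(0, 1)) for g in range(a)])
        m_bc = cube.mean(axis=0)
        m_gbc = np.array([cube[g_of == g].mean(axis=0) for g in range(a)])
        m_s = cube.mean(axis=(1, 2))
        ss = {}
        ss["A"] = n * b * c * np.sum((m_g - grand) ** 2)
        ss["s(A)"] = b * c * np.sum((m_s - m_g[g_of]) ** 2)
        ss["B"] = N * c * np.sum((m_b - grand) ** 2)
        ss["C"] = N * b * np.sum((m_c - grand) ** 2)
        ss["A x B"] = n * c * np.sum(
            (m_gb - m_g[:, None] - m_b[None, :] + grand) ** 2
        )
        ss["A x C"] = n * b * np.sum(
            (m_gc - m_g[:, None] - m_c[None, :] + grand) ** 2
        )
        ss["B x C"] = N * np.sum(
            (m_bc - m_b[:, None] - m_c[None, :] + grand) ** 2
        )
        ss["A x B x C"] = n * np.sum(
            (
                m_gbc
                - m_gb[:, :, None]
                - m_gc[:, None, :]
                - m_bc[None, :, :]
                + m_g[:, None, None]
                + m_b[None, :, None]
                + m_c[None, None, :]
                - grand
            )
            ** 2
        )
        return ss

    def test_agrees_with_brute_force_oracle(self, rng):
        cm = self._toy(rng)
        table = mixed_anova(cm).set_index("effect")
        oracle = self._brute_force_ss(cm)
        for effect, ss in oracle.items():
            assert table.loc[effect, "SS"] == pytest.approx(ss, abs=1e-8), effect

    def test_f_from_brute_force_ss(self, rng):
        cm = self._toy(rng, n_per_group=5)
        table = mixed_anova(cm).set_index("effect")
        oracle = self._brute_force_ss(cm)
        a, b, c, n = 3, 2, 2, 5
        N = a * n
        dfs = {"A": a - 1, "B": b - 1, "C": c - 1, "A x B": (a - 1) * (b - 1),
               "A x C": (a - 1) * (c - 1), "B x C": (b - 1) * (c - 1),
               "A x B x C": (a - 1) * (b - 1) * (c - 1)}
        # error strata SS are taken from the table (their partition is
        # checked by test_ss_additivity_balanced); effect SS and hence F
        # come from the independent marginal-mean oracle
        for effect in ("A", "B", "C", "A x B", "A x C", "B x C", "A x B x C"):
            err_name = table.loc[effect, "error_term"]
            ms_eff = oracle[effect] / dfs[effect]
            ms_err = table.loc[err_name, "SS"] / table.loc[err_name, "df"]
            assert table.loc[effect, "F"] == pytest.approx(ms_eff / ms_err, abs=1e-8)

    def test_constant_data_all_zero_f(self):
        cm = pd.DataFrame(
            [
                dict(participant_id=f"p{p}", age_band=band, soa_ms=soa, n_actual=n,
                     mean_reported=3.0)
                for band in (20, 30)
                for p in (f"{band}a", f"{band}b", f"{band}c")
                for soa in (100, 150)
                for n in (2, 3)
            ]
        )
        table = mixed_anova(cm).set_index("effect")
        for effect in ("A", "B", "C", "A x B", "B x C"):
            assert table.loc[effect, "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_groups_zero_between_f(self, rng):
        cm1 = self._toy(rng, groups=(20,))
        cm2 = cm1.copy()
        cm2["age_band"] = 30
        cm2["participant_id"] = cm2["participant_id"] + "_b"
        table = mixed_anova(pd.concat([cm1, cm2])).set_index("effect")
        assert table.loc["A", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_gg_epsilon_range_and_f_unchanged(self, clean_study_trials):
        retained, _ = apply_exclusions(clean_study_trials)
        means = condition_means(retained)
        table = mixed_anova(means).set_index("effect")
        for effect, levels in (("B", 4), ("C", 5), ("B x C", 12)):
            eps = table.loc[effect, "epsilon"]
            assert 1.0 / levels < eps <= 1.0
            # F is SS_eff/df_eff over SS_err/df_err; epsilon cancels
            err = table.loc[effect, "error_term"]
            f_uncorrected = (table.loc[effect, "SS"] / table.loc[effect, "df"]) / (
                table.loc[err, "SS"] / table.loc[err, "df"]
            )
            assert table.loc[effect, "F"] == pytest.approx(f_uncorrected, rel=1e-12)

    def test_ss_additivity_balanced(self, rng):
        cm = self._toy(rng)
        table = mixed_anova(cm)
        y = cm.pivot_table(index=["participant_id", "age_band"],
                           columns=["soa_ms", "n_actual"], values="mean_reported").to_numpy()
        total = np.sum((y - y.mean()) ** 2)
        assert table["SS"].sum() == pytest.approx(total, rel=1e-10)

    def test_unbalanced_within_rejected(self, rng):
        cm = self._toy(rng)
        broken = cm.drop(cm.index[0])
        with pytest.raises(DesignError):
            mixed_anova(broken)


class TestSummaries:
    def test_constant_differences(self):
        cm = pd.DataFrame(
            [
                dict(participant_id=p, age_band=20, soa_ms=100, n_actual=4,
                     mean_reported=3.5, diff=-0.5)
                for p in ("a", "b", "c")
            ]
        )
        res = summarize_underestimation(cm)
        assert res["mean_diff"].iloc[0] == pytest.approx(-0.5)
        assert res["ci95_low"].iloc[0] == pytest.approx(-0.5)
        assert res["ci95_high"].iloc[0] == pytest.approx(-0.5)

    def test_single_participant_ci_undefined(self):
        cm = pd.DataFrame(
            [dict(participant_id="a", age_band=20, soa_ms=100, n_actual=4,
                  mean_reported=3.5, diff=-0.5)]
        )
        res = summarize_underestimation(cm)
        assert res["n"].iloc[0] == 1
        assert np.isnan(res["ci95_low"].iloc[0])

    def test_wider_window_band_underestimates_more(self):
        from tnjmodel import SynthSpec, generate_dataset

        spec = SynthSpec(
            band_params={20: (0.5, 200.0), 60: (0.5, 600.0)},
            participants_per_band=8,
            inattentive_fraction=0.0,
            catch_correct_prob=1.0,
            seed=9,
        )
        retained, _ = apply_exclusions(generate_dataset(spec))
        means = condition_means(retained)
        res = summarize_underestimation(means, by_age_band=True)
        cell = res[(res.soa_ms == 100) & (res.n_actual == 6)].set_index("age_band")
        assert abs(cell.loc[60, "mean_diff"]) > abs(cell.loc[20, "mean_diff"])
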