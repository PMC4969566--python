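"""Cohort table validation and repeated-measures comparisons.

The brute-force oracle below computes the same sequential (Type-I)
decomposition as the library routine but by explicit dummy-design least
squares, sharing no code with the statsmodels-backed implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegkappa import (
    CohortTable,
    DegenerateDataError,
    InputError,
    ParameterError,
    bonferroni,
    compare_all,
    rm_anova,
)
from eegkappa.stats import AnovaResult


def brute_force_anova(y, state, subject):
    """Sequential SS by explicit projections: state first, then subject."""
    y = np.asarray(y, dtype=float)
    state = np.asarray(state)
    subject = np.asarray(subject)

    def rss(cols):
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ones = np.ones_like(y)
    s_cols = [(state == s).astype(float) for s in np.unique(state)[1:]]
    b_cols = [(subject == s).astype(float) for s in np.unique(subject)[1:]]
    ss_state = rss([ones]) - rss([ones, *s_cols])
    ss_error = rss([ones, *s_cols, *b_cols])
    df_num = len(s_cols)
    df_den = y.size - 1 - df_num - len(b_cols)
    f = (ss_state / df_num) / (ss_error / df_den)
    return f, float(sps.f.sf(f, df_num, df_den)), df_den


def make_table(y, state, subject):
    rows = [
        dict(
            subject_id=s,
            state=st,
            segment_id=f"g{i}",
            delta_t_s=0.004,
            metric_name="kappa_avg",
            metric_value=v,
        )
        for i, (v, st, s) in enumerate(zip(y, state, subject))
    ]
    return CohortTable(pd.DataFrame(rows))


def random_table(rng, n_subjects, n_segments, effect=0.0, subject_sd=0.5):
    y, state, subject = [], [], []
    for s in range(n_subjects):
        bump = rng.normal(0, subject_sd)
        for st, mu in [("A", 0.0), ("B", effect)]:
            for _ in range(n_segments):
                y.append(mu + bump + rng.normal())
                state.append(st)
                subject.append(f"s{s}")
    return np.array(y), np.array(state), np.array(subject)


class TestRmAnova:
    def test_identical_states_give_null_f(self):
        # same value in both states for every subject/segment
        y, state, subject = [], [], []
        for s in range(3):
            for st in ("A", "B"):
                for g, v in enumerate([1.0 + s, 2.0 + s]):
                    y.append(v)
                    state.append(st)
                    subject.append(f"s{s}")
        r = rm_anova(make_table(y, state, subject), "A", "B", 0.004, "kappa_avg")
        assert r.f_stat == 0.0
        assert r.p_raw == 1.0

    def test_crafted_table_matches_brute_force(self, rng):
        y, state, subject = random_table(rng, 3, 2, effect=1.0)
        r = rm_anova(make_table(y, state, subject), "A", "B", 0.004, "kappa_avg")
        f, p, df_den = brute_force_anova(y, state, subject)
        assert r.f_stat == pytest.approx(f, rel=1e-10)
        assert r.p_raw == pytest.approx(p, rel=1e-10)
        assert (r.df_num, r.df_den) == (1, df_den)

    def test_oracle_equivalence_over_random_small_tables(self, rng):
        for _ in range(100):
            n_sub = int(rng.integers(2, 6))
            n_seg = int(rng.integers(1, 5))
            if n_sub * n_seg * 2 - 1 - 1 - (n_sub - 1) < 1:
                continue
            y, state, subject = random_table(
                rng, n_sub, n_seg, effect=float(rng.normal(0, 1))
            )
            r = rm_anova(make_table(y, state, subject), "A", "B", 0.004, "kappa_avg")
            f, p, _ = brute_force_anova(y, state, subject)
            assert r.f_stat == pytest.approx(f, rel=1e-10, abs=1e-12)
            assert r.p_raw == pytest.approx(p, rel=1e-10, abs=1e-12)

    def test_unbalanced_subject_retained_with_warning(self, rng, caplog):
        y, state, subject = random_table(rng, 4, 2)
        keep = ~((subject == "s3") & (state == "B"))  # s3 missing state B
        with caplog.at_level("WARNING", logger="eegkappa.stats"):
            r = rm_anova(
                make_table(y[keep], state[keep], subject[keep]),
                "A", "B", 0.004, "kappa_avg",
            )
        assert any("unbalanced" in m for m in caplog.messages)
        f, p, df_den = brute_force_anova(y[keep], state[keep], subject[keep])
        assert r.f_stat == pytest.approx(f, rel=1e-10)
        assert r.df_den == df_den

    def test_missing_state_rejected(self, rng):
        y, state, subject = random_table(rng, 3, 2)
        with pytest.raises(DegenerateDataError, match="no data"):
            rm_anova(make_table(y, state, subject), "A", "C", 0.004, "kappa_avg")

    def test_null_permutation_p_values_uniform(self, rng):
        """Shuffling state labels within subject gives uniform p (KS at 0.01)."""
        y, state, subject = random_table(rng, 8, 4, effect=0.0, subject_sd=1.0)
        ps = []
        for _ in range(500):
            perm = state.copy()
            for s in np.unique(subject):
                idx = np.where(subject == s)[0]
                perm[idx] = rng.permutation(perm[idx])
            f, p, _ = brute_force_anova(y, perm, subject)
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestBonferroni:
    def _res(self, p):
        return AnovaResult(
            f_stat=1.0, df_num=1, df_den=10, p_raw=p, p_adjusted=None,
            state_a="A", state_b="B", delta_t_s=0.004, metric="kappa_avg",
        )

    @pytest.mark.parametrize(
        "p_raw,m,expected",
        [(0.004, 8, 0.032), (0.5, 8, 1.0), (0.2, 1, 0.2)],
    )
    def test_adjustment_arithmetic(self, p_raw, m, expected):
        out = bonferroni([self._res(p_raw)], m)
        assert out[0].p_adjusted == pytest.approx(expected)

    def test_auto_family_size_and_monotonicity(self, rng):
        results = [self._res(float(p)) for p in rng.uniform(0, 0.3, 6)]
        out = bonferroni(results, "auto")
        for before, after in zip(results, out):
            assert after.p_adjusted == pytest.approx(min(1.0, 6 * before.p_raw))
            assert after.p_adjusted >= before.p_raw

    def test_invalid_family_size(self):
        with pytest.raises(ParameterError):
            bonferroni([self._res(0.1)], 0)


class TestCompareAll:
    @staticmethod
    def _cohort_frame(rng, shift_cell=None):
        rows = []
        for s in range(4):
            bump = rng.normal(0, 0.2)
            for st in ("A", "B"):
                for g in range(3):
                    for dt in (0.004, 0.04):
                        for metric in ("kappa_avg", "low_it_fraction"):
                            v = bump + rng.normal(0, 0.3)
                            if shift_cell and (st, dt, metric) == shift_cell:
                                v += 4.0
                            rows.append(
                                dict(
                                    subject_id=f"s{s}", state=st,
                                    segment_id=f"g{g}", delta_t_s=dt,
                                    metric_name=metric, metric_value=v,
                                )
                            )
        return pd.DataFrame(rows)

    def test_grid_shape_and_schema(self, rng):
        table = CohortTable(self._cohort_frame(rng))
        rep = compare_all(table, "A")
        assert len(rep.results) == 1 * 2 * 2  # states x delta_ts x metrics
        assert list(rep.results.columns) == [
            "comparison", "delta_t_s", "metric", "mean_a", "sd_a",
            "mean_b", "sd_b", "F", "df_num", "df_den", "p_raw", "p_adjusted",
        ]

    def test_shifted_cell_is_the_only_significant_one(self, rng):
        cell = ("B", 0.04, "kappa_avg")
        table = CohortTable(self._cohort_frame(rng, shift_cell=cell))
        rep = compare_all(table, "A")
        sig = rep.results[rep.results["p_adjusted"] < 0.01]
        assert len(sig) == 1
        assert sig.iloc[0]["metric"] == "kappa_avg"
        assert sig.iloc[0]["delta_t_s"] == pytest.approx(0.04)

    def test_single_state_reports_means_without_comparisons(self, rng):
        frame = self._cohort_frame(rng)
        table = CohortTable(frame[frame["state"] == "A"])
        rep = compare_all(table, "A")
        assert rep.results.empty
        assert not rep.group_stats.empty
        assert {"mean", "sd", "n"} <= set(rep.group_stats.columns)

    def test_missing_baseline_rejected(self, rng):
        table = CohortTable(self._cohort_frame(rng))
        with pytest.raises(DegenerateDataError, match="baseline"):
            compare_all(table, "Z")


class TestCohortTable:
    def test_duplicate_keys_rejected(self):
        row = dict(
            subject_id="s0", state="A", segment_id="g0", delta_t_s=0.004,
            metric_name="kappa_avg", metric_value=1.0,
        )
        with pytest.raises(InputError, match="duplicate"):
            CohortTable(pd.DataFrame([row, row]))

    def test_from_summary_frame_melts_metrics(self):
        wide = pd.DataFrame(
            [
                dict(
                    subject_id="s0", state="A", segment_id="g0", delta_t_s=0.004,
                    kappa_avg=1.0, low_it_fraction=0.1, n_values=100,
                )
            ]
        )
        table = CohortTable.from_summary_frame(wide)
        assert set(table.metrics()) == {"kappa_avg", "low_it_fraction"}
        assert len(table.frame) == 2

    def test_tsv_round_trip(self, tmp_path):
        wide = pd.DataFrame(
            [
                dict(subject_id=f"s{i}", state=st, segment_id="g0",
                     delta_t_s=0.004, kappa_avg=float(i))
                for i in range(2) for st in ("A", "B")
            ]
        )
        p = tmp_path / "summary.tsv"
        wide.to_csv(p, sep="\t", index=False)
        table = CohortTable.read_tsv(p)
        assert table.states() == ["A", "B"]
        assert table.metrics() == ["kappa_avg"]
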