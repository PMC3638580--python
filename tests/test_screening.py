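import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathflux.errors import (
    ConfigurationError,
    LookupMismatchError,
    ValidationError,
    ZeroVarianceError,
)
from pathflux.metrics import CompoundMetrics
from pathflux.perturbation import ScoreMatrix
from pathflux.screening import (
    ActivityTable,
    correlate,
    pearson_r,
    rank_compounds,
    single_target_correlation,
)


def metrics_row(compound, ne_dec, nf_dec):
    comb = float(np.sqrt(max(ne_dec, 0) * max(nf_dec, 0)))
    return CompoundMetrics(
        compound=compound, ne=50 - ne_dec / 2, nf=2 - nf_dec / 100,
        ne_relative=100 - ne_dec, nf_relative=100 - nf_dec,
        ne_decrease=ne_dec, nf_decrease=nf_dec, combination=comb,
    )


def make_activity(rows):
    return ActivityTable(
        pd.DataFrame(rows, columns=["compound", "inhibition", "glycoside", "is_drug"])
    )


class TestRanking:
    def test_single_compound_gets_rank_one(self):
        report = rank_compounds([metrics_row("only", 10, 20)], key="ne_decrease")
        assert report.ranking["rank"].tolist() == [1]
        assert report.ranking["compound"].tolist() == ["only"]

    def test_larger_ne_decrease_ranks_first(self):
        report = rank_compounds(
            [metrics_row("weak", 25.0, 22.8), metrics_row("strong", 45.5, 79.8)],
            key="ne_decrease",
        )
        assert report.ranking["compound"].tolist() == ["strong", "weak"]

    def test_ties_broken_by_compound_id(self):
        report = rank_compounds(
            [metrics_row("zeta", 30, 30), metrics_row("alpha", 30, 30)],
            key="combination",
        )
        assert report.ranking["compound"].tolist() == ["alpha", "zeta"]

    def test_ranking_is_a_permutation(self):
        rng = np.random.default_rng(5)
        names = [f"c{i}" for i in range(40)]
        metrics = [
            metrics_row(n, float(rng.uniform(0, 80)), float(rng.uniform(0, 80)))
            for n in names
        ]
        report = rank_compounds(metrics, key="nf_decrease")
        assert sorted(report.ranking["compound"]) == sorted(names)
        got = report.ranking["nf_decrease"].to_numpy()
        assert (np.diff(got) <= 1e-12).all()

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError):
            rank_compounds([metrics_row("a", 1, 1)], key="charisma")

    def test_empty_metrics_rejected(self):
        with pytest.raises(ValidationError):
            rank_compounds([], key="combination")


class TestPearson:
    def test_perfect_line_gives_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_negated_line_gives_minus_one(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 2.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 500),
        a=st.floats(0.1, 5.0),
        b=st.floats(-10.0, 10.0),
    )
    def test_invariant_under_positive_affine_maps(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r0 = pearson_r(x, y)
        assert pearson_r(a * x + b, y) == pytest.approx(r0, abs=1e-9)
        assert pearson_r(-x, y) == pytest.approx(-r0, abs=1e-9)


class TestCorrelate:
    @pytest.fixture
    def toy(self):
        metrics = [
            metrics_row("a", 10, 20), metrics_row("b", 30, 35),
            metrics_row("c", 50, 60), metrics_row("g1", 20, 25),
            metrics_row("g2", 40, 45),
        ]
        activity = make_activity(
            [("a", 0.2, False, False), ("b", 0.4, False, False),
             ("c", 0.6, False, True), ("g1", 0.3, True, False),
             ("g2", 0.5, True, False)]
        )
        return metrics, activity

    def test_record_fields_and_fit(self, toy):
        metrics, activity = toy
        rec = correlate(metrics, activity, predictor="ne_decrease", subset="all")
        assert rec.n == 5
        assert -1.0 <= rec.pearson_r <= 1.0
        # ne_decrease maps affinely onto inhibition in this toy set
        assert rec.pearson_r == pytest.approx(1.0)
        assert rec.slope == pytest.approx(0.01)
        assert rec.intercept == pytest.approx(0.1)

    def test_nonglycoside_subset_filters_rows(self, toy):
        metrics, activity = toy
        nonglyc = [m for m in metrics if not m.compound.startswith("g")]
        rec = correlate(nonglyc, activity, predictor="ne_decrease", subset="nonglycoside")
        assert rec.n == 3

    def test_subsets_coincide_without_glycoside_flags(self, toy):
        metrics, _ = toy
        activity = make_activity(
            [("a", 0.2, False, False), ("b", 0.4, False, False),
             ("c", 0.6, False, False), ("g1", 0.3, False, False),
             ("g2", 0.5, False, False)]
        )
        r_all = correlate(metrics, activity, "combination", "all")
        r_non = correlate(metrics, activity, "combination", "nonglycoside")
        assert (r_all.n, r_all.pearson_r, r_all.slope, r_all.intercept) == (
            r_non.n, r_non.pearson_r, r_non.slope, r_non.intercept
        )

    def test_missing_compound_raises_with_name(self, toy):
        metrics, activity = toy
        metrics = metrics + [metrics_row("phantom", 15, 15)]
        with pytest.raises(LookupMismatchError, match="phantom"):
            correlate(metrics, activity, "combination", "all")

    def test_too_few_rows_after_subsetting(self):
        metrics = [metrics_row("a", 10, 20), metrics_row("b", 30, 35)]
        activity = make_activity(
            [("a", 0.2, False, False), ("b", 0.4, False, False)]
        )
        with pytest.raises(ValidationError):
            correlate(metrics, activity, "combination", "all")

    def test_activity_table_validation(self):
        with pytest.raises(ValidationError):
            make_activity([("a", 1.2, False, False)])  # inhibition > 1
        with pytest.raises(ValidationError):
            make_activity([("a", 0.2, False, False), ("a", 0.3, False, False)])


class TestSingleTarget:
    def test_affine_score_column_gives_perfect_r(self):
        activity = make_activity(
            [(f"c{i}", 0.1 * i, False, False) for i in range(1, 6)]
        )
        scores = np.array([[0.2 * i + 1.0, 5.0] for i in range(1, 6)])
        matrix = ScoreMatrix(
            [f"c{i}" for i in range(1, 6)], ["T", "U"], scores,
            {"T": 5.0, "U": 5.0},
        )
        rec = single_target_correlation(matrix, activity, "T")
        assert rec.pearson_r == pytest.approx(1.0)
        assert rec.predictor == "docking:T"

    def test_null_scores_stay_weakly_correlated(self):
        # independent scores vs activity at n=50: |r| stays below 0.5
        n = 50
        activity = make_activity(
            [(f"c{i}", (i % 10) / 10.0, False, False) for i in range(n)]
        )
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            matrix = ScoreMatrix(
                [f"c{i}" for i in range(n)], ["T"],
                rng.uniform(0, 8, size=(n, 1)), {"T": 5.0},
            )
            rec = single_target_correlation(matrix, activity, "T")
            worst = max(worst, abs(rec.pearson_r))
        assert worst < 0.5

    def test_subset_filter_applies(self):
        activity = make_activity(
            [("a", 0.2, True, False), ("b", 0.4, False, False),
             ("c", 0.6, False, False), ("d", 0.5, False, False)]
        )
        matrix = ScoreMatrix(
            ["a", "b", "c", "d"], ["T"],
            np.array([[1.0], [2.0], [3.0], [2.5]]), {"T": 5.0},
        )
        rec = single_target_correlation(matrix, activity, "T", subset="nonglycoside")
        assert rec.n == 3

    def test_unknown_target_rejected(self):
        activity = make_activity([("a", 0.2, False, False)])
        matrix = ScoreMatrix(["a"], ["T"], np.array([[1.0]]), {"T": 5.0})
        with pytest.raises(LookupMismatchError):
            single_target_correlation(matrix, activity, "Z")
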