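import math

import numpy as np
import pandas as pd
import pytest

from ulign import (
    SCORE_COLUMNS,
    UndefinedScoreError,
    average_ranks,
    best_mean_score,
    best_score_table,
    competition_ranks,
    make_score_table,
    rank_aligners,
    score_correlation,
    tradeoff_score,
)


def _table(rows):
    return make_score_table(rows)


class TestBestMeanScore:
    def test_single_row(self):
        t = _table([{"aligner": "A", "alpha": 0.5, "pair": "p1", "S3": 0.4}])
        assert best_mean_score(t, "A", "S3") == (0.5, 0.4)

    def test_picks_best_alpha(self):
        t = _table(
            [
                {"aligner": "A", "alpha": 0.0, "pair": "p1", "S3": 0.3},
                {"aligner": "A", "alpha": 0.5, "pair": "p1", "S3": 0.5},
            ]
        )
        assert best_mean_score(t, "A", "S3") == (0.5, 0.5)

    def test_ties_go_to_smallest_alpha(self):
        t = _table(
            [
                {"aligner": "A", "alpha": 0.8, "pair": "p1", "S3": 0.5},
                {"aligner": "A", "alpha": 0.2, "pair": "p1", "S3": 0.5},
            ]
        )
        assert best_mean_score(t, "A", "S3")[0] == 0.2

    def test_missing_values_excluded_from_means(self):
        t = _table(
            [
                {"aligner": "A", "alpha": 0.0, "pair": "p1", "S3": 0.8},
                {"aligner": "A", "alpha": 0.0, "pair": "p2", "S3": np.nan},
                {"aligner": "A", "alpha": 0.5, "pair": "p1", "S3": 0.5},
                {"aligner": "A", "alpha": 0.5, "pair": "p2", "S3": 0.5},
            ]
        )
        # alpha 0 mean is 0.8 over the single defined pair
        assert best_mean_score(t, "A", "S3") == (0.0, 0.8)

    def test_no_defined_value_is_an_error(self):
        t = _table([{"aligner": "A", "alpha": 0.0, "pair": "p1", "S3": np.nan}])
        with pytest.raises(UndefinedScoreError):
            best_mean_score(t, "A", "S3")

    def test_matches_exhaustive_search_on_random_tables(self, rng):
        aligners = [f"A{i}" for i in range(5)]
        alphas = [round(0.1 * i, 1) for i in range(11)]
        pairs = [f"p{i}" for i in range(4)]
        rows = [
            {
                "aligner": a,
                "alpha": al,
                "pair": p,
                "S3": float(rng.random()),
                "KP": float(rng.random()),
            }
            for a in aligners
            for al in alphas
            for p in pairs
        ]
        t = _table(rows)
        for a in aligners:
            for metric in ("S3", "KP"):
                # oracle: explicit loop over alphas
                best_alpha, best_val = None, -1.0
                for al in alphas:
                    vals = [
                        r[metric]
                        for r in rows
                        if r["aligner"] == a and r["alpha"] == al
                    ]
                    mean = sum(vals) / len(vals)
                    if mean > best_val:
                        best_alpha, best_val = al, mean
                got_alpha, got_val = best_mean_score(t, a, metric)
                assert got_alpha == best_alpha
                assert got_val == pytest.approx(best_val)


class TestTradeoff:
    @pytest.mark.parametrize(
        "s3,kp,expect",
        [(0.4, 0.4, 0.4), (0.25, 0.49, 0.35), (0.0, 0.9, 0.0), (1.0, 1.0, 1.0)],
    )
    def test_geometric_mean(self, s3, kp, expect):
        assert tradeoff_score(s3, kp) == pytest.approx(expect)

    def test_missing_input_gives_missing_output(self):
        assert math.isnan(tradeoff_score(None, 0.5))
        assert math.isnan(tradeoff_score(0.5, float("nan")))

    def test_bounded_by_inputs(self, rng):
        for _ in range(100):
            s3, kp = rng.random(), rng.random()
            v = tradeoff_score(s3, kp)
            assert min(s3, kp) - 1e-12 <= v <= max(s3, kp) + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tradeoff_score(1.2, 0.5)


class TestCompetitionRanks:
    def test_published_nc_column_pattern(self):
        values = pd.Series(
            [1.00, 1.00, 1.00, 0.994, 0.952, 0.923],
            index=["MAGNA", "HUBALIGN", "MODULEALIGN", "SPINAL", "L-GRAAL", "NATALIE"],
        )
        ranks = competition_ranks(values)
        assert list(ranks) == [1, 1, 1, 4, 5, 6]

    def test_rank_is_one_plus_strictly_greater_count(self, rng):
        for _ in range(50):
            vals = pd.Series(rng.integers(0, 5, size=8) / 4.0)
            ranks = competition_ranks(vals)
            for i, v in vals.items():
                assert ranks[i] == 1 + int((vals > v).sum())

    def test_all_tied(self):
        ranks = competition_ranks(pd.Series([0.5, 0.5, 0.5]))
        assert list(ranks) == [1, 1, 1]


class TestAverageRanks:
    # per-metric ranks of the eight aligners in the published comparison
    PUBLISHED_RANKS = {
        "L-GRAAL":     [5, 2, 2, 1, 2, 1, 2, 2, 2],
        "HUBALIGN":    [1, 1, 3, 3, 1, 4, 4, 4, 4],
        "NATALIE":     [6, 4, 5, 5, 5, 3, 1, 3, 1],
        "MAGNA":       [1, 5, 1, 2, 4, 6, 6, 6, 6],
        "PISWAP":      [7, 7, 8, 7, 7, 2, 3, 1, 3],
        "MODULEALIGN": [1, 3, 4, 4, 3, 7, 7, 7, 7],
        "SPINAL":      [4, 6, 7, 6, 6, 5, 5, 5, 5],
        "OPTNET":      [8, 8, 6, 8, 8, 8, 8, 8, 8],
    }

    def _rank_df(self):
        return pd.DataFrame.from_dict(
            self.PUBLISHED_RANKS, orient="index", columns=list(SCORE_COLUMNS)
        )

    def test_reproduces_published_averages(self):
        out = average_ranks(self._rank_df())
        expected_all = {
            "L-GRAAL": 2.11, "HUBALIGN": 2.78, "NATALIE": 3.67, "MAGNA": 4.11,
            "PISWAP": 5.00, "MODULEALIGN": 4.78, "SPINAL": 5.44, "OPTNET": 7.78,
        }
        for aligner, avg in expected_all.items():
            assert round(out.loc[aligner, "avg_all"], 2) == avg
        expected_s3_kp = {
            "L-GRAAL": 1.0, "HUBALIGN": 3.5, "NATALIE": 4.0, "MAGNA": 4.0,
            "PISWAP": 4.5, "MODULEALIGN": 5.5, "SPINAL": 5.5, "OPTNET": 8.0,
        }
        for aligner, avg in expected_s3_kp.items():
            assert out.loc[aligner, "avg_s3_kp"] == pytest.approx(avg)

    def test_sorted_by_avg_all(self):
        out = average_ranks(self._rank_df())
        assert list(out["avg_all"]) == sorted(out["avg_all"])
        assert out.index[0] == "L-GRAAL"
        assert out.index[-1] == "OPTNET"


class TestRankAligners:
    def test_all_tied_gives_all_ones(self):
        best = pd.DataFrame(
            0.5, index=["A", "B", "C"], columns=list(SCORE_COLUMNS)
        )
        out = rank_aligners(best)
        assert (out[list(SCORE_COLUMNS)] == 1).all().all()
        assert (out["avg_all"] == 1).all()

    def test_missing_metric_excluded_from_its_ranking(self):
        best = pd.DataFrame(
            {m: [0.5, 0.4] for m in SCORE_COLUMNS}, index=["A", "B"]
        )
        best.loc["B", "ICS"] = np.nan
        out = rank_aligners(best)
        assert math.isnan(out.loc["B", "ICS"])
        assert out.loc["A", "ICS"] == 1
        # B's averages skip the missing metric
        assert out.loc["B", "avg_all"] == pytest.approx(2.0)

    def test_fewer_than_two_rejected(self):
        best = pd.DataFrame({m: [0.5] for m in SCORE_COLUMNS}, index=["A"])
        with pytest.raises(ValueError):
            rank_aligners(best)


class TestScoreCorrelation:
    def _rand_table(self, rng, n=20):
        rows = []
        for i in range(n):
            x = float(rng.random())
            rows.append(
                {
                    "aligner": "A",
                    "alpha": 0.0,
                    "pair": f"p{i}",
                    "S3": x,
                    "EC": 1.0 - x,
                    "KP": float(rng.random()),
                }
            )
        return _table(rows)

    def test_perfect_anticorrelation_and_unit_diagonal(self, rng):
        pcc = score_correlation(self._rand_table(rng))
        assert pcc.loc["S3", "S3"] == pytest.approx(1.0)
        assert pcc.loc["S3", "EC"] == pytest.approx(-1.0)

    def test_matches_closed_form(self, rng):
        t = self._rand_table(rng)
        x = t["S3"].to_numpy()
        y = t["KP"].to_numpy()
        expect = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        pcc = score_correlation(t)
        assert pcc.loc["S3", "KP"] == pytest.approx(expect)
        assert pcc.loc["KP", "S3"] == pytest.approx(expect)

    def test_symmetric_and_bounded(self, rng):
        pcc = score_correlation(self._rand_table(rng)).to_numpy()
        finite = np.isfinite(pcc)
        assert np.allclose(pcc[finite], pcc.T[finite])
        assert (np.abs(pcc[finite]) <= 1 + 1e-12).all()

    def test_zero_variance_metric_is_flagged_missing(self, rng):
        t = self._rand_table(rng)
        t["LCC"] = 0.5  # constant
        pcc = score_correlation(t)
        assert pcc["LCC"].drop("LCC").isna().all() or math.isnan(pcc.loc["LCC", "S3"])


class TestMakeScoreTable:
    def test_duplicate_identity_rejected(self):
        rows = [
            {"aligner": "A", "alpha": 0.0, "pair": "p", "S3": 0.5},
            {"aligner": "A", "alpha": 0.0, "pair": "p", "S3": 0.6},
        ]
        with pytest.raises(ValueError):
            make_score_table(rows)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            make_score_table(
                [{"aligner": "A", "alpha": 0.0, "pair": "p", "S3": 1.5}]
            )
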