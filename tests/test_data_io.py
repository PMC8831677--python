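"""Readers, scale heuristics, filtering and per-ego fit orchestration."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egocircles.data_io import (
    CostScale,
    EgoRecord,
    Tie,
    filter_ties,
    fit_ego,
    fit_population,
    global_scale,
    read_contact_triplets,
    read_edge_list,
    summary_stats,
    windowed_scale,
    write_edge_list,
)
from egocircles.exceptions import (
    DegenerateScaleError,
    ParseError,
    ScaleError,
    ValidationError,
)
from egocircles.inference import summarize
from egocircles.synthetic import SyntheticConfig, generate_ego


class TestReadEdgeList:
    def test_basic_parse(self):
        recs = read_edge_list(io.StringIO(
            "ego,alter,weight\ne1,a,3\ne1,b,5\ne1,c,7\n"
        ))
        assert len(recs) == 1
        assert [t.weight for t in recs[0].ties] == [3.0, 5.0, 7.0]

    def test_duplicates_summed(self):
        recs = read_edge_list(io.StringIO(
            "ego,alter,weight,window\ne1,a,3,w1\ne1,a,4,w1\n"
        ))
        assert recs[0].ties == (Tie("a", 7.0, "w1"),)

    def test_empty_file_returns_empty_list(self):
        assert read_edge_list(io.StringIO("ego,alter,weight\n")) == []

    def test_malformed_weight_reports_line(self):
        with pytest.raises(ParseError, match=r"line.*3"):
            read_edge_list(io.StringIO("ego,alter,weight\ne1,a,3\ne1,b,oops\n"))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            read_edge_list(io.StringIO("ego,alter,weight\ne1,a,-2\n"))

    def test_round_trip_exact(self, tmp_path):
        recs = [EgoRecord("e1", (Tie("a", 3.25, "w1"), Tie("b", 11.0, None)))]
        path = tmp_path / "edges.csv"
        write_edge_list(recs, path)
        back = read_edge_list(path)
        assert back == recs


class TestReadContactTriplets:
    def test_counts_times_interval_symmetric(self):
        text = "\n".join(["100 A B"] * 5) + "\n"
        recs = read_contact_triplets(io.StringIO(text))
        by_id = {r.ego_id: r for r in recs}
        assert by_id["A"].ties == (Tie("B", 100.0),)
        assert by_id["B"].ties == (Tie("A", 100.0),)

    def test_single_record_is_one_interval(self):
        recs = read_contact_triplets(io.StringIO("7 x y\n"))
        assert recs[0].ties[0].weight == 20.0

    def test_group_rows_expand_pairwise(self):
        # a 3-badge group appears as its 3 concurrent pairs
        recs = read_contact_triplets(io.StringIO("5 A B\n5 A C\n5 B C\n"))
        by_id = {r.ego_id: r for r in recs}
        assert all(len(by_id[k].ties) == 2 for k in "ABC")

    def test_self_contacts_dropped(self):
        recs = read_contact_triplets(io.StringIO("1 A A\n2 A B\n"))
        by_id = {r.ego_id: r for r in recs}
        assert by_id["A"].ties == (Tie("B", 20.0),)


class TestScales:
    def test_windowed_sums_of_extrema(self):
        ties = []
        maxima = [30, 40, 25, 35, 20, 45]
        minima = [1, 2, 1, 1, 3, 1]
        for m, (hi, lo) in enumerate(zip(maxima, minima)):
            ties += [Tie("big", float(hi), f"m{m}"), Tie("small", float(lo), f"m{m}")]
        scale = windowed_scale(EgoRecord("e", tuple(ties)))
        assert (scale.s_min, scale.s_max) == (9.0, 195.0)

    def test_single_window_reduces_to_extrema(self):
        ego = EgoRecord("e", (Tie("a", 3.0, "w1"), Tie("b", 9.0, "w1")))
        scale = windowed_scale(ego)
        assert (scale.s_min, scale.s_max) == (3.0, 9.0)

    def test_global_extrema(self):
        ego = EgoRecord("e", (Tie("a", 3.0), Tie("b", 8.0), Tie("c", 21.0)))
        scale = global_scale(ego)
        assert (scale.s_min, scale.s_max) == (3.0, 21.0)
        # by construction at least one t=0 and one t=1
        s = summarize([3.0, 8.0, 21.0], scale)
        assert 0.0 < s.t_bar < 1.0

    def test_degenerate_scales_rejected(self):
        with pytest.raises(DegenerateScaleError):
            global_scale(EgoRecord("e", (Tie("a", 5.0), Tie("b", 5.0))))
        with pytest.raises(DegenerateScaleError):
            windowed_scale(EgoRecord("e", (Tie("a", 5.0, "w1"),)))
        with pytest.raises(ScaleError):
            CostScale(-1.0, 2.0)

    @given(st.lists(st.lists(st.floats(min_value=0.1, max_value=100.0),
                             min_size=1, max_size=6),
                    min_size=1, max_size=6))
    @settings(max_examples=60, derandomize=True)
    def test_windowed_smax_dominates_any_alter_total(self, windows):
        # sum of per-window maxima >= any single alter's total
        ties = tuple(
            Tie(f"a{i}", w, f"w{m}")
            for m, ws in enumerate(windows)
            for i, w in enumerate(ws)
        )
        ego = EgoRecord("e", ties)
        s_max = sum(max(ws) for ws in windows)
        assert all(total <= s_max + 1e-9 for total in ego.alter_totals().values())


class TestFilterTies:
    def test_strictly_below_smin_removed_equal_kept(self):
        ego = EgoRecord("e", (Tie("a", 9.0), Tie("b", 5.0), Tie("c", 12.0)))
        res = filter_ties(ego, CostScale(9.0, 12.0), min_alters=0)
        assert sorted(t.weight for t in res.record.ties) == [9.0, 12.0]
        assert res.n_removed == 1 and not res.excluded

    def test_minimum_alter_floor(self):
        ego = EgoRecord("e", tuple(Tie(f"a{i}", 5.0 + i) for i in range(4)))
        res = filter_ties(ego, CostScale(0.0, 10.0), min_alters=5)
        assert res.excluded

    def test_zero_smin_removes_nothing(self):
        ego = EgoRecord("e", (Tie("a", 0.0), Tie("b", 2.0)))
        res = filter_ties(ego, CostScale(0.0, 2.0), min_alters=0)
        assert res.n_removed == 0

    def test_overweight_clamped_with_warning(self, caplog):
        ego = EgoRecord("e", (Tie("a", 3.0), Tie("b", 99.0)))
        with caplog.at_level("WARNING"):
            res = filter_ties(ego, CostScale(1.0, 10.0), min_alters=0)
        assert max(t.weight for t in res.record.ties) == 10.0
        assert "clamped" in caplog.text


class TestFitEgo:
    def test_synthetic_round_trip_contains_truth(self):
        cfg = SyntheticConfig(eta_true=6.0, n_alters=200, seed=99)
        fit = fit_ego(generate_ego(cfg), min_alters=5)
        assert fit.status == "ok"
        assert fit.ci_low <= fit.eta_hat <= fit.ci_high
        # global-extrema scale shrinks |eta|; estimate still well positive
        assert 2.0 < fit.eta_hat < 8.0

    def test_symmetric_network_gives_zero(self):
        ego = EgoRecord("e", (Tie("a", 1.0), Tie("b", 2.0), Tie("c", 3.0)))
        fit = fit_ego(ego, min_alters=0)
        assert fit.eta_hat == 0.0
        assert fit.ci_low == pytest.approx(-fit.ci_high, abs=1e-6)
        assert fit.regime == "boundary"

    def test_failures_are_statuses_not_exceptions(self):
        degenerate = EgoRecord("d", (Tie("a", 5.0), Tie("b", 5.0)))
        small = EgoRecord("s", (Tie("a", 1.0), Tie("b", 2.0)))
        table = fit_population([degenerate, small], min_alters=5)
        assert list(table["status"]) == ["degenerate_scale", "excluded"]
        assert table["eta_hat"].isna().all()

    def test_population_median_near_truth_known_scale(self):
        rng = np.random.default_rng(5)
        scale = CostScale(0.0, 1.0)
        egos = [
            generate_ego(SyntheticConfig(eta_true=6.0, n_alters=100, seed=0),
                         ego_id=f"e{i}", rng=rng)
            for i in range(40)
        ]
        fits = fit_population(egos, scale=scale, min_alters=0, compute_ci=False)
        assert abs(np.median(fits["eta_hat"]) - 6.0) < 0.5


def test_summary_stats_fields():
    ego_ids = [f"e{i}" for i in range(6)]
    import pandas as pd

    fits = pd.DataFrame({
        "ego_id": ego_ids,
        "eta_hat": [5.2, 6.1, 5.8, -1.0, 6.3, 5.9],
        "status": ["ok"] * 6,
    })
    stats = summary_stats(fits, bin_width=1.0)
    assert stats["n_ok"] == 6
    assert stats["frac_inverse"] == pytest.approx(1 / 6)
    assert stats["mode"] == pytest.approx(5.5)
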