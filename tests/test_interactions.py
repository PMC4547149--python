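import numpy as np
import pandas as pd
import pytest

from mirtarnet import (
    DirectionOption,
    InteractionTable,
    PredictionResult,
    ScoreTable,
    SelectionSpec,
    apply_direction_filter,
    combine_results,
    select_interactions,
)
from mirtarnet.data_io import DesignError

from conftest import random_stats_table


def stats_from(mapping):
    from mirtarnet import DiffStatsTable

    return DiffStatsTable(
        pd.DataFrame(
            {"p": [0.01] * len(mapping), "fc": list(mapping.values())},
            index=list(mapping.keys()),
        )
    )


class TestDirectionFilter:
    @pytest.fixture
    def case_pair(self):
        # fold changes as published for hsa-let-7b-star_st / ACVR2B
        return (
            {("mirA", "geneB")},
            stats_from({"mirA": 2.31}),
            stats_from({"geneB": -1.18}),
        )

    def test_up_mirna_down_mrna_kept(self, case_pair):
        pairs, ms, gs = case_pair
        assert apply_direction_filter(pairs, ms, gs, DirectionOption.UP_MIR_DOWN_MRNA) == pairs

    def test_opposite_one_sided_mismatch_dropped(self, case_pair):
        pairs, ms, gs = case_pair
        assert apply_direction_filter(pairs, ms, gs, DirectionOption.DOWN_MIR_UP_MRNA) == set()

    def test_all_keeps_everything(self, case_pair):
        pairs, ms, gs = case_pair
        assert apply_direction_filter(pairs, None, None, DirectionOption.ALL) == pairs

    def test_unit_fold_change_matches_no_direction(self):
        ms = stats_from({"m": 1.0})
        gs = stats_from({"g": -2.0})
        assert apply_direction_filter({("m", "g")}, ms, gs, DirectionOption.OPPOSITE) == set()

    def test_opposite_equals_union_of_one_sided_options(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            mids = [f"m{i}" for i in range(5)]
            gids = [f"g{i}" for i in range(5)]
            ms = random_stats_table(rng, mids)
            gs = random_stats_table(rng, gids)
            pairs = {(m, g) for m in mids for g in gids}
            up = apply_direction_filter(pairs, ms, gs, DirectionOption.UP_MIR_DOWN_MRNA)
            down = apply_direction_filter(pairs, ms, gs, DirectionOption.DOWN_MIR_UP_MRNA)
            both = apply_direction_filter(pairs, ms, gs, DirectionOption.OPPOSITE)
            assert both == up | down

    def test_missing_stats_is_design_error(self):
        with pytest.raises(DesignError):
            apply_direction_filter({("m", "g")}, None, None, DirectionOption.OPPOSITE)


def score_table(method, mapping):
    rows = pd.DataFrame(
        [(m, g, s) for (m, g), s in mapping.items()],
        columns=["mirna_id", "mrna_id", "score"],
    )
    return ScoreTable(method=method, rows=rows)


class TestSelection:
    def test_top_n_most_negative_correlations_first(self):
        table = score_table(
            "pearson", {("a", "x"): -0.9, ("b", "x"): -0.2, ("c", "x"): 0.5}
        )
        result = select_interactions(
            table, SelectionSpec(mode="top_n", n=1, ordering="ascending")
        )
        assert result.pair_set() == {("a", "x")}

    def test_threshold_keeps_accepted_side(self):
        table = score_table("mic", {("p", "x"): 0.7, ("q", "x"): 0.5})
        result = select_interactions(
            table, SelectionSpec(mode="threshold", threshold=0.6, ordering="descending")
        )
        assert result.pair_set() == {("p", "x")}

    def test_top_n_saturates_at_available(self):
        table = score_table("mic", {("a", "x"): 0.1, ("b", "x"): 0.2, ("c", "x"): 0.3})
        result = select_interactions(table, SelectionSpec(mode="top_n", n=10))
        assert len(result.pairs) == 3

    def test_deterministic_lexicographic_tie_break(self):
        table = score_table("mic", {("b", "x"): 0.5, ("a", "y"): 0.5, ("a", "x"): 0.5})
        result = select_interactions(table, SelectionSpec(mode="top_n", n=2))
        assert result.pair_set() == {("a", "x"), ("a", "y")}

    def test_threshold_monotone(self):
        table = score_table("mic", {("a", "x"): 0.3, ("b", "x"): 0.6, ("c", "x"): 0.9})
        sizes = [
            len(
                select_interactions(
                    table, SelectionSpec(mode="threshold", threshold=t)
                ).pairs
            )
            for t in (0.2, 0.5, 0.8)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SelectionSpec(mode="top_n", n=2, threshold=0.5)


def make_results():
    present = [("mirX", "ACVR2B", 1.0)]
    return [
        PredictionResult("correlation", present),
        PredictionResult("genmir", [("mirX", "ACVR2B", 0.99)]),
        PredictionResult("mine", []),
        PredictionResult("targetscan", [("mirX", "ACVR2B", None)]),
        PredictionResult("microrna_org", []),
    ]


class TestCombine:
    def test_intersection_records_all_flags(self):
        table = combine_results(
            make_results(), mode="intersection", selected=["correlation", "genmir", "targetscan"]
        )
        assert len(table) == 1
        row = table.frame.iloc[0]
        assert [bool(row[a]) for a in table.algorithms] == [True, True, False, True, False]

    def test_intersection_over_all_five_drops_partial_support(self):
        table = combine_results(make_results(), mode="intersection")
        assert len(table) == 0

    def test_union_of_disjoint_results(self):
        results = [
            PredictionResult("correlation", [("m1", "g1", -0.8)]),
            PredictionResult("mine", [("m2", "g2", 0.9)]),
        ]
        table = combine_results(results, mode="union")
        assert len(table) == 2
        assert all(table.support_of(p) == 1 for p in table.pair_set())

    def test_intersection_subset_of_union_and_idempotence(self):
        results = [
            PredictionResult("correlation", [("m1", "g1", -0.8), ("m2", "g2", -0.5)]),
            PredictionResult("mine", [("m1", "g1", 0.9)]),
        ]
        inter = combine_results(results, mode="intersection")
        union = combine_results(results, mode="union")
        assert inter.pair_set() <= union.pair_set()
        solo = combine_results([results[0]], mode="intersection")
        assert solo.pair_set() == results[0].pair_set()

    def test_empty_selection_is_design_error(self):
        with pytest.raises(DesignError):
            combine_results(make_results(), selected=[])

    def test_table_round_trips_published_flag_format(self, tmp_path):
        table = combine_results(
            make_results(), mode="intersection", selected=["correlation"]
        )
        out = tmp_path / "t.tsv"
        table.to_tsv(out)
        text = out.read_text()
        assert "TRUE" in text and "FALSE" in text
        back = InteractionTable.from_frame(pd.read_csv(out, sep="\t"))
        assert back.pair_set() == table.pair_set()
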