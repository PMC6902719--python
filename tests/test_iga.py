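"""Iterative group analysis: PC scores, correction, and invariants."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipidiga as L
from lipidiga import iga


def oracle_pc(n: int, ranks: set[int]) -> float:
    """Exhaustive-enumeration oracle for the iGA score.

    For each prefix count x, enumerate every placement of the group over
    the N ranks and count placements with >= x members within the first
    r_x; minimize the resulting tails.  Independent of the closed-form
    tail summation used by the implementation.
    """
    g = len(ranks)
    sorted_ranks = sorted(ranks)
    best = 1.0
    for x, r in enumerate(sorted_ranks, start=1):
        hits = sum(
            1
            for placement in combinations(range(1, n + 1), g)
            if sum(rank <= r for rank in placement) >= x
        )
        best = min(best, hits / comb(n, g))
    return best


def results_frame(species, log2fc, p=None):
    return pd.DataFrame(
        {
            "species": species,
            "n": 12,
            "log2fc": log2fc,
            "p": p if p is not None else [0.5] * len(species),
        }
    )


class TestRankSpecies:
    def test_up_orders_by_descending_fold_change(self):
        res = results_frame(["a", "b", "c"], [2.0, 1.0, -1.0])
        assert L.rank_species(res, "up").species == ("a", "b", "c")

    def test_down_is_reverse_of_up_without_ties(self):
        res = results_frame(["a", "b", "c"], [2.0, 1.0, -1.0])
        assert L.rank_species(res, "down").species == ("c", "b", "a")

    def test_ties_break_on_smaller_p_then_name(self):
        res = results_frame(["a", "b"], [1.0, 1.0], p=[0.20, 0.01])
        assert L.rank_species(res, "up").species == ("b", "a")
        res2 = results_frame(["b", "a"], [1.0, 1.0], p=[0.1, 0.1])
        assert L.rank_species(res2, "up").species == ("a", "b")

    def test_t_statistic_ranking_available(self):
        res = results_frame(["a", "b"], [0.5, 1.0])
        res["t"] = [5.0, 1.0]
        assert L.rank_species(res, "up", by="t").species == ("a", "b")


class TestPcValue:
    def test_analytic_two_member_case(self):
        ranked = [f"s{i}" for i in range(1, 11)]
        pc, x_star, r_star = L.iga_pc_value(ranked, {"s1", "s2"})
        # p(1) = 1 - C(8,1)... = 0.2; p(2) = 1/C(10,2) = 1/45
        assert pc == pytest.approx(1 / 45, rel=1e-12)
        assert (x_star, r_star) == (2, 2)

    def test_group_at_bottom_scores_one(self):
        ranked = [f"s{i}" for i in range(10)]
        pc, *_ = L.iga_pc_value(ranked, set(ranked[-3:]))
        assert pc == 1.0

    def test_matches_enumeration_oracle(self):
        ranked = [f"s{i}" for i in range(1, 21)]
        member_ranks = {1, 4, 5, 11, 19}
        group = {f"s{r}" for r in member_ranks}
        pc, *_ = L.iga_pc_value(ranked, group)
        assert pc == pytest.approx(oracle_pc(20, member_ranks), rel=1e-12)

    def test_absent_member_errors_by_name(self):
        with pytest.raises(ValueError, match="ghost"):
            L.iga_pc_value(["a", "b"], {"a", "ghost"})

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_random_instances_match_oracle(self, data):
        n = data.draw(st.integers(3, 11))
        g = data.draw(st.integers(1, n - 1))
        ranks = set(data.draw(st.permutations(range(1, n + 1)))[:g])
        ranked = [f"s{i}" for i in range(1, n + 1)]
        group = {f"s{r}" for r in ranks}
        pc, *_ = L.iga_pc_value(ranked, group)
        assert pc == pytest.approx(oracle_pc(n, ranks), rel=1e-12)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_promoting_a_member_never_increases_pc(self, data):
        n = data.draw(st.integers(4, 15))
        g = data.draw(st.integers(1, n - 1))
        ranks = sorted(data.draw(st.permutations(range(1, n + 1)))[:g])
        ranked = [f"s{i}" for i in range(1, n + 1)]
        pc_before, *_ = L.iga_pc_value(ranked, {f"s{r}" for r in ranks})
        # move the worst-ranked member up one rank (swap with neighbour)
        worst = ranks[-1]
        if worst == 1 or worst - 1 in ranks:
            return
        promoted = set(ranks) - {worst} | {worst - 1}
        pc_after, *_ = L.iga_pc_value(ranked, {f"s{r}" for r in promoted})
        assert pc_after <= pc_before + 1e-15


class TestCorrectPc:
    def test_bonferroni_sixteen_tests(self):
        table = pd.DataFrame({"group": ["g"], "direction": ["up"], "pc_raw": [1e-5]})
        out = iga.correct_pc(table, n_tests=16)
        assert out["pc_corrected"].iloc[0] == pytest.approx(1.6e-4)
        assert bool(out["significant"].iloc[0])

    def test_cap_at_one(self):
        table = pd.DataFrame({"group": ["g"], "direction": ["up"], "pc_raw": [0.2]})
        out = iga.correct_pc(table, n_tests=16)
        assert out["pc_corrected"].iloc[0] == 1.0
        assert not bool(out["significant"].iloc[0])


class TestRunIga:
    def test_direction_antisymmetry(self, scheme):
        rng = np.random.default_rng(3)
        species = [m for ms in scheme.groups.values() for m in ms]
        res = results_frame(species, rng.normal(size=len(species)),
                            p=rng.uniform(size=len(species)))
        table = L.run_iga(res, scheme)
        up = table[table.direction == "up"].set_index("group")
        # reversing the ranking statistic swaps the direction results exactly
        flipped = res.assign(log2fc=-res["log2fc"])
        table_flipped = L.run_iga(flipped, scheme)
        down_flipped = table_flipped[table_flipped.direction == "down"].set_index("group")
        assert np.allclose(up["pc_raw"], down_flipped.loc[up.index, "pc_raw"])

    def test_group_equal_to_universe_scores_one(self):
        species = [f"s{i}" for i in range(6)]
        res = results_frame(species, np.arange(6, dtype=float))
        scheme = L.GroupScheme({"all": tuple(species)})
        table = L.run_iga(res, scheme)
        assert (table["pc_raw"] == 1.0).all()

    def test_groups_without_survivors_skipped(self, scheme):
        species = list(scheme.groups["HDHAs"])
        res = results_frame(species, np.arange(len(species), dtype=float))
        table = L.run_iga(res, scheme)
        assert set(table["group"]) == {"HDHAs"}
        assert set(table.attrs["skipped_groups"]) == set(scheme.groups) - {"HDHAs"}

    def test_no_overlap_at_all_errors(self, scheme):
        res = results_frame(["zzz1", "zzz2"], [1.0, 2.0])
        with pytest.raises(ValueError, match="no scheme group"):
            L.run_iga(res, scheme)
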