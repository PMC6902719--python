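"""n-3 index, precursor totals, percent change, and the Spearman screen."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import lipidiga as L
from lipidiga.summaries import _rank_corr
from scipy import stats

from tests.conftest import epidermis_config


class TestN3Index:
    def test_additive_definition(self):
        assert L.n3_index({"20:5n-3": 2.0, "22:6n-3": 3.0}) == 5.0

    def test_zero_case(self):
        assert L.n3_index({"20:5n-3": 0.0, "22:6n-3": 0.0}) == 0.0

    def test_other_entries_ignored(self):
        a = L.n3_index({"20:5n-3": 1.0, "22:6n-3": 2.0, "16:0": 20.0})
        b = L.n3_index({"16:0": 50.0, "22:6n-3": 2.0, "20:5n-3": 1.0})
        assert a == b == 3.0

    def test_missing_fatty_acid_errors(self):
        with pytest.raises(ValueError, match="22:6n-3"):
            L.n3_index({"20:5n-3": 1.0})

    def test_simulated_cohort_mean_matches_template(self):
        profiles = L.generate_rbc_profiles(n_subjects=12, noise_sd=0.3, seed=5)
        pre = profiles[profiles.phase == "pre"]
        mean_idx = pre.apply(L.n3_index, axis=1).mean()
        se = 0.3 * np.sqrt(2) / np.sqrt(12)
        assert mean_idx == pytest.approx(4.86, abs=3 * se)


class TestFattyAcidPairedTests:
    def test_identical_phases_give_p_one(self):
        profiles = pd.DataFrame(
            {
                "subject": ["s1", "s2", "s1", "s2"],
                "phase": ["pre", "pre", "post", "post"],
                "20:5n-3": [1.0, 1.2, 1.0, 1.2],
            }
        )
        out = L.fatty_acid_paired_tests(profiles)
        assert out.loc[0, "p"] == 1.0

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(2, 0.2, 6)
        shift = rng.normal(0.3, 0.1, 6)
        frames = []
        for sgn in (1, -1):
            profiles = pd.DataFrame(
                {
                    "subject": [f"s{i}" for i in range(6)] * 2,
                    "phase": ["pre"] * 6 + ["post"] * 6,
                    "fa": np.concatenate([base, base + sgn * shift]),
                }
            )
            frames.append(L.fatty_acid_paired_tests(profiles))
        assert frames[0].loc[0, "p"] == pytest.approx(frames[1].loc[0, "p"])
        assert frames[0].loc[0, "t"] == pytest.approx(-frames[1].loc[0, "t"])

    def test_epa_shift_detected_in_most_replicates(self):
        hits = 0
        reps = 200
        for i in range(reps):
            profiles = L.generate_rbc_profiles(n_subjects=12, noise_sd=0.3, seed=10_000 + i)
            out = L.fatty_acid_paired_tests(profiles).set_index("fatty_acid")
            hits += out.loc["20:5n-3", "p"] < 0.05
        assert hits / reps >= 0.9


class TestPrecursorTotals:
    def test_two_species_sum(self, panel):
        design = pd.DataFrame(
            {
                "subject": ["s1"],
                "arm": ["EPA"],
                "phase": ["pre"],
                "tissue": ["epidermis"],
                "uvr_time": ["unirradiated"],
            },
            index=["x1"],
        )
        values = pd.DataFrame({"12-HEPE": [100.0], "18-HEPE": [219.0]}, index=["x1"])
        m = L.ConcentrationMatrix(
            design=design,
            values=values,
            lod=pd.Series({"12-HEPE": 0.5, "18-HEPE": 0.5}),
            unit="pg/mg-protein",
        )
        totals = L.precursor_totals(m, panel, "EPA")
        assert totals.loc["s1"] == pytest.approx(319.0)

    def test_column_order_invariance(self, panel, scheme):
        ds = L.generate_study(epidermis_config(seed=21, n=4, lod_quantile=0.0), [], panel, scheme)
        m = ds.matrices["epidermis"]
        shuffled = m.select_species(list(reversed(m.species)))
        a = L.precursor_totals(m, panel, "AA", {"phase": "pre"})
        b = L.precursor_totals(shuffled, panel, "AA", {"phase": "pre"})
        assert np.allclose(a.sort_index(), b.sort_index())

    def test_missing_precursor_errors(self, panel, scheme):
        ds = L.generate_study(epidermis_config(seed=22, n=3, lod_quantile=0.0), [], panel, scheme)
        m = ds.matrices["epidermis"].select_species(["PGE2", "PGD2"])
        with pytest.raises(ValueError, match="EPA"):
            L.precursor_totals(m, panel, "EPA")


class TestPercentChange:
    def test_worked_example(self):
        assert L.percent_change([100.0], [208.0]) == pytest.approx(108.0)

    def test_equal_means_give_zero(self):
        assert L.percent_change([3.0, 5.0], [4.0, 4.0]) == 0.0

    def test_halving(self):
        assert L.percent_change([100.0], [50.0]) == -50.0

    def test_scale_invariance(self):
        pre = np.array([3.0, 7.0, 5.0])
        post = np.array([4.0, 9.0, 6.0])
        assert L.percent_change(pre, post) == pytest.approx(L.percent_change(10 * pre, 10 * post))

    def test_zero_pre_mean_errors(self):
        with pytest.raises(ValueError):
            L.percent_change([0.0], [1.0])


def _make_pair_matrices(skin_vals: dict, plasma_vals: dict, subjects):
    def build(vals, tissue, unit):
        design = pd.DataFrame(
            {
                "subject": subjects,
                "arm": "EPA",
                "phase": "pre",
                "tissue": tissue,
                "uvr_time": "unirradiated",
            },
            index=[f"{tissue}-{s}" for s in subjects],
        )
        values = pd.DataFrame(vals, index=design.index)
        lod = pd.Series(0.01, index=values.columns)
        return L.ConcentrationMatrix(design=design, values=values, lod=lod, unit=unit)

    return build(skin_vals, "epidermis", "pg/mg-protein"), build(plasma_vals, "plasma", "pg/ml")


class TestSpearmanCrossCompartment:
    def test_perfect_monotone_pairs(self):
        subjects = [f"s{i}" for i in range(5)]
        skin, plasma = _make_pair_matrices(
            {"PGE2": [1.0, 2.0, 3.0, 4.0, 5.0]},
            {"PGE2": [10.0, 20.0, 30.0, 40.0, 50.0]},
            subjects,
        )
        out = L.spearman_cross_compartment(skin, plasma).set_index("species")
        assert out.loc["PGE2", "rho"] == pytest.approx(1.0)

    def test_reversed_pairs(self):
        subjects = [f"s{i}" for i in range(5)]
        skin, plasma = _make_pair_matrices(
            {"PGE2": [1.0, 2.0, 3.0, 4.0, 5.0]},
            {"PGE2": [50.0, 40.0, 30.0, 20.0, 10.0]},
            subjects,
        )
        out = L.spearman_cross_compartment(skin, plasma).set_index("species")
        assert out.loc["PGE2", "rho"] == pytest.approx(-1.0)

    def test_exact_permutation_p_small_n(self):
        subjects = [f"s{i}" for i in range(5)]
        skin, plasma = _make_pair_matrices(
            {"PGE2": [1.0, 2.0, 3.0, 4.0, 5.0]},
            {"PGE2": [2.0, 1.0, 4.0, 3.0, 5.0]},
            subjects,
        )
        out = L.spearman_cross_compartment(skin, plasma).set_index("species")
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*4/120 = 0.8
        assert out.loc["PGE2", "rho"] == pytest.approx(0.8)
        # oracle: all 120 permutations of one margin
        ra = np.array([1.0, 2, 3, 4, 5])
        rhos = [abs(_rank_corr(ra, np.array(p))) for p in permutations(ra)]
        p_oracle = np.mean([r >= 0.8 - 1e-12 for r in rhos])
        assert out.loc["PGE2", "p"] == pytest.approx(p_oracle)

    def test_exact_matches_scipy_for_n_up_to_7(self):
        rng = np.random.default_rng(8)
        for n in (4, 5, 6, 7):
            a, b = rng.normal(size=n), rng.normal(size=n)
            subjects = [f"s{i}" for i in range(n)]
            skin, plasma = _make_pair_matrices(
                {"PGE2": np.abs(a) + 1}, {"PGE2": np.abs(b) + 1}, subjects
            )
            out = L.spearman_cross_compartment(skin, plasma).set_index("species")
            rho_ref = stats.spearmanr(np.abs(a) + 1, np.abs(b) + 1).statistic
            assert out.loc["PGE2", "rho"] == pytest.approx(rho_ref)

    def test_constant_vector_reported_missing(self):
        subjects = [f"s{i}" for i in range(4)]
        skin, plasma = _make_pair_matrices(
            {"PGE2": [2.0, 2.0, 2.0, 2.0]},
            {"PGE2": [1.0, 2.0, 3.0, 4.0]},
            subjects,
        )
        out = L.spearman_cross_compartment(skin, plasma).set_index("species")
        assert np.isnan(out.loc["PGE2", "rho"])
        assert out.loc["PGE2", "note"] == "constant"
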