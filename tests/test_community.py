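"""Functional and taxonomic diversity metrics against closed forms."""

import numpy as np
import pandas as pd
import pytest

from forestdiv.community import (
    CommunityAbundance,
    EmptyCommunityError,
    PlotCensus,
    TraitTable,
    basal_area_weights,
    fdis,
    gower_distance,
    hill_simpson,
    rao_q,
    simpson_index,
    stem_basal_area,
    trait_coverage,
)


class TestBasalAreaWeights:
    def test_single_stem_formula(self):
        census = PlotCensus("p", 2000.0, 1.0, [("A", 10.0)])
        com = basal_area_weights(census)
        assert com.total_ba == pytest.approx(np.pi * 0.05**2)
        assert com.weights == {"A": 1.0}

    def test_equal_stems_split_equally(self):
        census = PlotCensus("p", 2000.0, 1.0, [("A", 10.0), ("B", 10.0)])
        com = basal_area_weights(census)
        assert com.weights["A"] == pytest.approx(0.5)
        assert com.weights["B"] == pytest.approx(0.5)

    def test_basal_area_additivity(self):
        # two 10 cm stems carry the same basal area as one 10*sqrt(2) stem
        census = PlotCensus(
            "p", 2000.0, 1.0,
            [("A", 10.0), ("A", 10.0), ("B", 10.0 * np.sqrt(2.0))],
        )
        com = basal_area_weights(census)
        assert com.weights["A"] == pytest.approx(0.5, abs=1e-12)

    def test_empty_census_raises(self):
        with pytest.raises(EmptyCommunityError):
            basal_area_weights(PlotCensus("p", 2000.0, 1.0, []))

    def test_sub_threshold_dbh_rejected(self):
        with pytest.raises(ValueError, match="dbh"):
            PlotCensus("p", 2000.0, 1.0, [("A", 9.9)])


class TestSimpsonHill:
    @pytest.mark.parametrize("props, expected", [
        ([1.0], 0.0),
        ([0.25] * 4, 0.75),
        ([2, 1, 1], 0.625),
    ])
    def test_simpson_closed_forms(self, props, expected):
        assert simpson_index(props) == pytest.approx(expected)

    @pytest.mark.parametrize("props, expected", [
        ([1.0], 1.0),
        ([0.2] * 5, 5.0),
        ([2, 1, 1], 1 / 0.375),
    ])
    def test_hill_closed_forms(self, props, expected):
        assert hill_simpson(props) == pytest.approx(expected)

    def test_simpson_hill_duality(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(rng.integers(2, 12)))
            assert simpson_index(p) == pytest.approx(
                1 - 1 / hill_simpson(p), abs=1e-12
            )

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            simpson_index([0.5, -0.1, 0.6])


class TestGower:
    def test_identical_rows_zero(self):
        df = pd.DataFrame({"x": [1.0, 1.0], "c": ["u", "u"]},
                          index=["a", "b"])
        tt = TraitTable(df, {"x": "numeric", "c": "categorical"})
        assert gower_distance(tt).iloc[0, 1] == 0.0

    def test_range_extremes_distance_one(self):
        df = pd.DataFrame({"x": [0.0, 5.0]}, index=["a", "b"])
        tt = TraitTable(df, {"x": "numeric"})
        assert gower_distance(tt).iloc[0, 1] == pytest.approx(1.0)

    def test_mixed_traits_average(self):
        df = pd.DataFrame({"x": [0.0, 1.0], "c": ["u", "u"]},
                          index=["a", "b"])
        tt = TraitTable(df, {"x": "numeric", "c": "categorical"})
        assert gower_distance(tt).iloc[0, 1] == pytest.approx(0.5)

    def test_zero_range_trait_skipped_with_warning(self, caplog):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0], "y": [0.0, 1.0, 2.0]},
                          index=list("abc"))
        tt = TraitTable(df, {"x": "numeric", "y": "numeric"})
        with caplog.at_level("WARNING"):
            d = gower_distance(tt)
        assert "zero range" in caplog.text
        assert d.iloc[0, 2] == pytest.approx(1.0)  # only y contributes

    def test_matrix_properties(self, numeric_traits):
        d = gower_distance(numeric_traits).to_numpy()
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1


class TestFDis:
    def test_single_species_zero(self, numeric_traits, community_factory):
        com = community_factory([numeric_traits.species[0]], [1.0])
        assert fdis(numeric_traits, com) == 0.0

    def test_two_species_closed_form(self, community_factory):
        tt = TraitTable(pd.DataFrame({"x": [0.0, 2.0]}, index=["a", "b"]),
                        {"x": "numeric"})
        com = community_factory(["a", "b"], [0.5, 0.5])
        # sample-sd standardization puts the species at -1/sqrt2, +1/sqrt2
        assert fdis(tt, com) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_dominant_species_limit(self, community_factory):
        tt = TraitTable(pd.DataFrame({"x": [0.0, 2.0]}, index=["a", "b"]),
                        {"x": "numeric"})
        vals = [fdis(tt, community_factory(["a", "b"], [1 - eps, eps]))
                for eps in (0.1, 0.01, 0.001)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.01

    def test_affine_trait_rescaling_invariance(self, numeric_traits,
                                               community_factory):
        rng = np.random.default_rng(1)
        w = rng.dirichlet(np.ones(5))
        sp = numeric_traits.species[:5]
        com = community_factory(sp, w)
        base = fdis(numeric_traits, com)
        scaled = numeric_traits.data.copy()
        scaled["wd"] = scaled["wd"] * 1000.0 + 77.0
        tt = TraitTable(scaled, numeric_traits.kinds)
        assert fdis(tt, com) == pytest.approx(base, abs=1e-10)

    def test_species_duplication_invariance(self, community_factory):
        # an identical-trait species split into two equal halves leaves the
        # dispersion unchanged (richness-insensitivity)
        df = pd.DataFrame({"x": [0.0, 2.0, 2.0], "g": ["u", "v", "v"]},
                          index=["a", "b", "b2"])
        tt = TraitTable(df, {"x": "numeric", "g": "categorical"})
        com1 = community_factory(["a", "b"], [0.5, 0.5])
        com2 = community_factory(["a", "b", "b2"], [0.5, 0.25, 0.25])
        assert fdis(tt, com2) == pytest.approx(fdis(tt, com1), abs=1e-10)

    def test_zero_weight_species_no_effect(self, numeric_traits,
                                           community_factory):
        sp = numeric_traits.species
        com1 = community_factory(sp[:4], [0.4, 0.3, 0.2, 0.1])
        com2 = CommunityAbundance(
            "p", 2000.0,
            {**com1.weights, sp[5]: 0.0}, 1.0,
        )
        assert fdis(numeric_traits, com2) == pytest.approx(
            fdis(numeric_traits, com1), abs=1e-12
        )

    def test_embedding_equals_direct_formula(self, numeric_traits,
                                             community_factory):
        # PCoA path on Euclidean distances reproduces direct evaluation in
        # standardized trait space
        rng = np.random.default_rng(5)
        df = numeric_traits.data
        Z = (df - df.mean()) / df.std(ddof=1)
        for n in (3, 4, 6):
            sp = list(rng.choice(numeric_traits.species, n, replace=False))
            w = rng.dirichlet(np.ones(n))
            com = community_factory(sp, w)
            zz = Z.loc[sp].to_numpy()
            c = w @ zz
            direct = float(w @ np.linalg.norm(zz - c, axis=1))
            assert fdis(numeric_traits, com) == pytest.approx(
                direct, abs=1e-10
            )

    def test_species_order_invariance(self, numeric_traits,
                                      community_factory):
        sp = numeric_traits.species[:5]
        w = [0.4, 0.25, 0.2, 0.1, 0.05]
        com1 = community_factory(sp, w)
        com2 = community_factory(sp[::-1], w[::-1])
        assert fdis(numeric_traits, com1) == pytest.approx(
            fdis(numeric_traits, com2), abs=1e-12
        )


class TestRaoQ:
    def test_closed_forms(self, community_factory):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        com = community_factory(["a", "b"], [0.5, 0.5])
        assert rao_q(d, com) == pytest.approx(0.5)
        single = community_factory(["a"], [1.0])
        assert rao_q(d, single) == 0.0

    def test_tracks_fdis_ranking(self, numeric_traits, community_factory):
        from scipy import stats

        rng = np.random.default_rng(11)
        g = gower_distance(numeric_traits)
        f_vals, r_vals = [], []
        for _ in range(50):
            n = int(rng.integers(3, 10))
            sp = list(rng.choice(numeric_traits.species, n, replace=False))
            w = rng.dirichlet(np.ones(n))
            com = community_factory(sp, w)
            f_vals.append(fdis(numeric_traits, com))
            r_vals.append(rao_q(g, com))
        rho = stats.spearmanr(f_vals, r_vals).statistic
        assert rho > 0.8


class TestTraitCoverage:
    def test_complete_table_full_coverage(self, numeric_traits,
                                          community_factory):
        com = community_factory(numeric_traits.species[:4], [0.25] * 4)
        cov = trait_coverage(numeric_traits, com)
        assert all(v == pytest.approx(1.0) for v in cov.values())

    def test_missing_value_reduces_coverage(self, community_factory, caplog):
        df = pd.DataFrame({"x": [1.0, np.nan, 3.0]}, index=list("abc"))
        tt = TraitTable(df, {"x": "numeric"})
        com = community_factory(list("abc"), [0.4, 0.3, 0.3])
        with caplog.at_level("WARNING"):
            cov = trait_coverage(tt, com, warn_threshold=0.9)
        assert cov["x"] == pytest.approx(0.7)
        assert "covers" in caplog.text
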