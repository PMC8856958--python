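"""Categorical co-expression statistics."""

import numpy as np
import pandas as pd
import pytest

import shmirkit as sk
from shmirkit.coexpr import exact_rank_sum_p


def _cells(rows):
    base = {
        "cell_id": None, "section_id": "S01", "region_id": "R01",
        "compartment": "caudate", "treated": True, "marker": "ChAT",
    }
    out = []
    for i, r in enumerate(rows):
        d = dict(base, cell_id=f"C{i}", **r)
        out.append(d)
    return pd.DataFrame(out)


class TestCategoryTable:
    def test_planted_singletons(self):
        rows = [
            {"marker_level": m, "reporter_level": r}
            for m in ("strong", "weak")
            for r in ("RN", "RM", "RS")
        ]
        cells = _cells(rows)
        table = sk.build_category_table(cells, include_untreated=False)
        assert table.to_numpy().sum() == 6
        assert table.loc["strong", "RN"] == 1
        assert table.loc["medium"].sum() == 0

    def test_sum_equals_selected_cells(self, cell_sim):
        cells, regions, _, spec = cell_sim
        table = sk.build_category_table(cells, regions, construct=spec.construct)
        assert table.to_numpy().sum() == len(cells)

    def test_disjoint_collections_add(self, cell_sim):
        cells, regions, _, spec = cell_sim
        half = len(cells) // 2
        a, b = cells.iloc[:half], cells.iloc[half:]
        ta = sk.build_category_table(a, regions, construct=spec.construct)
        tb = sk.build_category_table(b, regions, construct=spec.construct)
        tall = sk.build_category_table(cells, regions, construct=spec.construct)
        assert ((ta + tb) == tall).all().all()

    def test_empty_selection_raises_with_filter_name(self):
        cells = _cells([{"marker_level": "strong", "reporter_level": "RN"}])
        with pytest.raises(ValueError, match="AChE"):
            sk.build_category_table(cells, marker="AChE")

    def test_csv_loader_roundtrip(self, tmp_path, cell_sim):
        cells, regions, _, spec = cell_sim
        table = sk.build_category_table(cells, regions, construct=spec.construct)
        p = tmp_path / "counts.csv"
        table.to_csv(p)
        assert sk.load_category_table(p).equals(table)


class TestChisqGof:
    def test_perfect_fit(self):
        res = sk.chisq_goodness_of_fit([30, 60, 10], [0.3, 0.6, 0.1])
        assert res.x2 == pytest.approx(0.0)
        assert res.df == 2

    def test_hand_computed_statistic(self):
        # (10,40,50) vs expected (30,60,10): 400/30 + 400/60 + 1600/10 = 180
        res = sk.chisq_goodness_of_fit([10, 40, 50], [0.3, 0.6, 0.1])
        assert res.x2 == pytest.approx(180.0)
        assert res.df == 2
        assert 0 < res.p < 1e-10

    def test_renormalises_with_warning(self):
        with pytest.warns(UserWarning):
            res = sk.chisq_goodness_of_fit([30, 60, 10], [3, 6, 1])
        assert res.x2 == pytest.approx(0.0)

    def test_zero_reference_with_observed_rejected(self):
        with pytest.raises(ValueError):
            sk.chisq_goodness_of_fit([10, 10, 5], [0.5, 0.5, 0.0])


class TestLinearByLinear:
    def test_perfect_association_closed_form(self):
        res = sk.linear_by_linear_test([[10, 0], [0, 10]])
        assert res.r == pytest.approx(1.0)
        assert res.Z == pytest.approx(np.sqrt(19))

    def test_uniform_table_zero(self):
        res = sk.linear_by_linear_test(np.full((3, 5), 7))
        assert res.Z == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_affine_score_invariance(self, rng):
        tab = rng.integers(1, 20, size=(3, 5))
        a = sk.linear_by_linear_test(tab)
        b = sk.linear_by_linear_test(tab, u=2 * a.u + 3, v=-1.5 * a.v + 7)
        assert abs(b.Z) == pytest.approx(abs(a.Z))

    def test_z_r_identity(self, rng):
        for _ in range(20):
            tab = rng.integers(0, 25, size=(3, 5)) + np.eye(3, 5, dtype=int)
            res = sk.linear_by_linear_test(tab)
            assert res.Z == pytest.approx(res.r * np.sqrt(res.n - 1), abs=1e-12)
            assert res.chi2_1df == pytest.approx(res.Z**2)
            assert res.df_table == 8

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            sk.linear_by_linear_test([[5, 5, 5], [0, 0, 0]])

    def test_sign_convention_knockdown_positive(self, cell_sim):
        """Stronger reporter with weaker marker must give positive Z under
        the strong=1..weak=3 / RU=1..RS=5 orientation."""
        cells, regions, _, spec = cell_sim
        table = sk.build_category_table(cells, regions, construct=spec.construct)
        assert sk.linear_by_linear_test(table).Z > 0

    def test_z_grows_with_sqrt_n(self):
        zs = []
        for n in (200, 800, 3200):
            spec = sk.CoexprSpec(beta=0.6, seed=21).with_expected_cells(n)
            cells, regions, _ = sk.simulate_cell_table(spec)
            table = sk.build_category_table(cells, regions, construct=spec.construct)
            zs.append(sk.linear_by_linear_test(table).Z)
        assert zs[0] > 0
        assert zs[0] < zs[1] < zs[2]


class TestPearsonTrend:
    def test_perfect_decrease(self):
        r, p = sk.pearson_trend([0.5, 0.4, 0.3, 0.2, 0.1])
        assert r == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            sk.pearson_trend([0.2, 0.2, 0.2, 0.2])

    def test_matches_direct_formula(self, rng):
        y = rng.random(5)
        x = np.arange(1, 6)
        r, _ = sk.pearson_trend(y)
        direct = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(direct, abs=1e-12)


class TestDensities:
    def _tables(self, treated_d, untreated_d):
        regions = pd.DataFrame(
            [
                {"region_id": f"R{i}", "section_id": "S1", "compartment": "caudate",
                 "treated": i < len(treated_d), "construct": "c" if i < len(treated_d) else "",
                 "area_mm2": 1.0}
                for i in range(len(treated_d) + len(untreated_d))
            ]
        )
        rows = []
        for i, d in enumerate(list(treated_d) + list(untreated_d)):
            rows.extend(
                {"cell_id": f"C{i}_{j}", "section_id": "S1", "region_id": f"R{i}",
                 "compartment": "caudate", "treated": i < len(treated_d), "marker": "ChAT",
                 "marker_level": "strong", "reporter_level": "RN" if i < len(treated_d) else "RU"}
                for j in range(int(d * 2))
            )
        regions["area_mm2"] = 2.0  # so density = count / 2 reproduces d
        return pd.DataFrame(rows), regions

    def test_exact_enumeration_example(self):
        # all treated densities below all untreated: p = 2/C(6,3) = 0.1
        cells, regions = self._tables([5, 6, 5.5], [9, 10, 9.5])
        res = sk.compare_densities(cells, regions, construct="c")
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1)
        assert sorted(res.densities["density"]) == [5, 5.5, 6, 9, 9.5, 10]

    def test_identical_groups_p_one(self):
        cells, regions = self._tables([4, 5, 6], [4, 5, 6])
        res = sk.compare_densities(cells, regions, construct="c")
        assert res.p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        u, p = exact_rank_sum_p(x, y)
        # oracle: scipy exact method (valid, no ties here)
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_area_rejected(self):
        cells, regions = self._tables([4], [5])
        regions.loc[0, "area_mm2"] = 0.0
        with pytest.raises(ValueError):
            sk.compare_densities(cells, regions, construct="c")

    def test_simulated_untreated_density_in_stated_range(self, cell_sim):
        cells, regions, _, spec = cell_sim
        res = sk.compare_densities(cells, regions, construct=spec.construct)
        unt = res.densities.loc[~res.densities["treated"], "density"]
        assert 6.0 < unt.mean() < 17.0  # generator draws densities in 8-15


class TestPenetrance:
    def test_fraction(self):
        rows = [{"marker_level": "strong", "reporter_level": "RM"}] * 80 + [
            {"marker_level": "strong", "reporter_level": "RN"}
        ] * 20
        res = sk.penetrance(_cells(rows))
        assert res.pooled == pytest.approx(0.80)

    def test_all_undetected_is_zero(self):
        rows = [{"marker_level": "medium", "reporter_level": "RN"}] * 10
        assert sk.penetrance(_cells(rows)).pooled == 0.0

    def test_simulated_penetrance_near_planted(self, cell_sim):
        cells, regions, _, spec = cell_sim
        res = sk.penetrance(cells, regions, construct=spec.construct)
        assert res.pooled == pytest.approx(spec.penetrance, abs=0.08)
        assert set(res.per_region.index) <= set(regions["region_id"])
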