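"""Composition, density, differential expression, BH, pseudobulk."""

import numpy as np
import pandas as pd
import pytest

from spatiomux import CellLayer, Experiment, FeatureMismatchError, InvalidPolygonError, Sample
from spatiomux.analysis import (
    bh_adjust,
    cell_composition,
    cell_type_density,
    differential_expression,
    pseudobulk,
)
from spatiomux.core import PolygonSet
from spatiomux.synthetic import generate_dge_pair, generate_sample


def _typed_layer(types, n_genes=3, seed=0):
    rng = np.random.default_rng(seed)
    n = len(types)
    table = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "centroid_x": rng.uniform(0, 100, n),
            "centroid_y": rng.uniform(0, 100, n),
            "cell_type": types,
        }
    )
    feats = pd.DataFrame({"feature": [f"g{i}" for i in range(n_genes)]})
    return CellLayer(rng.integers(0, 5, (n, n_genes)), table, feats)


def _exp_of(layers_with_meta):
    exp = Experiment()
    for i, (layer, meta) in enumerate(layers_with_meta):
        exp.add(Sample(uid=f"u{i}", cells={"default": layer}), meta)
    return exp


class TestComposition:
    def test_single_sample_proportions(self):
        exp = _exp_of([(_typed_layer(["A"] * 3 + ["B"]), {})])
        comp = cell_composition(exp)
        assert comp.loc["u0", "A"] == pytest.approx(0.75)
        assert comp.loc["u0", "B"] == pytest.approx(0.25)

    def test_grouping_two_identical_samples(self):
        layer = _typed_layer(["A", "A", "B", "C"])
        exp = _exp_of([(layer, {"g": "x"}), (_typed_layer(["A", "A", "B", "C"], seed=1), {"g": "x"})])
        comp = cell_composition(exp, group_key="g")
        assert list(comp.index) == ["x"]
        np.testing.assert_allclose(comp.loc["x"].to_numpy(), [0.5, 0.25, 0.25])

    def test_rows_sum_to_one_and_absent_types_zero(self):
        exp = _exp_of([(_typed_layer(["A", "B"]), {}), (_typed_layer(["C", "C"]), {})])
        comp = cell_composition(exp)
        np.testing.assert_allclose(comp.sum(axis=1).to_numpy(), 1.0, atol=1e-9)
        assert comp.loc["u1", "A"] == 0.0

    def test_permutation_invariance(self):
        types = ["A"] * 5 + ["B"] * 3
        rng = np.random.default_rng(1)
        c1 = cell_composition(_exp_of([(_typed_layer(types), {})]))
        c2 = cell_composition(_exp_of([(_typed_layer(list(rng.permutation(types))), {})]))
        pd.testing.assert_frame_equal(c1, c2)

    def test_missing_column_raises(self):
        layer = _typed_layer(["A"])
        layer.cell_table = layer.cell_table.drop(columns="cell_type")
        with pytest.raises(KeyError):
            cell_composition(_exp_of([(layer, {})]))

    def test_planted_fractions_recovered(self):
        """Spatially planted type fractions recovered from 2000 cells within ±0.03."""
        sample, truth = generate_sample(
            n_cells=2000, image_px=2048, type_fractions=(0.5, 0.3, 0.2),
            seed=11, render_image=False,
        )
        sample.uid = "big"
        exp = Experiment().add(sample, {})
        comp = cell_composition(exp)
        np.testing.assert_allclose(
            comp.loc["big", ["A", "B", "C"]].to_numpy(), [0.5, 0.3, 0.2], atol=0.03
        )


class TestDensity:
    def test_one_mm_square(self):
        layer = _typed_layer(["A"] * 10)
        layer.cell_table["centroid_x"] = np.linspace(10, 900, 10)
        layer.cell_table["centroid_y"] = 500.0
        sample = Sample(uid="d", cells={"default": layer})
        pset = PolygonSet(scope="region")
        pset.add("sq", "core", [(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        sample.regions["mm"] = pset
        out = cell_type_density(sample, "mm")
        assert out.loc[0, "density_per_mm2"] == pytest.approx(10.0)

    def test_empty_polygon_region_zero_density(self):
        layer = _typed_layer(["A", "B"])
        layer.cell_table["centroid_x"] = [5.0, 6.0]
        layer.cell_table["centroid_y"] = [5.0, 6.0]
        sample = Sample(uid="d", cells={"default": layer})
        pset = PolygonSet(scope="annotation")
        pset.add("far", "x", [(500, 500), (600, 500), (600, 600), (500, 600)])
        sample.annotations["a"] = pset
        out = cell_type_density(sample, "a")
        assert (out["density_per_mm2"] == 0).all()

    def test_zero_area_polygon_rejected(self):
        layer = _typed_layer(["A"])
        sample = Sample(uid="d", cells={"default": layer})
        pset = PolygonSet(scope="annotation")
        pset.add("line", "x", [(0, 0), (10, 0), (5, 0), (2, 0)])
        sample.annotations["a"] = pset
        with pytest.raises(InvalidPolygonError):
            cell_type_density(sample, "a")

    def test_matches_brute_force_oracle(self, small_sample):
        sample, _ = small_sample
        out = cell_type_density(sample, "bands")
        layer = sample.cells["default"]
        from spatiomux import points_in_polygon, polygon_area

        for _, row in out.iterrows():
            entry = next(e for e in sample.annotations["bands"] if e.name == row["polygon"])
            inside = points_in_polygon(layer.centroids(), entry.vertices)
            n = int(np.sum(inside & (layer.cell_table["cell_type"] == row["cell_type"]).to_numpy()))
            assert row["n_cells"] == n
            assert row["density_per_mm2"] == pytest.approx(n / (polygon_area(entry.vertices) / 1e6))

    def test_density_scales_linearly_with_count(self):
        base = _typed_layer(["A"] * 4)
        base.cell_table["centroid_x"] = [10, 20, 30, 40]
        base.cell_table["centroid_y"] = [50, 50, 50, 50]
        doubled = _typed_layer(["A"] * 8, seed=2)
        doubled.cell_table["centroid_x"] = [10, 20, 30, 40, 12, 22, 32, 42]
        doubled.cell_table["centroid_y"] = 50.0
        pset = PolygonSet(scope="region")
        pset.add("sq", "core", [(0, 0), (100, 0), (100, 100), (0, 100)])
        d1 = cell_type_density(Sample(uid="a", cells={"default": base}, regions={"r": pset}), "r")
        d2 = cell_type_density(Sample(uid="b", cells={"default": doubled}, regions={"r": pset}), "r")
        assert d2.loc[0, "density_per_mm2"] == pytest.approx(2 * d1.loc[0, "density_per_mm2"])


class TestBHAdjust:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5), [1.0] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 200)
        p[:10] /= 1000
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)

    def test_step_up_monotone_in_p_rank(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert q.max() <= 1.0


class TestDifferentialExpression:
    def test_identical_groups_zero_lfc(self):
        a, _, _ = generate_dge_pair(n_cells=20, n_genes=10, seed=1)
        res = differential_expression(a, a)
        np.testing.assert_allclose(res["log2_fold_change"], 0.0, atol=1e-12)

    def test_symmetry_under_group_swap(self):
        a, b, _ = generate_dge_pair(n_cells=30, n_genes=20, seed=2)
        ab = differential_expression(a, b)
        ba = differential_expression(b, a)
        np.testing.assert_allclose(
            ab["log2_fold_change"].to_numpy(), -ba["log2_fold_change"].to_numpy(), atol=1e-9
        )
        np.testing.assert_allclose(ab["p_value"].to_numpy(), ba["p_value"].to_numpy(), atol=1e-12)

    def test_null_type_one_error_calibrated(self):
        """Fraction of p<0.05 under the null lies in the binomial band."""
        a, b, _ = generate_dge_pair(null=True, seed=13)
        res = differential_expression(a, b)
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_planted_markers_recovered(self):
        """All 10 planted 4x markers top the |statistic| ranking at q<0.05."""
        a, b, markers = generate_dge_pair(seed=13)
        res = differential_expression(a, b)
        marker_names = {f"gene_{g:03d}" for g in markers}
        by_stat = res.reindex(res["statistic"].abs().sort_values(ascending=False).index)
        assert set(by_stat.head(10)["feature"]) == marker_names
        assert (res.loc[res["feature"].isin(marker_names), "q_value"] < 0.05).all()
        assert (res.loc[res["feature"].isin(marker_names), "log2_fold_change"] > 0).all()

    def test_group_size_and_feature_mismatch_errors(self):
        a, b, _ = generate_dge_pair(n_cells=10, n_genes=5, seed=3)
        single = a.subset(np.arange(10) == 0)
        with pytest.raises(ValueError, match="2 cells"):
            differential_expression(single, b)
        other = CellLayer(
            b.matrix, b.cell_table.copy(),
            pd.DataFrame({"feature": [f"other{i}" for i in range(5)]}),
        )
        with pytest.raises(FeatureMismatchError):
            differential_expression(a, other)

    def test_partial_overlap_uses_intersection(self):
        a, b, _ = generate_dge_pair(n_cells=10, n_genes=6, seed=4)
        renamed = list(b.feature_table["feature"])
        renamed[-1] = "private_gene"
        b2 = CellLayer(b.matrix, b.cell_table.copy(), pd.DataFrame({"feature": renamed}))
        res = differential_expression(a, b2)
        assert len(res) == 5
        assert "private_gene" not in set(res["feature"])


class TestPseudobulk:
    def test_single_group_equals_column_sums(self):
        layer = _typed_layer(["A"] * 4, n_genes=3, seed=5)
        exp = _exp_of([(layer, {"g": "only"})])
        pb = pseudobulk(exp, group_key="g")
        np.testing.assert_array_equal(
            pb.loc["only"].to_numpy(), layer.dense_matrix().sum(axis=0)
        )

    def test_groups_partition_conserves_totals(self, small_experiment):
        exp, _ = small_experiment
        pb = pseudobulk(exp, group_key="condition")
        total = sum(s.cells["default"].dense_matrix().sum() for _, s in exp)
        assert pb.to_numpy().sum() == total

    def test_matches_brute_force_oracle(self, small_experiment):
        exp, _ = small_experiment
        pb = pseudobulk(exp, group_key="condition")
        for cond in ("treated", "control"):
            acc = 0
            for row, s in exp:
                if row["condition"] == cond:
                    acc = acc + s.cells["default"].dense_matrix().sum(axis=0)
            np.testing.assert_array_equal(pb.loc[cond].to_numpy(), acc)

    def test_empty_feature_intersection_rejected(self):
        l1 = _typed_layer(["A"], n_genes=2, seed=6)
        l2 = CellLayer(
            l1.matrix.copy(), l1.cell_table.copy(), pd.DataFrame({"feature": ["x", "y"]})
        )
        exp = _exp_of([(l1, {}), (l2, {})])
        with pytest.raises(FeatureMismatchError):
            pseudobulk(exp)
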