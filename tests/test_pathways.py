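"""Function aggregation, layer log2 ratios, split-node assembly, heatmap export."""

import numpy as np
import pandas as pd
import pytest

from metaomix.core import (
    AbundanceMatrix,
    MetaomixError,
    PathwayDefinition,
    PathwayNode,
    SampleMetadata,
)
from metaomix.pathways import (
    LayerRatios,
    SplitNodeTable,
    aggregate_to_function,
    assemble_split_nodes,
    export_split_heatmap,
    layer_log2_ratio,
)


def _annotated(values, features, samples, annotations, layer=None):
    ann = pd.DataFrame(index=features, columns=["taxon", "ec", "ko"], dtype=object)
    for f in features:
        ko, ec = annotations.get(f, ((), ()))
        ann.at[f, "taxon"] = None
        ann.at[f, "ko"] = frozenset(ko)
        ann.at[f, "ec"] = frozenset(ec)
    return AbundanceMatrix(
        pd.DataFrame(values, index=features, columns=samples),
        feature_annotations=ann,
        layer=layer,
    )


def _meta(groups):
    samples = [f"s{i}" for i in range(len(groups))]
    return SampleMetadata(
        pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample")),
        phenotype="group",
    )


class TestAggregateToFunction:
    def test_single_feature_single_ko(self):
        m = _annotated([[3.0, 5.0]], ["f1"], ["s0", "s1"], {"f1": (("K00001",), ())})
        fn, support, dropped = aggregate_to_function(m)
        np.testing.assert_allclose(fn.values.loc["K00001"], [3.0, 5.0])
        assert support["K00001"] == 1 and dropped == 0

    def test_two_features_sharing_ko_summed(self):
        m = _annotated(
            [[3.0], [4.0]], ["f1", "f2"], ["s0"],
            {"f1": (("K00001",), ()), "f2": (("K00001",), ())},
        )
        fn, support, _ = aggregate_to_function(m)
        assert fn.values.loc["K00001", "s0"] == 7.0 and support["K00001"] == 2

    def test_unannotated_dropped_with_tally(self):
        m = _annotated(
            [[3.0], [4.0]], ["f1", "naked"], ["s0"], {"f1": (("K00001",), ())}
        )
        _, _, dropped = aggregate_to_function(m)
        assert dropped == 1

    def test_no_annotations_is_error(self):
        m = _annotated([[1.0]], ["f1"], ["s0"], {})
        with pytest.raises(MetaomixError):
            aggregate_to_function(m)

    def test_matches_scatter_add_oracle(self):
        rng = np.random.default_rng(113)
        feats = [f"f{i:02d}" for i in range(25)]
        kos = [f"K{i:05d}" for i in range(1, 7)]
        ecs = ["1.1.1.1", "2.2.2.2"]
        ann = {}
        for f in feats:
            ks = tuple(rng.choice(kos, size=rng.integers(0, 3), replace=False))
            es = tuple(rng.choice(ecs, size=rng.integers(0, 2), replace=False))
            ann[f] = (ks, es)
        vals = rng.gamma(2, 5, size=(25, 4))
        m = _annotated(vals, feats, [f"s{i}" for i in range(4)], ann)
        fn, support, dropped = aggregate_to_function(m)
        expected: dict = {}
        exp_support: dict = {}
        exp_dropped = 0
        for i, f in enumerate(feats):
            ids = set(ann[f][0]) | set(ann[f][1])
            if not ids:
                exp_dropped += 1
                continue
            for fid in ids:
                expected[fid] = expected.get(fid, np.zeros(4)) + vals[i]
                exp_support[fid] = exp_support.get(fid, 0) + 1
        assert dropped == exp_dropped
        assert set(fn.features) == set(expected)
        for fid in expected:
            np.testing.assert_allclose(fn.values.loc[fid], expected[fid])
            assert support[fid] == exp_support[fid]

    def test_split_weights_divides_contribution(self):
        m = _annotated(
            [[6.0]], ["f1"], ["s0"], {"f1": (("K00001", "K00002"), ())}
        )
        fn, _, _ = aggregate_to_function(m, split_weights=True)
        assert fn.values.loc["K00001", "s0"] == 3.0
        assert fn.values.loc["K00002", "s0"] == 3.0


class TestLayerLog2Ratio:
    def _fn(self, vals, samples):
        feats = [f"K{i:05d}" for i in range(1, len(vals) + 1)]
        ann = {f: ((f,), ()) for f in feats}
        return _annotated(vals, feats, samples, ann)

    def test_identical_group_means_give_zero(self):
        m = self._fn([[2.0, 2.0, 4.0, 4.0]], ["s0", "s1", "s2", "s3"])
        lr = layer_log2_ratio(m, _meta(["A", "B", "A", "B"]), "A", "B", pseudocount=0.0)
        np.testing.assert_allclose(lr.ratios, [0.0], atol=1e-12)

    def test_doubled_mean_gives_one(self):
        # two features so TSS is nontrivial; feature 1 share doubles in B
        vals = np.array([[10.0, 10.0, 20.0, 20.0], [90.0, 90.0, 80.0, 80.0]])
        m = self._fn(vals, ["s0", "s1", "s2", "s3"])
        lr = layer_log2_ratio(m, _meta(["A", "A", "B", "B"]), "A", "B", pseudocount=0.0)
        assert lr.ratios.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_toy_table(self):
        vals = np.array(
            [
                [10.0, 30.0, 20.0, 60.0],
                [40.0, 20.0, 60.0, 20.0],
                [50.0, 50.0, 20.0, 20.0],
            ]
        )
        samples = [f"s{i}" for i in range(4)]
        m = self._fn(vals, samples)
        lr = layer_log2_ratio(m, _meta(["A", "A", "B", "B"]), "A", "B", pseudocount=0.0)
        rel = vals / vals.sum(axis=0, keepdims=True)
        expected = np.log2(rel[:, 2:].mean(axis=1) / rel[:, :2].mean(axis=1))
        np.testing.assert_allclose(lr.ratios.to_numpy(), expected, atol=1e-10)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(127)
        vals = rng.gamma(2, 10, size=(6, 8))
        m = self._fn(vals, [f"s{i}" for i in range(8)])
        meta = _meta(["A"] * 4 + ["B"] * 4)
        ab = layer_log2_ratio(m, meta, "A", "B", pseudocount=1e-6)
        ba = layer_log2_ratio(m, meta, "B", "A", pseudocount=1e-6)
        np.testing.assert_array_equal(ab.ratios.to_numpy(), -ba.ratios.to_numpy())

    def test_scale_invariance_per_sample(self):
        rng = np.random.default_rng(131)
        vals = rng.gamma(2, 10, size=(5, 6))
        scaled = vals.copy()
        scaled[:, 2] *= 37.0
        meta = _meta(["A"] * 3 + ["B"] * 3)
        r1 = layer_log2_ratio(self._fn(vals, [f"s{i}" for i in range(6)]), meta, "A", "B", pseudocount=1e-9)
        r2 = layer_log2_ratio(self._fn(scaled, [f"s{i}" for i in range(6)]), meta, "A", "B", pseudocount=1e-9)
        np.testing.assert_allclose(r1.ratios, r2.ratios, atol=1e-12)

    def test_epsilon_limit_converges_on_positive_data(self):
        rng = np.random.default_rng(137)
        vals = rng.gamma(5, 10, size=(4, 6)) + 1.0
        m = self._fn(vals, [f"s{i}" for i in range(6)])
        meta = _meta(["A"] * 3 + ["B"] * 3)
        exact = layer_log2_ratio(m, meta, "A", "B", pseudocount=0.0)
        diffs = []
        for eps in (1e-3, 1e-6, 1e-9):
            approx = layer_log2_ratio(m, meta, "A", "B", pseudocount=eps)
            diffs.append(np.abs(approx.ratios - exact.ratios).max())
        assert diffs == sorted(diffs, reverse=True) or diffs[-1] < 1e-12
        assert diffs[-1] < 1e-8

    def test_unknown_group_label_rejected(self):
        m = self._fn([[1.0, 2.0, 1.0]], ["s0", "s1", "s2"])
        with pytest.raises(MetaomixError, match="nope"):
            layer_log2_ratio(m, _meta(["A", "B", "A"]), "A", "nope")


def _ratios(layer, mapping):
    return LayerRatios(
        layer=layer, ratios=pd.Series(mapping, dtype=float), group_a="A", group_b="B"
    )


class TestAssembleSplitNodes:
    def _pathway(self):
        return PathwayDefinition(
            id="pw",
            nodes={
                "n1": PathwayNode("one", kos=frozenset({"K00001"})),
                "n2": PathwayNode("two", kos=frozenset({"K00002", "K00003"})),
                "n3": PathwayNode("three", ecs=frozenset({"1.1.1.1"})),
            },
        )

    def test_single_ko_present_in_one_layer_only(self):
        table = assemble_split_nodes(
            self._pathway(),
            [_ratios("MG", {"K00001": 0.7}), _ratios("MP", {"K00099": 1.0})],
        )
        assert table.values.loc["n1", "MG"] == pytest.approx(0.7)
        assert np.isnan(table.values.loc["n1", "MP"])

    def test_mean_combine_over_two_kos(self):
        table = assemble_split_nodes(
            self._pathway(), [_ratios("MG", {"K00002": 1.0, "K00003": 3.0})]
        )
        assert table.values.loc["n2", "MG"] == pytest.approx(2.0)

    def test_max_abs_combine(self):
        table = assemble_split_nodes(
            self._pathway(),
            [_ratios("MG", {"K00002": 1.0, "K00003": -3.0})],
            combine="max_abs",
        )
        assert table.values.loc["n2", "MG"] == pytest.approx(-3.0)

    def test_ec_ids_match_too(self):
        table = assemble_split_nodes(self._pathway(), [_ratios("MP", {"1.1.1.1": -0.4})])
        assert table.values.loc["n3", "MP"] == pytest.approx(-0.4)

    def test_empty_pathway_rejected(self):
        with pytest.raises(MetaomixError):
            assemble_split_nodes(PathwayDefinition(id="empty"), [_ratios("MG", {"K1": 0.0})])

    def test_matches_nested_loop_oracle_on_12_node_pathway(self):
        rng = np.random.default_rng(139)
        kos = [f"K{i:05d}" for i in range(1, 25)]
        nodes = {}
        for n in range(12):
            picked = rng.choice(kos, size=int(rng.integers(1, 4)), replace=False)
            nodes[f"n{n:02d}"] = PathwayNode(f"step{n}", kos=frozenset(str(k) for k in picked))
        pathway = PathwayDefinition(id="fixture", nodes=nodes)
        layers = []
        for layer in ["MG", "MT", "MP"]:
            present = rng.choice(kos, size=15, replace=False)
            layers.append(
                _ratios(layer, {str(k): float(rng.normal()) for k in present})
            )
        table = assemble_split_nodes(pathway, layers, combine="mean")
        for nid, node in pathway.nodes.items():
            for lr in layers:
                hits = [lr.ratios[k] for k in sorted(node.kos) if k in lr.ratios.index]
                cell = table.values.loc[nid, lr.layer]
                if hits:
                    assert cell == pytest.approx(float(np.mean(hits)))
                    assert table.matched_ids[(nid, lr.layer)] == tuple(
                        sorted(k for k in node.kos if k in lr.ratios.index)
                    )
                else:
                    assert np.isnan(cell)

    def test_cell_presence_iff_any_id_matched(self):
        table = assemble_split_nodes(
            self._pathway(), [_ratios("MG", {"K00003": 0.5})]
        )
        present = table.values.notna()
        assert present.loc["n2", "MG"] and not present.loc["n1", "MG"]


class TestHeatmapExport:
    def _table(self):
        values = pd.DataFrame(
            [[1.0, np.nan], [-0.5, 0.25]], index=["n1", "n2"], columns=["MG", "MP"]
        )
        labels = pd.Series({"n1": "one", "n2": "two"})
        return SplitNodeTable(pathway_id="pw", values=values, labels=labels)

    def test_tsv_round_trip(self, tmp_path):
        table = self._table()
        export_split_heatmap(table, tmp_path / "h.svg", tsv_path=tmp_path / "h.tsv")
        back = SplitNodeTable.from_tsv(tmp_path / "h.tsv", pathway_id="pw")
        pd.testing.assert_frame_equal(back.values, table.values, check_names=False)
        assert list(back.labels) == list(table.labels)

    def test_deterministic_rerender(self, tmp_path):
        import metaomix.plots  # applies deterministic matplotlib settings

        table = self._table()
        export_split_heatmap(table, tmp_path / "a.svg", tsv_path=tmp_path / "a.tsv")
        export_split_heatmap(table, tmp_path / "b.svg", tsv_path=tmp_path / "b.tsv")
        assert (tmp_path / "a.svg").read_bytes() == (tmp_path / "b.svg").read_bytes()

    def test_all_zero_table_renders(self, tmp_path):
        values = pd.DataFrame(0.0, index=["n1"], columns=["MG"])
        table = SplitNodeTable("pw", values, pd.Series({"n1": "one"}))
        export_split_heatmap(table, tmp_path / "z.svg")
        assert (tmp_path / "z.svg").exists() and (tmp_path / "z.tsv").exists()
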