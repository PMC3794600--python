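"""Decision-tree induction, pruning, cross-validation and rendering."""

import math

import numpy as np
import pandas as pd
import pytest

from methexpr import tree as T
from methexpr.core import UsageError
from methexpr.simulate import simulate_tree_instances
from methexpr.tree import (
    HIGH,
    LOW,
    Leaf,
    Node,
    TreeInstance,
    best_split,
    build_instances,
    cross_validate,
    induce_tree,
    parse_tree,
    predict_one,
    render_tree,
)


def make_instances(attr_rows, labels, attrs=("CGI", "Exon1")):
    return [
        TreeInstance(f"g{i}", f"c{i}", dict(zip(attrs, row)), lab)
        for i, (row, lab) in enumerate(zip(attr_rows, labels))
    ]


# ---------------------------------------------------------------------------
# instance construction

class TestBuildInstances:
    @pytest.fixture()
    def lu_instances(self, small_dataset):
        ds = small_dataset
        genes = list(ds.truth.planted_dm_genes["Lu"])
        calls = pd.DataFrame(
            {"gene_id": genes, "subtype": ["Lu"] * len(genes)}
        )
        return genes, build_instances(calls, ds.binned, ds.catalog, ds.subtypes)

    def test_instance_and_class_counts(self, lu_instances):
        genes, instances = lu_instances
        assert len(instances) == 30 * len(genes)
        n_low = sum(1 for i in instances if i.label == LOW)
        assert n_low == 13 * len(genes)  # 13 Lu lines marked low per gene

    def test_single_gene_split_13_17(self, small_dataset):
        ds = small_dataset
        gene = ds.truth.planted_dm_genes["Lu"][0]
        calls = pd.DataFrame({"gene_id": [gene], "subtype": ["Lu"]})
        instances = build_instances(calls, ds.binned, ds.catalog, ds.subtypes)
        labels = [i.label for i in instances]
        assert labels.count(LOW) == 13 and labels.count(HIGH) == 17

    def test_attributes_are_z_scored(self, lu_instances):
        _, instances = lu_instances
        for attr in instances[0].attributes:
            vals = np.array([i.attributes[attr] for i in instances])
            vals = vals[~np.isnan(vals)]
            assert np.mean(vals) == pytest.approx(0.0, abs=1e-9)
            assert np.std(vals) == pytest.approx(1.0, abs=1e-9)

    def test_mixed_subtypes_rejected(self, small_dataset):
        ds = small_dataset
        calls = pd.DataFrame(
            {"gene_id": ["G0001", "G0002"], "subtype": ["Lu", "BaB"]}
        )
        with pytest.raises(UsageError, match="one subtype"):
            build_instances(calls, ds.binned, ds.catalog, ds.subtypes)

    def test_cgi_overlap_separation_mode(self, small_dataset):
        ds = small_dataset
        genes = list(ds.truth.planted_dm_genes["Lu"])
        calls = pd.DataFrame({"gene_id": genes, "subtype": ["Lu"] * len(genes)})
        instances = build_instances(
            calls, ds.binned, ds.catalog, ds.subtypes, separate_cgi_overlap=True
        )
        names = set(instances[0].attributes)
        # synthetic CGIs overlap the proximal promoter and first exon
        assert "TSS1-1000|CGIov" in names and "TSS1-1000|nonCGI" in names


# ---------------------------------------------------------------------------
# induction

def exhaustive_depth1(instances):
    """Oracle: best information-gain stump by brute force over every
    attribute and midpoint threshold."""
    def entropy(nl, nh):
        n = nl + nh
        if n == 0 or nl == 0 or nh == 0:
            return 0.0
        p = nl / n
        return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))

    attrs = sorted({a for i in instances for a in i.attributes})
    y = [i.label == LOW for i in instances]
    parent = entropy(sum(y), len(y) - sum(y))
    best_gain = -1.0
    for a in attrs:
        vals = sorted({i.attributes[a] for i in instances if not math.isnan(i.attributes[a])})
        for v1, v2 in zip(vals, vals[1:]):
            thr = (v1 + v2) / 2
            nl_l = nh_l = nl_r = nh_r = 0
            for inst, is_low in zip(instances, y):
                v = inst.attributes[a]
                if math.isnan(v):
                    continue
                if v <= thr:
                    nl_l, nh_l = nl_l + is_low, nh_l + (not is_low)
                else:
                    nl_r, nh_r = nl_r + is_low, nh_r + (not is_low)
            n = nl_l + nh_l + nl_r + nh_r
            gain = parent - (
                (nl_l + nh_l) / n * entropy(nl_l, nh_l)
                + (nl_r + nh_r) / n * entropy(nl_r, nh_r)
            )
            if gain > best_gain + 1e-12:
                best_gain = gain
    return best_gain


class TestInduction:
    def test_depth1_matches_exhaustive_search(self):
        rng = np.random.default_rng(13)
        for trial in range(5):
            n = int(rng.integers(20, 200))
            rows = rng.normal(size=(n, 3))
            labels = [LOW if r[0] + 0.5 * r[1] + rng.normal(0, 0.5) > 0 else HIGH
                      for r in rows]
            instances = make_instances(rows, labels, attrs=("CGI", "Exon1", "Intron1"))
            if len(set(labels)) < 2:
                continue
            split = best_split(instances, ("CGI", "Exon1", "Intron1"))
            oracle_gain = exhaustive_depth1(instances)
            if split is None:
                assert oracle_gain <= 1e-12
            else:
                assert split[2] == pytest.approx(oracle_gain, abs=1e-12)

    def test_separable_single_attribute_rule(self):
        rng = np.random.default_rng(2)
        rows = rng.uniform(-2, 2, size=(100, 2))
        labels = [LOW if r[0] > 0.5 else HIGH for r in rows]
        instances = make_instances(rows, labels)
        tree = induce_tree(instances, max_depth=1, prune_fraction=0)
        assert isinstance(tree, Node)
        assert tree.attribute == "CGI"
        assert tree.depth == 1
        assert all(predict_one(tree, i.attributes) == i.label for i in instances)

    def test_pure_class_single_leaf(self):
        instances = make_instances([[0, 1], [1, 0], [2, 2]], [HIGH, HIGH, HIGH])
        tree = induce_tree(instances, prune_fraction=0)
        assert isinstance(tree, Leaf) and tree.label == HIGH

    def test_conjunctive_rule_recovered(self):
        instances = simulate_tree_instances(n_genes=20, rule="conjunctive", seed=4)
        tree = induce_tree(instances, max_depth=3, prune_fraction=0)
        used = set()

        def walk(node):
            if isinstance(node, Node):
                used.add(node.attribute)
                walk(node.left)
                walk(node.right)

        walk(tree)
        assert {"TSS1001-2000", "Exon1"} <= used
        acc = np.mean(
            [predict_one(tree, i.attributes) == i.label for i in instances]
        )
        assert acc >= 0.95

    def test_max_depth_respected(self):
        instances = simulate_tree_instances(n_genes=10, rule="conjunctive", seed=5)
        for depth in (1, 2, 3):
            tree = induce_tree(instances, max_depth=depth, prune_fraction=0)
            assert tree.depth <= depth

    def test_determinism(self):
        instances = simulate_tree_instances(n_genes=10, rule="conjunctive", seed=6,
                                            label_noise=0.1)
        t1 = induce_tree(instances, seed=3)
        t2 = induce_tree(instances, seed=3)
        assert render_tree(t1) == render_tree(t2)

    def test_too_few_instances_rejected(self):
        with pytest.raises(UsageError):
            induce_tree(make_instances([[0, 0]], [LOW]))


class TestPruning:
    def test_pruning_never_increases_holdout_error(self):
        from methexpr.tree import _errors, _grow, _prune

        rng = np.random.default_rng(8)
        instances = simulate_tree_instances(n_genes=15, rule="conjunctive", seed=8,
                                            label_noise=0.25)
        idx = rng.permutation(len(instances))
        split = len(instances) * 2 // 3
        grow_set = [instances[i] for i in idx[:split]]
        hold = [instances[i] for i in idx[split:]]
        attrs = sorted(instances[0].attributes)
        grown = _grow(grow_set, attrs, 3)
        pruned = _prune(grown, hold)
        assert _errors(pruned, hold) <= _errors(grown, hold)

    def test_noise_collapses_to_majority(self):
        instances = simulate_tree_instances(n_genes=20, rule="null", seed=9)
        # attributes carry no class signal; pruning should leave a stump or leaf
        tree = induce_tree(instances, max_depth=3, prune_fraction=1 / 3, seed=0)
        majority = max(
            (sum(1 for i in instances if i.label == lab), lab) for lab in (LOW, HIGH)
        )[1]
        acc = np.mean([predict_one(tree, i.attributes) == i.label for i in instances])
        base = np.mean([i.label == majority for i in instances])
        assert acc >= base - 0.05


class TestCrossValidation:
    def test_separable_data_high_accuracy(self):
        instances = simulate_tree_instances(n_genes=20, rule="conjunctive", seed=10)
        acc, folds = cross_validate(instances, max_depth=3, k=10, seed=0)
        assert len(folds) == 10
        assert acc >= 0.95

    def test_null_data_near_majority_rate(self):
        instances = simulate_tree_instances(n_genes=20, rule="null", seed=11)
        acc, _ = cross_validate(instances, max_depth=3, k=10, seed=0)
        majority_rate = 17 / 30
        assert abs(acc - majority_rate) <= 0.1

    def test_leave_one_out_boundary(self):
        instances = simulate_tree_instances(n_genes=1, rule="single", seed=12)
        acc, folds = cross_validate(instances, k=len(instances), seed=0)
        assert 0.0 <= acc <= 1.0

    def test_k_validation(self):
        instances = simulate_tree_instances(n_genes=2, seed=0)
        with pytest.raises(UsageError):
            cross_validate(instances, k=1)
        with pytest.raises(UsageError):
            cross_validate(instances, k=len(instances) + 1)


class TestRendering:
    def test_depth1_diagram_three_lines(self):
        tree = Node("CGI", 0.5, Leaf(HIGH, 1, 9), Leaf(LOW, 8, 2), 9, 11)
        text = render_tree(tree)
        assert len(text.strip().splitlines()) == 3
        assert "CGI <= 0.5" in text
        assert "(Down)" in text and "(Up)" in text

    def test_round_trip(self):
        instances = simulate_tree_instances(n_genes=10, rule="conjunctive", seed=14,
                                            label_noise=0.05)
        tree = induce_tree(instances, seed=1)
        text = render_tree(tree)
        back = parse_tree(text)
        assert render_tree(back) == text

    def test_leaf_counts_shown(self):
        text = render_tree(Leaf(LOW, 12, 3))
        assert "[low=12, high=3]" in text
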