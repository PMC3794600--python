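"""Depth-limited decision-tree induction with reduced-error pruning
(protocol 3).

Each (downregulated gene, cell line) pair is an instance; the attributes
are the z-scored methylation levels of the named genomic regions and the
class is ``low`` when the cell line belongs to the subtype in which the
gene is downregulated, else ``high``.  Trees use greedy binary splits that
maximize information gain over candidate thresholds (midpoints of sorted
distinct values) and are post-pruned against a held-out, stratified
fraction of the instances: a subtree is collapsed to a leaf whenever the
leaf does not increase held-out error (reduced-error pruning).

Conventions chosen where the procedure is otherwise open:

* tie-breaking among equal-gain splits follows the canonical attribute
  order ``TSS1-1000, TSS1001-2000, CGI, CGIShore, Exon1, Intron1, Exon2``
  (then the smaller threshold);
* instances missing the split attribute are routed to the child that
  received the larger training mass (ties: left);
* the right branch is the higher-methylation side.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import REGION_ORDER, SUBTYPES, SubtypeTable, UsageError
from .profiles import BinnedMethylation
from .regions import RegionCatalog

LOW, HIGH = "low", "high"
DEFAULT_MAX_DEPTH = 3
DEFAULT_PRUNE_FRACTION = 1.0 / 3.0
DEFAULT_CV_FOLDS = 10


@dataclass(frozen=True)
class TreeInstance:
    gene_id: str
    cell_line_id: str
    attributes: Mapping[str, float]  # NaN marks a missing region
    label: str

    def __post_init__(self) -> None:
        if self.label not in (LOW, HIGH):
            raise UsageError(f"label must be '{LOW}' or '{HIGH}'")


@dataclass
class Leaf:
    label: str
    n_low: int
    n_high: int

    @property
    def depth(self) -> int:
        return 0


@dataclass
class Node:
    attribute: str
    threshold: float
    left: "Node | Leaf"  # attribute <= threshold (hypomethylated side)
    right: "Node | Leaf"  # attribute >  threshold (hypermethylated side)
    n_low: int
    n_high: int
    missing_to_left: bool = True

    @property
    def depth(self) -> int:
        return 1 + max(self.left.depth, self.right.depth)


DecisionTree = Node | Leaf


# ---------------------------------------------------------------------------
# instance construction

def build_instances(
    down_calls: pd.DataFrame,
    binned: BinnedMethylation,
    catalog: RegionCatalog,
    subtypes: SubtypeTable,
    attributes: Sequence[str] = REGION_ORDER,
    separate_cgi_overlap: bool = False,
) -> list[TreeInstance]:
    """One instance per (called gene, cell line) with z-scored attributes.

    ``down_calls`` must concern a single subtype.  With
    ``separate_cgi_overlap`` the promoter and exon attributes are split
    into CGI-overlapping and non-overlapping variants.
    """
    from .profiles import region_level
    from .regions import _subtract

    called = set(down_calls["subtype"])
    if len(called) != 1:
        raise UsageError(f"calls must concern exactly one subtype, got {sorted(called)}")
    subtype = called.pop()
    genes = [g for g in down_calls["gene_id"] if g in binned.gene_ids and g in catalog]

    # attribute -> gene -> per-cell-line level
    attr_levels: dict[str, pd.DataFrame] = {}
    if not separate_cgi_overlap:
        for name in attributes:
            attr_levels[name] = region_level(binned, catalog, name)
    else:
        split_targets = {"TSS1-1000", "TSS1001-2000", "Exon1", "Exon2"}
        for name in attributes:
            if name not in split_targets:
                attr_levels[name] = region_level(binned, catalog, name)
                continue
            inside_rows, outside_rows = {}, {}
            for g in genes:
                gr = catalog[g]
                if name not in gr.regions:
                    continue
                cgis = list(gr.regions.get("CGI", ()))
                inside, outside = [], []
                for iv in gr.regions[name]:
                    pieces = _subtract(iv, cgis)
                    outside.extend(pieces)
                    for cs, ce in cgis:
                        s, e = max(iv[0], cs), min(iv[1], ce)
                        if e > s:
                            inside.append((s, e))
                for label, ivs, store in (
                    ("CGIov", inside, inside_rows),
                    ("nonCGI", outside, outside_rows),
                ):
                    if ivs:
                        lv = _weighted_level(binned, gr, ivs)
                        if lv is not None:
                            store[g] = lv
            for label, store in (("CGIov", inside_rows), ("nonCGI", outside_rows)):
                if store:
                    attr_levels[f"{name}|{label}"] = pd.DataFrame.from_dict(
                        store, orient="index", columns=list(binned.cell_lines)
                    )

    cell_lines = list(binned.cell_lines)
    low_mask = subtypes.mask(cell_lines, subtype)

    # assemble raw attribute values, then z-score each attribute globally
    names = list(attr_levels)
    raw: dict[str, np.ndarray] = {}
    for name in names:
        lv = attr_levels[name]
        mat = np.full((len(genes), len(cell_lines)), np.nan)
        for i, g in enumerate(genes):
            if g in lv.index:
                mat[i] = lv.loc[g, cell_lines].to_numpy(dtype=float)
        raw[name] = mat
    for name in names:
        m = raw[name]
        mu = np.nanmean(m) if not np.all(np.isnan(m)) else 0.0
        sd = np.nanstd(m)
        raw[name] = (m - mu) / sd if sd > 0 else m - mu

    instances: list[TreeInstance] = []
    n_dropped = 0
    for i, g in enumerate(genes):
        for j, cl in enumerate(cell_lines):
            attrs = {name: float(raw[name][i, j]) for name in names}
            if all(math.isnan(v) for v in attrs.values()):
                n_dropped += 1
                continue
            label = LOW if low_mask[j] else HIGH
            instances.append(TreeInstance(g, cl, attrs, label))
    if n_dropped:
        import warnings

        warnings.warn(f"dropped {n_dropped} instances with all attributes missing")
    return instances


def _weighted_level(binned, gr, intervals):
    from .profiles import _region_bin_weights

    bins, weights = _region_bin_weights(gr, intervals)
    if not len(bins):
        return None
    sub = binned.data.loc[gr.gene_id]
    present = [b for b in bins if b in sub.index]
    if not present:
        return None
    w = weights[[list(bins).index(b) for b in present]]
    vals = sub.loc[present].to_numpy()
    return (vals * w[:, None]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# induction

def _entropy(n_low: int, n_high: int) -> float:
    n = n_low + n_high
    if n == 0 or n_low == 0 or n_high == 0:
        return 0.0
    p = n_low / n
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def _attribute_order_key(name: str) -> tuple[int, str]:
    base = name.split("|")[0]
    try:
        return (REGION_ORDER.index(base), name)
    except ValueError:
        return (len(REGION_ORDER), name)


def best_split(
    instances: Sequence[TreeInstance], attributes: Sequence[str]
) -> tuple[str, float, float] | None:
    """Exhaustive best (attribute, threshold) by information gain.

    Gain is evaluated on the instances with the attribute present.
    Returns ``(attribute, threshold, gain)`` or None when no split has
    positive gain.
    """
    labels = np.array([inst.label == LOW for inst in instances])
    best: tuple[float, tuple[int, str], float, str] | None = None
    ordered = sorted(attributes, key=_attribute_order_key)
    for name in ordered:
        vals = np.array([inst.attributes.get(name, math.nan) for inst in instances])
        present = ~np.isnan(vals)
        if present.sum() < 2:
            continue
        v = vals[present]
        y = labels[present]
        order = np.argsort(v, kind="mergesort")
        v_sorted, y_sorted = v[order], y[order]
        distinct = np.unique(v_sorted)
        if len(distinct) < 2:
            continue
        thresholds = (distinct[:-1] + distinct[1:]) / 2
        total_low = int(y.sum())
        parent_h = _entropy(total_low, int((~y).sum()))
        n = len(v)
        cum_low = np.cumsum(y_sorted)
        for thr in thresholds:
            k = int(np.searchsorted(v_sorted, thr, side="right"))
            left_low = int(cum_low[k - 1]) if k > 0 else 0
            left_high = k - left_low
            right_low = total_low - left_low
            right_high = (n - k) - right_low
            gain = parent_h - (
                k / n * _entropy(left_low, left_high)
                + (n - k) / n * _entropy(right_low, right_high)
            )
            if best is None or gain > best[0] + 1e-12 or (
                abs(gain - best[0]) <= 1e-12
                and (_attribute_order_key(name), thr) < (best[1], best[2])
            ):
                best = (gain, _attribute_order_key(name), float(thr), name)
    if best is None or best[0] <= 1e-12:
        return None
    return best[3], best[2], best[0]


def _majority(n_low: int, n_high: int) -> str:
    # tie goes to the globally more frequent 'high' class
    return LOW if n_low > n_high else HIGH


def _grow(
    instances: list[TreeInstance], attributes: Sequence[str], max_depth: int
) -> DecisionTree:
    n_low = sum(1 for i in instances if i.label == LOW)
    n_high = len(instances) - n_low
    if max_depth == 0 or n_low == 0 or n_high == 0 or len(instances) < 2:
        return Leaf(_majority(n_low, n_high), n_low, n_high)
    split = best_split(instances, attributes)
    if split is None:
        return Leaf(_majority(n_low, n_high), n_low, n_high)
    name, thr, _gain = split
    left_i, right_i, missing_i = [], [], []
    for inst in instances:
        v = inst.attributes.get(name, math.nan)
        if math.isnan(v):
            missing_i.append(inst)
        elif v <= thr:
            left_i.append(inst)
        else:
            right_i.append(inst)
    missing_to_left = len(left_i) >= len(right_i)
    (left_i if missing_to_left else right_i).extend(missing_i)
    if not left_i or not right_i:
        return Leaf(_majority(n_low, n_high), n_low, n_high)
    return Node(
        name,
        thr,
        _grow(left_i, attributes, max_depth - 1),
        _grow(right_i, attributes, max_depth - 1),
        n_low,
        n_high,
        missing_to_left,
    )


def predict_one(tree: DecisionTree, attributes: Mapping[str, float]) -> str:
    node = tree
    while isinstance(node, Node):
        v = attributes.get(node.attribute, math.nan)
        if isinstance(v, float) and math.isnan(v):
            node = node.left if node.missing_to_left else node.right
        elif v <= node.threshold:
            node = node.left
        else:
            node = node.right
    return node.label


def _errors(tree: DecisionTree, instances: Sequence[TreeInstance]) -> int:
    return sum(1 for i in instances if predict_one(tree, i.attributes) != i.label)


def _prune(tree: DecisionTree, prune_set: list[TreeInstance]) -> DecisionTree:
    """Bottom-up reduced-error pruning; never increases prune-set error."""
    if isinstance(tree, Leaf):
        return tree
    left_set, right_set = [], []
    for inst in prune_set:
        v = inst.attributes.get(tree.attribute, math.nan)
        if isinstance(v, float) and math.isnan(v):
            (left_set if tree.missing_to_left else right_set).append(inst)
        elif v <= tree.threshold:
            left_set.append(inst)
        else:
            right_set.append(inst)
    pruned = Node(
        tree.attribute,
        tree.threshold,
        _prune(tree.left, left_set),
        _prune(tree.right, right_set),
        tree.n_low,
        tree.n_high,
        tree.missing_to_left,
    )
    as_leaf = Leaf(_majority(tree.n_low, tree.n_high), tree.n_low, tree.n_high)
    if _errors(as_leaf, prune_set) <= _errors(pruned, prune_set):
        return as_leaf
    return pruned


def _stratified_split(
    instances: Sequence[TreeInstance], fraction: float, rng: np.random.Generator
) -> tuple[list[TreeInstance], list[TreeInstance]]:
    grow, hold = [], []
    for label in (LOW, HIGH):
        group = [i for i in instances if i.label == label]
        idx = rng.permutation(len(group))
        n_hold = int(round(len(group) * fraction))
        held = {int(i) for i in idx[:n_hold]}
        for i, inst in enumerate(group):
            (hold if i in held else grow).append(inst)
    return grow, hold


def induce_tree(
    instances: Sequence[TreeInstance],
    max_depth: int = DEFAULT_MAX_DEPTH,
    prune_fraction: float = DEFAULT_PRUNE_FRACTION,
    seed: int = 0,
) -> DecisionTree:
    """Grow a depth-limited tree and apply reduced-error pruning.

    ``prune_fraction`` of the instances (stratified, seeded) is held out
    for pruning; 0 disables pruning and grows on everything.  Single-class
    input yields a single leaf.
    """
    instances = list(instances)
    if len(instances) < 2:
        raise UsageError("need at least 2 instances")
    if not 0 <= prune_fraction < 1:
        raise UsageError("prune_fraction must be in [0, 1)")
    attributes = sorted(
        {a for inst in instances for a in inst.attributes}, key=_attribute_order_key
    )
    if prune_fraction == 0:
        return _grow(instances, attributes, max_depth)
    rng = np.random.default_rng(seed)
    grow_set, prune_set = _stratified_split(instances, prune_fraction, rng)
    if not grow_set:
        raise UsageError("prune_fraction leaves no growing instances")
    tree = _grow(grow_set, attributes, max_depth)
    if prune_set:
        tree = _prune(tree, prune_set)
    return tree


def cross_validate(
    instances: Sequence[TreeInstance],
    max_depth: int = DEFAULT_MAX_DEPTH,
    k: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    prune_fraction: float = DEFAULT_PRUNE_FRACTION,
) -> tuple[float, list[float]]:
    """Stratified k-fold cross-validated accuracy (mean, per-fold)."""
    instances = list(instances)
    if k < 2:
        raise UsageError("k must be >= 2")
    if k > len(instances):
        raise UsageError("k exceeds the number of instances")
    rng = np.random.default_rng(seed)
    folds: list[list[TreeInstance]] = [[] for _ in range(k)]
    for label in (LOW, HIGH):
        group = [i for i in instances if i.label == label]
        for pos, idx in enumerate(rng.permutation(len(group))):
            folds[pos % k].append(group[int(idx)])
    accuracies = []
    for f in range(k):
        test = folds[f]
        train = [i for g in range(k) if g != f for i in folds[g]]
        if not test or not train:
            continue
        tree = induce_tree(
            train, max_depth=max_depth, prune_fraction=prune_fraction, seed=seed + f
        )
        correct = sum(1 for i in test if predict_one(tree, i.attributes) == i.label)
        accuracies.append(correct / len(test))
    return float(np.mean(accuracies)), accuracies


# ---------------------------------------------------------------------------
# rendering / serialization

def render_tree(tree: DecisionTree, indent: str = "|  ") -> str:
    """Indented text diagram; the right branch is the hypermethylated side
    and leaves carry Down (low) / Up (high) labels with class counts."""
    lines: list[str] = []

    def rec(node: DecisionTree, depth: int, prefix: str) -> None:
        pad = indent * depth
        if isinstance(node, Leaf):
            word = "Down" if node.label == LOW else "Up"
            lines.append(
                f"{pad}{prefix}{node.label} ({word}) [low={node.n_low}, high={node.n_high}]"
            )
            return
        lines.append(f"{pad}{prefix}{node.attribute} <= {node.threshold!r}")
        rec(node.left, depth + 1, "<= : ")
        rec(node.right, depth + 1, "> : ")

    rec(tree, 0, "")
    return "\n".join(lines) + "\n"


_LEAF_RE = re.compile(
    r"^(?P<prefix>(?:<= : |> : )?)(?P<label>low|high) \((?:Down|Up)\) "
    r"\[low=(?P<nl>\d+), high=(?P<nh>\d+)\]$"
)
_NODE_RE = re.compile(r"^(?P<prefix>(?:<= : |> : )?)(?P<attr>.+) <= (?P<thr>[^ ]+)$")


def parse_tree(text: str, indent: str = "|  ") -> DecisionTree:
    """Inverse of :func:`render_tree` (structure and counts round-trip)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    pos = 0

    def depth_of(line: str) -> int:
        d = 0
        while line.startswith(indent):
            line = line[len(indent):]
            d += 1
        return d

    def rec(depth: int) -> DecisionTree:
        nonlocal pos
        line = lines[pos]
        if depth_of(line) != depth:
            raise UsageError(f"malformed tree text at line {pos}: {line!r}")
        body = line[len(indent) * depth:]
        m = _LEAF_RE.match(body)
        if m:
            pos += 1
            return Leaf(m.group("label"), int(m.group("nl")), int(m.group("nh")))
        m = _NODE_RE.match(body)
        if not m:
            raise UsageError(f"unparseable tree line: {body!r}")
        pos += 1
        left = rec(depth + 1)
        right = rec(depth + 1)
        node = Node(m.group("attr"), float(m.group("thr")), left, right, 0, 0)
        node.n_low = left.n_low + right.n_low
        node.n_high = left.n_high + right.n_high
        return node

    tree = rec(0)
    if pos != len(lines):
        raise UsageError("trailing lines after tree")
    return tree


def tree_to_dict(tree: DecisionTree) -> dict:
    if isinstance(tree, Leaf):
        return {"leaf": tree.label, "n_low": tree.n_low, "n_high": tree.n_high}
    return {
        "attribute": tree.attribute,
        "threshold": tree.threshold,
        "missing_to_left": tree.missing_to_left,
        "n_low": tree.n_low,
        "n_high": tree.n_high,
        "left": tree_to_dict(tree.left),
        "right": tree_to_dict(tree.right),
    }


def tree_to_json(tree: DecisionTree) -> str:
    return json.dumps(tree_to_dict(tree), indent=2, sort_keys=True)
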