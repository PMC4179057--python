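"""C4.5-style decision tree with gain-ratio splitting.

Top-down recursive partitioning over a mixed-type observation table:
categorical attributes split into one branch per observed value, numeric
attributes into binary ``<= threshold`` splits with thresholds at the
midpoints between consecutive distinct sorted values.  At each node one
candidate split per attribute is scored; following Quinlan's heuristic,
only candidates whose information gain reaches the mean gain of all
candidates stay in the running, and among those the split with the
highest gain ratio (gain divided by the split's intrinsic information)
wins.  Ties break by attribute declaration order, then by the smaller
threshold.  Growth stops on purity, on a minimum leaf size, on a maximum
depth, or when no candidate has positive gain.  No post-pruning is
applied.

All quantities are in bits (log base 2).  Prediction routes unseen
categorical values to the majority child.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-12


def entropy(labels) -> float:
    """Shannon entropy of a label sequence, in bits."""
    _vals, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _partition_entropy(parts, n: int) -> tuple[float, float]:
    """(weighted child entropy, split info) over label partitions."""
    h = 0.0
    si = 0.0
    for part in parts:
        if len(part) == 0:
            continue
        w = len(part) / n
        h += w * entropy(part)
        si -= w * math.log2(w)
    return h, si


@dataclass(frozen=True)
class SplitCandidate:
    attr: str
    kind: str                      # "categorical" | "numeric"
    threshold: float | None
    gain: float
    gain_ratio: float


def categorical_split_score(values, labels) -> SplitCandidate | None:
    """Score the branch-per-value split of a categorical attribute."""
    values = np.asarray(values, dtype=object)
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    uniq = pd.unique(values)
    if len(uniq) < 2:
        return None
    parts = [labels[values == v] for v in uniq]
    h, si = _partition_entropy(parts, n)
    gain = entropy(labels) - h
    if si <= _EPS:
        return None
    return SplitCandidate("", "categorical", None, gain, gain / si)


def numeric_split_score(values, labels) -> SplitCandidate | None:
    """Best binary ``<= t`` split of a numeric attribute.

    Thresholds are midpoints between consecutive distinct sorted values;
    the threshold with the highest gain ratio wins, smaller threshold on
    ties.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    order = np.argsort(values, kind="stable")
    sv = values[order]
    sl = labels[order]
    distinct = np.unique(sv)
    if distinct.size < 2:
        return None
    h_parent = entropy(labels)
    best: SplitCandidate | None = None
    for i in range(distinct.size - 1):
        t = 0.5 * (distinct[i] + distinct[i + 1])
        k = np.searchsorted(sv, t, side="right")
        h, si = _partition_entropy([sl[:k], sl[k:]], n)
        if si <= _EPS:
            continue
        gain = h_parent - h
        gr = gain / si
        if best is None or gr > best.gain_ratio + _EPS:
            best = SplitCandidate("", "numeric", float(t), gain, gr)
    return best


def candidate_splits(
    df: pd.DataFrame,
    labels,
    categorical: list[str],
    numeric: list[str],
    min_leaf: int = 1,
) -> list[SplitCandidate]:
    """One best candidate per attribute, in declaration order, subject to
    the minimum-leaf constraint (numeric: both sides >= min_leaf;
    categorical: the two largest branches each >= min_leaf)."""
    labels = np.asarray(labels, dtype=object)
    out: list[SplitCandidate] = []
    for attr in categorical:
        values = df[attr].to_numpy(dtype=object)
        cand = categorical_split_score(values, labels)
        if cand is None:
            continue
        sizes = sorted(pd.Series(values).value_counts().to_numpy(), reverse=True)
        if len(sizes) < 2 or sizes[1] < min_leaf:
            continue
        out.append(SplitCandidate(attr, "categorical", None, cand.gain, cand.gain_ratio))
    for attr in numeric:
        values = df[attr].to_numpy(dtype=float)
        distinct = np.unique(values)
        if distinct.size < 2:
            continue
        h_parent = entropy(labels)
        order = np.argsort(values, kind="stable")
        sv, sl = values[order], labels[order]
        best: SplitCandidate | None = None
        for i in range(distinct.size - 1):
            t = 0.5 * (distinct[i] + distinct[i + 1])
            k = int(np.searchsorted(sv, t, side="right"))
            if k < min_leaf or len(sv) - k < min_leaf:
                continue
            h, si = _partition_entropy([sl[:k], sl[k:]], len(sl))
            if si <= _EPS:
                continue
            gr = (h_parent - h) / si
            if best is None or gr > best.gain_ratio + _EPS:
                best = SplitCandidate(attr, "numeric", float(t), h_parent - h, gr)
        if best is not None:
            out.append(best)
    return out


def select_split(candidates: list[SplitCandidate]) -> SplitCandidate | None:
    """Quinlan's heuristic: among candidates with positive gain whose
    gain reaches the mean gain of all positive-gain candidates, take the
    highest gain ratio (first in declaration order on ties)."""
    pos = [c for c in candidates if c.gain > _EPS]
    if not pos:
        return None
    mean_gain = sum(c.gain for c in pos) / len(pos)
    eligible = [c for c in pos if c.gain >= mean_gain - _EPS]
    best = eligible[0]
    for c in eligible[1:]:
        if c.gain_ratio > best.gain_ratio + _EPS:
            best = c
    return best


@dataclass
class Node:
    n: int
    class_counts: dict[str, int]
    label: str
    depth: int
    attr: str | None = None
    kind: str | None = None
    threshold: float | None = None
    children: dict = field(default_factory=dict)   # branch value -> Node, or "le"/"gt"

    @property
    def is_leaf(self) -> bool:
        return self.attr is None

    def majority_child(self) -> "Node":
        return max(self.children.values(), key=lambda c: c.n)


@dataclass
class DecisionTree:
    root: Node
    categorical: list[str]
    numeric: list[str]
    classes: list[str]

    def predict_row(self, row) -> str:
        node = self.root
        while not node.is_leaf:
            if node.kind == "numeric":
                node = node.children["le"] if float(row[node.attr]) <= node.threshold else node.children["gt"]
            else:
                child = node.children.get(row[node.attr])
                node = child if child is not None else node.majority_child()
        return node.label

    def predict(self, df: pd.DataFrame) -> list[str]:
        missing = [a for a in self.categorical + self.numeric if a not in df.columns]
        if missing:
            raise ValueError(f"feature columns missing from input: {missing}")
        return [self.predict_row(row) for _i, row in df.iterrows()]

    @property
    def depth(self) -> int:
        def d(node: Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(d(c) for c in node.children.values())
        return d(self.root)

    def n_leaves(self) -> int:
        def count(node: Node) -> int:
            if node.is_leaf:
                return 1
            return sum(count(c) for c in node.children.values())
        return count(self.root)

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: Node, prefix: str, header: str) -> None:
            if node.is_leaf:
                lines.append(f"{prefix}{header}-> {node.label} {node.class_counts}")
                return
            if node.kind == "numeric":
                lines.append(f"{prefix}{header}[{node.attr} <= {node.threshold:g}] (n={node.n})")
                walk(node.children["le"], prefix + "  ", "yes: ")
                walk(node.children["gt"], prefix + "  ", "no:  ")
            else:
                lines.append(f"{prefix}{header}[{node.attr}] (n={node.n})")
                for v in sorted(node.children, key=str):
                    walk(node.children[v], prefix + "  ", f"= {v}: ")

        walk(self.root, "", "")
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        lines = ["digraph tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node: Node) -> int:
            nid = counter[0]
            counter[0] += 1
            if node.is_leaf:
                lines.append(f'  n{nid} [label="{node.label}\\nn={node.n}"];')
                return nid
            if node.kind == "numeric":
                lines.append(f'  n{nid} [label="{node.attr} <= {node.threshold:g}\\nn={node.n}"];')
                for tag, key in (("yes", "le"), ("no", "gt")):
                    cid = walk(node.children[key])
                    lines.append(f'  n{nid} -> n{cid} [label="{tag}"];')
            else:
                lines.append(f'  n{nid} [label="{node.attr}\\nn={node.n}"];')
                for v in sorted(node.children, key=str):
                    cid = walk(node.children[v])
                    lines.append(f'  n{nid} -> n{cid} [label="{v}"];')
            return nid

        walk(self.root)
        lines.append("}")
        return "\n".join(lines) + "\n"


def _majority(labels, classes: list[str]) -> tuple[str, dict[str, int]]:
    counts = {c: 0 for c in classes}
    for lb in labels:
        counts[lb] = counts.get(lb, 0) + 1
    label = max(classes, key=lambda c: counts.get(c, 0))   # tie -> earlier class
    return label, {c: n for c, n in counts.items() if n}


def train_c45(
    dataset: pd.DataFrame,
    label_col: str = "label",
    categorical: list[str] | None = None,
    numeric: list[str] | None = None,
    min_leaf: int = 5,
    max_depth: int = 10,
) -> DecisionTree:
    """Grow a C4.5-style tree on ``dataset``.

    Attribute lists default to the package's 15-feature schema when the
    dataset carries those columns, otherwise they are inferred from
    dtypes (object -> categorical).  Single-class data yields a
    single-leaf tree.
    """
    from .features import CATEGORICAL_FEATURES, NUMERIC_FEATURES

    if categorical is None and numeric is None:
        if set(CATEGORICAL_FEATURES + NUMERIC_FEATURES).issubset(dataset.columns):
            categorical = list(CATEGORICAL_FEATURES)
            numeric = list(NUMERIC_FEATURES)
        else:
            feats = [c for c in dataset.columns if c != label_col]
            categorical = [c for c in feats if dataset[c].dtype == object]
            numeric = [c for c in feats if c not in categorical]
    categorical = list(categorical or [])
    numeric = list(numeric or [])
    labels = dataset[label_col].to_numpy(dtype=object)
    classes = sorted(set(labels))   # order-independent tie-breaking

    def grow(df: pd.DataFrame, y: np.ndarray, depth: int) -> Node:
        label, counts = _majority(y, classes)
        node = Node(n=len(y), class_counts=counts, label=label, depth=depth)
        if len(counts) < 2 or depth >= max_depth or len(y) < 2 * min_leaf:
            return node
        cands = candidate_splits(df, y, categorical, numeric, min_leaf=min_leaf)
        chosen = select_split(cands)
        if chosen is None:
            return node
        node.attr = chosen.attr
        node.kind = chosen.kind
        node.threshold = chosen.threshold
        if chosen.kind == "numeric":
            mask = df[chosen.attr].to_numpy(dtype=float) <= chosen.threshold
            node.children["le"] = grow(df[mask], y[mask], depth + 1)
            node.children["gt"] = grow(df[~mask], y[~mask], depth + 1)
        else:
            values = df[chosen.attr].to_numpy(dtype=object)
            for v in pd.unique(values):
                mask = values == v
                node.children[v] = grow(df[mask], y[mask], depth + 1)
        return node

    feat_df = dataset[categorical + numeric].reset_index(drop=True)
    root = grow(feat_df, labels, 0)
    return DecisionTree(root=root, categorical=categorical, numeric=numeric, classes=classes)


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified partition into k folds.

    Within each class the indices are shuffled with ``seed`` and dealt
    round-robin; fold sizes differ by at most one per class.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size n={n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    offset = 0
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            assignment[i] = (pos + offset) % k
        offset += len(idx)
    return [np.flatnonzero(assignment == f) for f in range(k)]


def cross_validate(
    dataset: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    label_col: str = "label",
    **tree_kwargs,
) -> dict:
    """Stratified k-fold cross-validation of the C4.5 classifier.

    Returns fold accuracies, their mean and standard deviation, and the
    majority-class baseline rate of the full dataset.
    """
    labels = dataset[label_col].to_numpy(dtype=object)
    folds = stratified_folds(labels, k, seed)
    accs = []
    for f in range(k):
        test_idx = folds[f]
        train_idx = np.concatenate([folds[g] for g in range(k) if g != f])
        tree = train_c45(dataset.iloc[train_idx], label_col=label_col, **tree_kwargs)
        pred = tree.predict(dataset.iloc[test_idx])
        accs.append(float(np.mean(np.asarray(pred, dtype=object) == labels[test_idx])))
    _vals, counts = np.unique(labels, return_counts=True)
    return {
        "fold_accuracy": accs,
        "mean_accuracy": float(np.mean(accs)),
        "std_accuracy": float(np.std(accs)),
        "majority_baseline": float(counts.max() / counts.sum()),
    }
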