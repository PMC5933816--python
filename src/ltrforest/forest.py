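"""Relational decision trees and random forests over domain-hit features.

Trees are induced top-down: at each node a random sample of ceil(sqrt(T))
of the T enumerated relational tests is scored by information gain, and
the best valid split (both branches at least ``min_leaf`` examples) is
installed. Leaves store raw example counts; a forest averages the leaf
positive frequencies of its trees. No pruning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .errors import ConfigurationError
from .io import DomainHit
from .relational import (
    DomainHierarchy,
    RelationalTest,
    FeatureMatrix,
    enumerate_tests,
    enumeration_config,
    evaluate_test,
)


@dataclass(frozen=True)
class TrainingExample:
    """One labelled single-strand sequence represented by its domain hits."""

    example_id: str
    hits: tuple[DomainHit, ...]
    label: bool  # True = member of the target superfamily


class TreeNode:
    """Internal node (test + two children) or leaf (example counts)."""

    __slots__ = ("test", "yes_child", "no_child", "n_examples", "n_positive")

    def __init__(self, test=None, yes_child=None, no_child=None,
                 n_examples=0, n_positive=0):
        self.test = test
        self.yes_child = yes_child
        self.no_child = no_child
        self.n_examples = n_examples
        self.n_positive = n_positive

    @classmethod
    def leaf(cls, n_examples: int, n_positive: int) -> "TreeNode":
        return cls(n_examples=n_examples, n_positive=n_positive)

    @classmethod
    def internal(cls, test: RelationalTest, yes_child: "TreeNode",
                 no_child: "TreeNode") -> "TreeNode":
        return cls(test=test, yes_child=yes_child, no_child=no_child)

    @property
    def is_leaf(self) -> bool:
        return self.test is None

    @property
    def p_positive(self) -> float:
        return self.n_positive / self.n_examples

    def route(self, candidate, hierarchy: DomainHierarchy) -> "TreeNode":
        node = self
        while not node.is_leaf:
            branch = evaluate_test(candidate, node.test, hierarchy)
            node = node.yes_child if branch else node.no_child
        return node

    def iter_nodes(self):
        yield self
        if not self.is_leaf:
            yield from self.yes_child.iter_nodes()
            yield from self.no_child.iter_nodes()


@dataclass
class RelationalForest:
    """Ensemble of relational trees for one target superfamily."""

    trees: list[TreeNode]
    target: str
    enumeration: dict
    rng_seed: int
    config: RunConfig
    bootstrap_indices: Optional[list[np.ndarray]] = field(default=None, repr=False)

    def predict_proba(self, candidate, hierarchy: DomainHierarchy) -> float:
        return predict_proba(self, candidate, hierarchy)


def assemble_training_set(
    corpus: Sequence[tuple[str, str, Sequence[DomainHit]]],
    target: str,
    seed: int,
) -> list[TrainingExample]:
    """Build a balanced positive/negative set for one target superfamily.

    ``corpus`` rows are (sequence id, superfamily, hits). Sequences without
    hits or with hits on both strands are dropped. Positives are every
    surviving target sequence; negatives are sampled without replacement
    from the other superfamilies to the same size (or all of them when
    fewer are available).
    """
    usable: list[tuple[str, str, tuple[DomainHit, ...]]] = []
    for seq_id, family, hits in corpus:
        hits = tuple(hits)
        if not hits:
            continue
        if len({h.strand for h in hits}) > 1:
            continue
        usable.append((seq_id, family, hits))

    positives = [row for row in usable if row[1] == target]
    others = [row for row in usable if row[1] != target]
    if not positives:
        raise ConfigurationError(f"no usable training sequences for {target!r}")

    rng = np.random.default_rng(seed)
    n_neg = min(len(positives), len(others))
    chosen = sorted(rng.choice(len(others), size=n_neg, replace=False)) if others else []

    examples = [TrainingExample(sid, hits, True) for sid, _f, hits in positives]
    examples.extend(
        TrainingExample(others[i][0], others[i][2], False) for i in chosen
    )
    return examples


def _entropy(n_pos: int, n: int) -> float:
    if n == 0 or n_pos == 0 or n_pos == n:
        return 0.0
    p = n_pos / n
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def _best_split(
    matrix: np.ndarray,
    labels: np.ndarray,
    idx: np.ndarray,
    test_ids: np.ndarray,
    min_leaf: int,
) -> Optional[tuple[int, float]]:
    """Gain-optimal valid test among ``test_ids``; ties -> lowest test id.

    Returns (test id, gain) or None when no sampled test splits validly
    with positive gain.
    """
    sub = matrix[np.ix_(test_ids, idx)]
    y = labels[idx]
    n = idx.size
    n_pos = int(y.sum())
    parent = _entropy(n_pos, n)
    n_yes = sub.sum(axis=1)
    pos_yes = (sub & y).sum(axis=1)
    best: Optional[tuple[int, float]] = None
    for k in range(test_ids.size):
        ny = int(n_yes[k])
        nn = n - ny
        if ny < min_leaf or nn < min_leaf:
            continue
        py = int(pos_yes[k])
        gain = parent - (
            ny / n * _entropy(py, ny) + nn / n * _entropy(n_pos - py, nn)
        )
        if gain <= 1e-12:
            continue
        tid = int(test_ids[k])
        if best is None or gain > best[1] + 1e-12 or (
            abs(gain - best[1]) <= 1e-12 and tid < best[0]
        ):
            best = (tid, gain)
    return best


def _grow(
    matrix: np.ndarray,
    labels: np.ndarray,
    idx: np.ndarray,
    tests: Sequence[RelationalTest],
    cfg: RunConfig,
    rng: np.random.Generator,
    sample_size: int,
) -> TreeNode:
    n = idx.size
    n_pos = int(labels[idx].sum())
    if n_pos in (0, n) or n < 2 * cfg.min_leaf:
        return TreeNode.leaf(n, n_pos)
    if cfg.feature_sampling and sample_size < len(tests):
        test_ids = np.sort(rng.choice(len(tests), size=sample_size, replace=False))
    else:
        test_ids = np.arange(len(tests))
    best = _best_split(matrix, labels, idx, test_ids, cfg.min_leaf)
    if best is None:
        return TreeNode.leaf(n, n_pos)
    tid, _gain = best
    mask = matrix[tid, idx]
    yes = _grow(matrix, labels, idx[mask], tests, cfg, rng, sample_size)
    no = _grow(matrix, labels, idx[~mask], tests, cfg, rng, sample_size)
    return TreeNode.internal(tests[tid], yes, no)


def induce_tree(
    examples: Sequence[TrainingExample],
    cfg: RunConfig,
    hierarchy: DomainHierarchy,
    rng: np.random.Generator,
    tests: Optional[Sequence[RelationalTest]] = None,
    matrix: Optional[np.ndarray] = None,
) -> TreeNode:
    """Induce one relational decision tree (no pruning).

    ``tests``/``matrix`` may be precomputed and shared across the trees of
    a forest; otherwise they are built here.
    """
    if not examples:
        raise ConfigurationError("cannot induce a tree from zero examples")
    if tests is None:
        tests = enumerate_tests(hierarchy, cfg)
    if matrix is None:
        matrix = FeatureMatrix(hierarchy, cfg, examples).matrix(tests)
    labels = np.array([ex.label for ex in examples], dtype=bool)
    sample_size = math.ceil(math.sqrt(len(tests)))
    return _grow(matrix, labels, np.arange(len(examples)), tests, cfg, rng, sample_size)


def induce_forest(
    examples: Sequence[TrainingExample],
    cfg: RunConfig,
    hierarchy: DomainHierarchy,
    seed: int,
    target: str = "positive",
) -> RelationalForest:
    """Train ``cfg.n_trees`` trees on bootstrap resamples of ``examples``."""
    if not examples:
        raise ConfigurationError("cannot induce a forest from zero examples")
    tests = enumerate_tests(hierarchy, cfg)
    matrix = FeatureMatrix(hierarchy, cfg, examples).matrix(tests)
    labels = np.array([ex.label for ex in examples], dtype=bool)
    rng = np.random.default_rng(seed)
    n = len(examples)
    sample_size = math.ceil(math.sqrt(len(tests)))
    trees: list[TreeNode] = []
    boots: list[np.ndarray] = []
    for _ in range(cfg.n_trees):
        idx = rng.integers(0, n, size=n) if cfg.bootstrap else np.arange(n)
        boots.append(idx)
        trees.append(_grow(matrix, labels, idx, tests, cfg, rng, sample_size))
    return RelationalForest(
        trees=trees,
        target=target,
        enumeration=enumeration_config(cfg),
        rng_seed=seed,
        config=cfg,
        bootstrap_indices=boots,
    )


def predict_proba(forest: RelationalForest, candidate,
                  hierarchy: DomainHierarchy) -> float:
    """Mean leaf positive-frequency over the forest's trees."""
    total = 0.0
    for tree in forest.trees:
        total += tree.route(candidate, hierarchy).p_positive
    return total / len(forest.trees)


def oob_predictions(
    forest: RelationalForest,
    examples: Sequence[TrainingExample],
    hierarchy: DomainHierarchy,
) -> np.ndarray:
    """Out-of-bag probability per example (NaN where never out of bag)."""
    if forest.bootstrap_indices is None:
        raise ConfigurationError("forest was not trained in-session with bootstrap")
    n = len(examples)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for tree, idx in zip(forest.trees, forest.bootstrap_indices):
        in_bag = np.zeros(n, dtype=bool)
        in_bag[idx] = True
        for i in np.nonzero(~in_bag)[0]:
            sums[i] += tree.route(examples[i], hierarchy).p_positive
            counts[i] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def node_test_usage(forest: RelationalForest) -> dict[str, float]:
    """Fraction of internal nodes per test family (sums to 1 when non-empty)."""
    counts = {"OCCURS": 0, "OCCURS_LEN": 0, "BEFORE": 0, "COUNT": 0}
    total = 0
    for tree in forest.trees:
        for node in tree.iter_nodes():
            if not node.is_leaf:
                counts[node.test.variant] += 1
                total += 1
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}
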