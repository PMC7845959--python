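"""Information-theoretic feature selection: SU, FCBF, CFS and Scatter Search.

Symmetrical Uncertainty SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)) (entropies in
bits) measures non-linear dependency between discrete variables on [0, 1].
FCBF ranks features by SU with the class and removes a feature when an
already-kept feature dominates it (SU between the two features at least as
large as the feature's SU with the class).  Scatter Search explores feature
subsets guided by the CFS merit

    merit(S) = k r_cf / sqrt(k + k (k - 1) r_ff)

with k = |S|, r_cf the mean feature-class SU and r_ff the mean pairwise SU
inside S, maintaining a reference set of high-quality and diverse solutions
that are pairwise combined and refined by greedy local search.

Continuous features are discretized for SU with supervised MDL (recursive
entropy-based binary splitting with the MDL stopping rule), falling back to
equal-frequency binning when no cut is accepted; bin edges are fitted on
training folds only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "entropy_bits",
    "symmetrical_uncertainty",
    "mdl_cut_points",
    "DiscretizedMatrix",
    "discretize_matrix",
    "SUCache",
    "fcbf",
    "cfs_merit",
    "SSParams",
    "scatter_search",
    "selection_stability",
    "SelectionResult",
    "run_selection_cv",
]


# ---------------------------------------------------------------------------
# Entropy and symmetrical uncertainty
# ---------------------------------------------------------------------------

def entropy_bits(x: np.ndarray) -> float:
    """Shannon entropy in bits of a discrete vector."""
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x: Sequence[int], y: Sequence[int]) -> float:
    """SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)); 0 when both are constant."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    hx = entropy_bits(x)
    hy = entropy_bits(y)
    if hx + hy == 0.0:
        return 0.0
    # joint entropy via pairing
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = xi.astype(np.int64) * (yi.max() + 1) + yi
    hxy = entropy_bits(joint)
    mi = hx + hy - hxy
    su = 2.0 * mi / (hx + hy)
    return float(min(1.0, max(0.0, su)))


# ---------------------------------------------------------------------------
# Supervised MDL discretization (entropy-based recursive binary splitting)
# ---------------------------------------------------------------------------

def _class_entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def mdl_cut_points(x: np.ndarray, y: np.ndarray) -> List[float]:
    """Accepted cut points of the recursive MDL partitioning of ``x``.

    Candidate cuts are midpoints between adjacent distinct values whose
    class distributions differ; a cut is accepted when its information gain
    exceeds the MDL penalty (log2(n-1) + log2(3^c - 2) - c H(S) + c1 H(S1)
    + c2 H(S2)) / n.
    """
    order = np.argsort(x, kind="stable")
    xs = np.asarray(x)[order]
    ys = np.asarray(y)[order]
    classes = np.unique(ys)
    y_codes = np.searchsorted(classes, ys)
    n_classes = len(classes)
    cuts: List[float] = []

    def counts_in(lo: int, hi: int) -> np.ndarray:
        return np.bincount(y_codes[lo:hi], minlength=n_classes)

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 4:
            return
        total_counts = counts_in(lo, hi)
        h_s = _class_entropy(total_counts)
        if h_s == 0.0:
            return
        # prefix class counts for O(1) split evaluation
        prefix = np.zeros((n + 1, n_classes), dtype=np.int64)
        for i in range(n):
            prefix[i + 1] = prefix[i]
            prefix[i + 1, y_codes[lo + i]] += 1
        best_gain = -1.0
        best_i = None
        for i in range(1, n):
            if xs[lo + i] == xs[lo + i - 1]:
                continue
            left = prefix[i]
            right = total_counts - left
            h_l = _class_entropy(left)
            h_r = _class_entropy(right)
            gain = h_s - (i / n) * h_l - ((n - i) / n) * h_r
            if gain > best_gain:
                best_gain = gain
                best_i = i
        if best_i is None:
            return
        left = prefix[best_i]
        right = total_counts - left
        c = int((total_counts > 0).sum())
        c1 = int((left > 0).sum())
        c2 = int((right > 0).sum())
        h_l = _class_entropy(left)
        h_r = _class_entropy(right)
        delta = math.log2(3**c - 2) - (c * h_s - c1 * h_l - c2 * h_r)
        threshold = (math.log2(n - 1) + delta) / n
        if best_gain <= threshold:
            return
        cut = 0.5 * (xs[lo + best_i - 1] + xs[lo + best_i])
        cuts.append(float(cut))
        recurse(lo, lo + best_i)
        recurse(lo + best_i, hi)

    recurse(0, len(xs))
    return sorted(cuts)


def _equal_frequency_edges(x: np.ndarray, n_bins: int) -> List[float]:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return sorted(set(float(q) for q in qs))


@dataclass
class DiscretizedMatrix:
    """Integer bin codes per feature with the fitted bin edges.

    Edges are fitted on training data (:func:`discretize_matrix`) and can be
    re-applied to held-out rows with :meth:`transform`.
    """

    values: np.ndarray
    feature_names: List[str]
    bin_edges: List[List[float]]
    scheme: str = "mdl_supervised"

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape, dtype=np.int64)
        for j, edges in enumerate(self.bin_edges):
            out[:, j] = np.searchsorted(edges, X[:, j], side="right")
        return out


def discretize_matrix(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    fallback_bins: int = 10,
) -> DiscretizedMatrix:
    """Supervised MDL discretization per feature (equal-frequency fallback).

    A feature with no accepted MDL cut gets ``fallback_bins`` equal-frequency
    bins, so uninformative features keep non-trivial entropy instead of
    degenerating to a constant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{i}" for i in range(X.shape[1])]
    )
    edges_per_feature: List[List[float]] = []
    for j in range(X.shape[1]):
        edges = mdl_cut_points(X[:, j], y)
        if not edges:
            edges = _equal_frequency_edges(X[:, j], fallback_bins)
        edges_per_feature.append(edges)
    dm = DiscretizedMatrix(
        values=np.empty((0, X.shape[1]), dtype=np.int64),
        feature_names=names,
        bin_edges=edges_per_feature,
    )
    dm.values = dm.transform(X)
    return dm


# ---------------------------------------------------------------------------
# SU cache, FCBF and CFS merit
# ---------------------------------------------------------------------------

class SUCache:
    """Lazy cache of feature-class and pairwise feature-feature SU values."""

    def __init__(self, codes: np.ndarray, labels: np.ndarray):
        self.codes = np.asarray(codes)
        self.labels = np.asarray(labels)
        self.n_features = self.codes.shape[1]
        self.su_class = np.array(
            [
                symmetrical_uncertainty(self.codes[:, j], self.labels)
                for j in range(self.n_features)
            ]
        )
        self._pairwise: Dict[Tuple[int, int], float] = {}

    def su_pair(self, i: int, j: int) -> float:
        if i == j:
            return 1.0 if entropy_bits(self.codes[:, i]) > 0 else 0.0
        key = (min(i, j), max(i, j))
        if key not in self._pairwise:
            self._pairwise[key] = symmetrical_uncertainty(
                self.codes[:, key[0]], self.codes[:, key[1]]
            )
        return self._pairwise[key]


def fcbf(
    matrix: DiscretizedMatrix, labels: np.ndarray, delta: float = 0.0
) -> List[str]:
    """Fast Correlation-Based Filter.

    Phase 1 ranks features by SU with the class, keeping those with
    SU > delta (default delta = 0).  Phase 2 walks the ranking and removes a
    feature f when an already-kept feature f' satisfies
    SU(f', f) >= SU(f, class).  Ties in SU rank are broken by column index.
    """
    codes = matrix.values
    if codes.size == 0:
        raise ValueError("empty matrix")
    cache = SUCache(codes, labels)
    relevant = [j for j in range(cache.n_features) if cache.su_class[j] > delta]
    relevant.sort(key=lambda j: (-cache.su_class[j], j))
    kept: List[int] = []
    for j in relevant:
        dominated = any(
            cache.su_pair(i, j) >= cache.su_class[j] for i in kept
        )
        if not dominated:
            kept.append(j)
    return [matrix.feature_names[j] for j in kept]


def cfs_merit(
    subset: Sequence[int],
    su_class: np.ndarray,
    su_pair,
) -> float:
    """CFS merit of a feature subset (indices into the SU structures).

    ``su_pair`` is either a callable (i, j) -> SU or a dense matrix.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("empty subset")
    k = len(subset)
    r_cf = float(np.mean([su_class[i] for i in subset]))
    if k == 1:
        return r_cf
    pair = su_pair if callable(su_pair) else (lambda i, j: su_pair[i, j])
    total = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            total += pair(subset[a], subset[b])
    r_ff = total / (k * (k - 1) / 2)
    denom = math.sqrt(k + k * (k - 1) * r_ff)
    return k * r_cf / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# Scatter Search
# ---------------------------------------------------------------------------

@dataclass
class SSParams:
    """Scatter-Search hyperparameters.

    RefSet holds ``b1`` high-merit and ``b2`` diverse solutions
    (b = b1 + b2); the population must be at least b.
    """

    pop_size: int = 100
    b1: int = 5
    b2: int = 5
    max_iterations: int = 20
    seed: int = 7

    def __post_init__(self) -> None:
        if self.pop_size < self.b1 + self.b2:
            raise ValueError("pop_size must be >= b1 + b2")
        if self.b1 < 1 or self.b2 < 0:
            raise ValueError("invalid RefSet sizes")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _local_search(
    subset: FrozenSet[int], cache: SUCache, merit_fn
) -> Tuple[FrozenSet[int], float]:
    """Best-improvement greedy add/remove to a CFS local optimum."""
    current = set(subset) or {int(np.argmax(cache.su_class))}
    current_merit = merit_fn(frozenset(current))
    n = cache.n_features
    improved = True
    while improved:
        improved = False
        best_move = None
        best_merit = current_merit
        for j in range(n):
            if j in current:
                if len(current) > 1:
                    cand = frozenset(current - {j})
                    m = merit_fn(cand)
                    if m > best_merit + 1e-12:
                        best_merit = m
                        best_move = cand
            else:
                cand = frozenset(current | {j})
                m = merit_fn(cand)
                if m > best_merit + 1e-12:
                    best_merit = m
                    best_move = cand
        if best_move is not None:
            current = set(best_move)
            current_merit = best_merit
            improved = True
    return frozenset(current), current_merit


def _hamming(a: FrozenSet[int], b: FrozenSet[int]) -> int:
    return len(a.symmetric_difference(b))


def scatter_search(
    matrix: DiscretizedMatrix,
    labels: np.ndarray,
    params: Optional[SSParams] = None,
) -> List[str]:
    """Scatter Search over feature subsets with CFS merit.

    Pipeline: a seeded diverse initial population (all singletons plus
    random subsets of uniform random size) -> RefSet of b1 best-merit plus
    b2 max-min-Hamming diverse solutions -> every RefSet pair combined
    (intersection kept; each symmetric-difference member added with
    probability 1/2) -> greedy add/remove local search to a CFS local
    optimum -> static RefSet update; stops when the RefSet is unchanged or
    after ``max_iterations``.  Returns the best subset found, preferring
    smaller subsets and lexicographic order on exact merit ties.
    """
    params = params or SSParams()
    codes = matrix.values
    n = codes.shape[1]
    if n < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(params.seed)
    cache = SUCache(codes, labels)
    merit_cache: Dict[FrozenSet[int], float] = {}

    def merit_fn(subset: FrozenSet[int]) -> float:
        if subset not in merit_cache:
            merit_cache[subset] = cfs_merit(
                sorted(subset), cache.su_class, cache.su_pair
            )
        return merit_cache[subset]

    def solution_key(s: FrozenSet[int]):
        # higher merit first; then smaller, then lexicographic for determinism
        return (-merit_fn(s), len(s), tuple(sorted(s)))

    population = {frozenset({j}) for j in range(n)}
    # at most 2^n - 1 non-empty subsets exist; cap the population target
    target = params.pop_size if n > 20 else min(params.pop_size, 2**n - 1)
    while len(population) < target:
        size = int(rng.integers(1, n + 1))
        members = rng.choice(n, size=size, replace=False)
        population.add(frozenset(int(m) for m in members))

    def build_refset(pool: List[FrozenSet[int]]) -> List[FrozenSet[int]]:
        pool = sorted(set(pool), key=solution_key)
        refset = pool[: params.b1]
        remaining = pool[params.b1 :]
        for _ in range(params.b2):
            if not remaining:
                break
            # max-min Hamming distance to the current RefSet
            best = max(
                remaining,
                key=lambda s: (min(_hamming(s, r) for r in refset), solution_key(s)),
            )
            refset.append(best)
            remaining.remove(best)
        return refset

    # improve the initial RefSet members to seed quality
    refset = [
        _local_search(s, cache, merit_fn)[0] for s in build_refset(list(population))
    ]
    refset = build_refset(refset + list(population))
    best = min(refset, key=solution_key)

    for _ in range(params.max_iterations):
        children: List[FrozenSet[int]] = []
        for a_i in range(len(refset)):
            for b_i in range(a_i + 1, len(refset)):
                a, b = refset[a_i], refset[b_i]
                child = set(a & b)
                for f in sorted(a.symmetric_difference(b)):
                    if rng.random() < 0.5:
                        child.add(f)
                if not child:
                    child.add(int(rng.integers(n)))
                improved, _ = _local_search(frozenset(child), cache, merit_fn)
                children.append(improved)
        new_refset = build_refset(refset + children)
        candidate_best = min(new_refset, key=solution_key)
        if solution_key(candidate_best) < solution_key(best):
            best = candidate_best
        if set(new_refset) == set(refset):
            break
        refset = new_refset
    return [matrix.feature_names[j] for j in sorted(best)]


# ---------------------------------------------------------------------------
# Stability and cross-validated selection
# ---------------------------------------------------------------------------

def selection_stability(runs: Sequence[Sequence[str]]) -> float:
    """Mean pairwise Jaccard similarity of selected subsets across runs.

    1 iff all runs select identical subsets; a pair involving an empty
    subset contributes 0.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    sets = [frozenset(r) for r in runs]
    total = 0.0
    n_pairs = 0
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            n_pairs += 1
            union = sets[i] | sets[j]
            if not union:
                continue  # empty vs empty counts 0
            total += len(sets[i] & sets[j]) / len(union)
    return total / n_pairs


@dataclass
class SelectionResult:
    """Per-run selected subsets with relevance and stability summaries."""

    runs: List[List[str]]
    su_class: Dict[str, float]
    stability: float
    n_features_mean: float
    method: str

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "runs": [list(r) for r in self.runs],
            "su_class": {k: float(v) for k, v in self.su_class.items()},
            "stability": float(self.stability),
            "n_features_mean": float(self.n_features_mean),
        }


def run_selection_cv(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    method: str = "ss",
    folds: int = 5,
    seed: int = 7,
    delta: float = 0.0,
    ss_params: Optional[SSParams] = None,
) -> SelectionResult:
    """Run a selector on the training side of each stratified CV fold.

    Discretization is fitted on each training fold only.  Returns the
    per-fold subsets, the full-data SU relevances, the stability score and
    the mean subset size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    runs: List[List[str]] = []
    for fold_i, (train_idx, _) in enumerate(skf.split(X, y)):
        dm = discretize_matrix(X[train_idx], y[train_idx], feature_names)
        if method == "fcbf":
            selected = fcbf(dm, y[train_idx], delta=delta)
        elif method == "ss":
            params = ss_params or SSParams(seed=seed)
            selected = scatter_search(dm, y[train_idx], params)
        else:
            raise ValueError(f"unknown selection method {method!r}")
        runs.append(selected)
    dm_full = discretize_matrix(X, y, feature_names)
    cache = SUCache(dm_full.values, y)
    su_class = {
        name: float(su) for name, su in zip(feature_names, cache.su_class)
    }
    return SelectionResult(
        runs=runs,
        su_class=su_class,
        stability=selection_stability(runs),
        n_features_mean=float(np.mean([len(r) for r in runs])),
        method=method,
    )
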