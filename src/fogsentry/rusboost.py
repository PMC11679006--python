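"""Random-undersampling boosting (RUSBoost) with shallow decision trees.

The classifier is a binary AdaBoost-style ensemble in which each boosting
round trains its weak learner on a class-rebalanced random undersample of
the weighted training set: all minority-class examples plus a weighted
draw (without replacement) of majority-class examples to reach the
configured class ratio.  This is the two-class simplification of RUSBoost
(Seiffert et al.), where the pseudo-loss reduces to the weighted 0-1 error.

Weak learners are axis-aligned binary decision trees grown best-first by
weighted Gini impurity reduction, capped at ``max_splits`` internal splits
(5 by default, i.e. at most 6 leaves).  All tie-breaks are deterministic
(lowest feature index, then lowest threshold, then oldest leaf), training
rows are canonically sorted before fitting, and every round draws from a
substream derived from the root seed and a round counter — identical data,
parameters and seed give bit-identical ensembles.

Boosting round, in full:

1. undersample the majority class to ``sampling_ratio`` times the minority
   count, selection probabilities proportional to current example weights;
2. fit a tree on the round sample (weighted by the current weights);
3. compute the weighted error ``eps`` of that tree on the FULL training set;
4. ``alpha = learn_rate * ln((1 - eps)/eps)``; multiply the weights of
   correctly classified examples by ``exp(-alpha)`` and renormalize.

Rounds with ``eps = 0`` keep the learner with a capped ``alpha``; rounds
with ``eps >= 0.5`` discard the learner and resample (after repeated
failures boosting stops early, so an ensemble may hold fewer than
``n_learners`` trees).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["WeakTree", "Ensemble", "fit_tree", "fit_rusboost", "predict_score", "predict_class"]

_EPS_CAP = 1e-10
_MAX_RESAMPLE_ATTEMPTS = 10


@dataclass
class WeakTree:
    """Axis-aligned binary tree stored as flat node arrays.

    ``feature[i] >= 0`` marks an internal node splitting on
    ``x[feature[i]] <= threshold[i]`` (left = true); ``feature[i] == -1``
    marks a leaf whose ``posterior[i]`` is the weighted target-class
    fraction of its training samples.
    """

    feature: np.ndarray      # int, -1 for leaves
    threshold: np.ndarray    # float, NaN for leaves
    left: np.ndarray         # int child index, -1 for leaves
    right: np.ndarray
    posterior: np.ndarray    # float in [0, 1]

    @property
    def n_splits(self) -> int:
        return int(np.sum(self.feature >= 0))

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        node_of = np.zeros(len(X), dtype=int)
        # at most max_splits levels of routing; loop until all rows at leaves
        active = np.arange(len(X))
        while len(active):
            nodes = node_of[active]
            feats = self.feature[nodes]
            at_leaf = feats < 0
            leaf_rows = active[at_leaf]
            out[leaf_rows] = self.posterior[nodes[at_leaf]]
            rows = active[~at_leaf]
            if len(rows) == 0:
                break
            nd = node_of[rows]
            go_left = X[rows, self.feature[nd]] <= self.threshold[nd]
            node_of[rows] = np.where(go_left, self.left[nd], self.right[nd])
            active = rows
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean vote: target iff leaf posterior > 0.5."""
        return self.predict_posterior(X) > 0.5

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": [None if np.isnan(t) else t for t in self.threshold],
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "posterior": self.posterior.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeakTree":
        return cls(
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(
                [np.nan if t is None else t for t in d["threshold"]], dtype=float
            ),
            left=np.asarray(d["left"], dtype=int),
            right=np.asarray(d["right"], dtype=int),
            posterior=np.asarray(d["posterior"], dtype=float),
        )


def _gini_contrib(w1: float, w0: float) -> float:
    """Weighted Gini impurity contribution W * (1 - p1^2 - p0^2)."""
    w = w1 + w0
    if w <= 0:
        return 0.0
    return w * (1.0 - (w1 / w) ** 2 - (w0 / w) ** 2)


def _best_split(X: np.ndarray, y: np.ndarray, w: np.ndarray, rows: np.ndarray):
    """Best (gain, feature, threshold) over all axis-aligned splits of rows.

    Evaluated with cumulative weighted class sums over each feature's sort
    order; ties resolve to the lowest feature index then lowest threshold.
    """
    w1_tot = float(w[rows][y[rows]].sum())
    w0_tot = float(w[rows][~y[rows]].sum())
    parent = _gini_contrib(w1_tot, w0_tot)
    if parent <= 1e-15:
        return (-np.inf, -1, np.nan)  # pure leaf: nothing to gain
    best = (-np.inf, -1, np.nan)
    for f in range(X.shape[1]):
        xv = X[rows, f]
        order = np.argsort(xv, kind="stable")
        xs = xv[order]
        ys = y[rows][order]
        ws = w[rows][order]
        cw1 = np.cumsum(np.where(ys, ws, 0.0))
        cw0 = np.cumsum(np.where(ys, 0.0, ws))
        # candidate cut after position i where value changes
        distinct = xs[1:] != xs[:-1]
        if not distinct.any():
            continue
        idx = np.nonzero(distinct)[0]
        l1, l0 = cw1[idx], cw0[idx]
        r1, r0 = w1_tot - l1, w0_tot - l0
        wl = l1 + l0
        wr = r1 + r0
        with np.errstate(invalid="ignore", divide="ignore"):
            child = np.where(wl > 0, wl - (l1**2 + l0**2) / np.maximum(wl, _EPS_CAP), 0.0)
            child += np.where(wr > 0, wr - (r1**2 + r0**2) / np.maximum(wr, _EPS_CAP), 0.0)
        gains = parent - child
        k = int(np.argmax(gains))
        gain = float(gains[k])
        if gain > best[0] + 1e-12:
            thr = 0.5 * (xs[idx[k]] + xs[idx[k] + 1])
            best = (gain, f, float(thr))
    return best


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray | None = None,
    max_splits: int = 5,
) -> WeakTree:
    """Grow a tree best-first by weighted Gini reduction, <= max_splits splits.

    Single-class (or unsplittable) input yields a single leaf.  Growth is
    fully deterministic; among leaves whose best splits tie in gain the
    oldest leaf splits first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if len(X) == 0:
        raise ValueError("fit_tree: empty input")
    w = (
        np.full(len(X), 1.0 / len(X))
        if sample_weights is None
        else np.asarray(sample_weights, dtype=float) / np.sum(sample_weights)
    )

    feature = [-1]
    threshold = [np.nan]
    left = [-1]
    right = [-1]
    posterior = [_posterior(y, w, np.arange(len(X)))]
    leaf_rows = {0: np.arange(len(X))}
    leaf_best: dict[int, tuple] = {0: _best_split(X, y, w, leaf_rows[0])}

    splits = 0
    while splits < max_splits:
        # impure leaves may split even at zero gain (XOR-like data needs the
        # first, gainless cut); oldest leaf wins gain ties
        cand = [(nid, *leaf_best[nid]) for nid in sorted(leaf_rows) if leaf_best[nid][1] >= 0]
        cand = [c for c in cand if c[1] >= -1e-12]
        if not cand:
            break
        best = max(cand, key=lambda c: (c[1], -c[0]))
        nid, _, f, thr = best
        rows = leaf_rows.pop(nid)
        del leaf_best[nid]
        go_left = X[rows, f] <= thr
        lid, rid = len(feature), len(feature) + 1
        for rows_child in (rows[go_left], rows[~go_left]):
            feature.append(-1)
            threshold.append(np.nan)
            left.append(-1)
            right.append(-1)
            posterior.append(_posterior(y, w, rows_child))
        feature[nid] = f
        threshold[nid] = thr
        left[nid] = lid
        right[nid] = rid
        leaf_rows[lid] = rows[go_left]
        leaf_rows[rid] = rows[~go_left]
        leaf_best[lid] = _best_split(X, y, w, rows[go_left])
        leaf_best[rid] = _best_split(X, y, w, rows[~go_left])
        splits += 1

    return WeakTree(
        feature=np.asarray(feature, dtype=int),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=int),
        right=np.asarray(right, dtype=int),
        posterior=np.asarray(posterior, dtype=float),
    )


def _posterior(y: np.ndarray, w: np.ndarray, rows: np.ndarray) -> float:
    wt = w[rows].sum()
    if wt <= 0:
        return 0.5
    return float(w[rows][y[rows]].sum() / wt)


@dataclass
class Ensemble:
    """Fitted RUSBoost ensemble: weighted trees plus fitting metadata."""

    trees: list[WeakTree]
    alphas: np.ndarray
    params: dict
    seed: int
    feature_names: list[str] = field(default_factory=list)
    round_class_counts: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trees)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "fogsentry-rusboost-1",
            "params": self.params,
            "seed": self.seed,
            "feature_names": self.feature_names,
            "alphas": self.alphas.tolist(),
            "trees": [t.to_dict() for t in self.trees],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Ensemble":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            trees=[WeakTree.from_dict(t) for t in doc["trees"]],
            alphas=np.asarray(doc["alphas"], dtype=float),
            params=doc["params"],
            seed=doc["seed"],
            feature_names=doc.get("feature_names", []),
        )


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lexicographic row order over (features, label): permutation-invariant."""
    keys = [y.astype(int)] + [X[:, f] for f in range(X.shape[1] - 1, -1, -1)]
    return np.lexsort(keys)


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Indices of k items drawn without replacement, P(i) proportional to w_i.

    Exponential-race formulation of the Efraimidis–Spirakis scheme: draw
    Exp(1)/w_i keys and keep the k smallest.
    """
    w = np.asarray(weights, dtype=float)
    keys = rng.exponential(size=len(w)) / np.maximum(w, 1e-300)
    return np.argsort(keys, kind="stable")[:k]


def fit_rusboost(
    X: np.ndarray,
    y: np.ndarray,
    n_learners: int = 100,
    max_splits: int = 5,
    sampling_ratio: float = 1.0,
    learn_rate: float = 0.1,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> Ensemble:
    """Fit the boosted ensemble; see the module docstring for the round logic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("fit_rusboost: both classes must be present")

    order = _canonical_order(X, y)
    X = X[order]
    y = y[order]
    n = len(X)
    w = np.full(n, 1.0 / n)

    minority_is_target = y.sum() <= (~y).sum()
    min_rows = np.nonzero(y == minority_is_target)[0]
    maj_rows = np.nonzero(y != minority_is_target)[0]

    trees: list[WeakTree] = []
    alphas: list[float] = []
    round_counts: list[tuple[int, int]] = []

    for r in range(n_learners):
        kept = False
        for attempt in range(_MAX_RESAMPLE_ATTEMPTS):
            rng = np.random.default_rng([seed & 0x7FFFFFFF, r, attempt])
            k = min(len(maj_rows), int(round(sampling_ratio * len(min_rows))))
            take = maj_rows[_weighted_sample_without_replacement(rng, w[maj_rows], k)]
            rows = np.sort(np.concatenate([min_rows, take]))
            tree = fit_tree(X[rows], y[rows], w[rows], max_splits=max_splits)
            pred = tree.predict(X)
            eps = float(w[pred != y].sum())
            if eps >= 0.5:
                continue  # discard learner, resample
            eps_eff = max(eps, _EPS_CAP)  # eps = 0 keeps the learner, capped alpha
            alpha = learn_rate * np.log((1.0 - eps_eff) / eps_eff)
            w = np.where(pred == y, w * np.exp(-alpha), w)
            w /= w.sum()
            trees.append(tree)
            alphas.append(alpha)
            n_min_round = int((y[rows] == minority_is_target).sum())
            n_maj_round = len(rows) - n_min_round
            round_counts.append(
                (n_min_round, n_maj_round) if minority_is_target else (n_maj_round, n_min_round)
            )
            kept = True
            break
        if not kept:
            break  # early stop: no learner beats chance under current weights

    return Ensemble(
        trees=trees,
        alphas=np.asarray(alphas, dtype=float),
        params={
            "n_learners": n_learners,
            "max_splits": max_splits,
            "sampling_ratio": sampling_ratio,
            "learn_rate": learn_rate,
        },
        seed=seed,
        feature_names=list(feature_names or []),
        round_class_counts=round_counts,
    )


def predict_score(ens: Ensemble, X: np.ndarray) -> np.ndarray:
    """Weighted fraction of target votes, in [0, 1] per row."""
    if not ens.trees:
        raise ValueError("predict_score: unfitted ensemble")
    X = np.asarray(X, dtype=float)
    votes = np.zeros(len(X))
    for tree, alpha in zip(ens.trees, ens.alphas):
        votes += alpha * tree.predict(X)
    total = ens.alphas.sum()
    if total <= 0:
        return np.full(len(X), 0.5)
    return votes / total


def predict_class(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Target iff score strictly exceeds the threshold."""
    return np.asarray(scores) > threshold
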