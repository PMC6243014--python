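"""Tree-structured discrete Bayesian network over binarized peak presence.

Each sample's top 30% most abundant peaks are turned into a binary
presence mask; a Chow-Liu tree (maximum-weight spanning tree over pairwise
mutual information) is learned over the ~1600 binary peak variables plus
one categorical identity variable, and class posteriors follow from the
tree factorization p(x_1..x_m, y) = p(y) prod_i p(x_i | pa[x_i]).

The identity variable is the root of the directed tree, so the posterior
for each class state is a single product over the tree's conditionals.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from herbprint.featurize import FeatureVector

CLASS_NODE = -1  # sentinel for the identity variable in parent arrays


def binarize_top_fraction(v: np.ndarray | FeatureVector, fraction: float = 0.3) -> np.ndarray:
    """Binary mask keeping the ``ceil(fraction * n)`` largest of the n
    strictly positive entries; zeros are absences, never "low peaks".

    Ties at the cutoff are broken in favor of the lower feature index, so
    the mask is deterministic.  An all-zero input yields an all-zero mask
    with a warning.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    values = v.values if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-d feature vector")
    mask = np.zeros(values.shape, dtype=np.int8)
    pos = np.flatnonzero(values > 0)
    if pos.size == 0:
        warnings.warn("all-zero vector: binary mask is empty")
        return mask
    k = math.ceil(fraction * pos.size)
    # sort by (-value, index): stable among ties, lower index first
    order = pos[np.lexsort((pos, -values[pos]))]
    mask[order[:k]] = 1
    return mask


def _binary_pair_mi(B: np.ndarray, alpha: float) -> np.ndarray:
    """MI (nats) between every pair of binary columns, plug-in with
    a pseudocount of `alpha` on each joint cell."""
    n, m = B.shape
    Bf = B.astype(float)
    s = Bf.sum(axis=0)
    n11 = Bf.T @ Bf
    n10 = s[:, None] - n11
    n01 = s[None, :] - n11
    n00 = n - n11 - n10 - n01
    total = n + 4.0 * alpha
    mi = np.zeros((m, m))
    # accumulate sum p log(p / (p_i p_j)) over the 4 joint cells
    for cnt, a, b in ((n11, 1, 1), (n10, 1, 0), (n01, 0, 1), (n00, 0, 0)):
        p = (cnt + alpha) / total
        pa = ((s if a else n - s)[:, None] + 2.0 * alpha) / total
        pb = ((s if b else n - s)[None, :] + 2.0 * alpha) / total
        with np.errstate(divide="ignore", invalid="ignore"):
            term = p * (np.log(p) - np.log(pa) - np.log(pb))
        mi += np.where(p > 0, term, 0.0)
    np.fill_diagonal(mi, 0.0)
    return np.maximum(mi, 0.0)


def _class_feature_mi(B: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """MI (nats) between the categorical class and each binary column."""
    n, m = B.shape
    classes = np.unique(y)
    K = classes.size
    Y = (y[:, None] == classes[None, :]).astype(float)  # n x K one-hot
    c1 = Y.T @ B.astype(float)                          # K x m
    nk = Y.sum(axis=0)                                  # K
    c0 = nk[:, None] - c1
    total = n + 2.0 * K * alpha
    s = B.astype(float).sum(axis=0)
    mi = np.zeros(m)
    for cnt, marg in ((c1, s), (c0, n - s)):
        p = (cnt + alpha) / total
        pk = (nk[:, None] + 2.0 * alpha) / total
        px = (marg[None, :] + K * alpha) / total
        with np.errstate(divide="ignore", invalid="ignore"):
            term = p * (np.log(p) - np.log(pk) - np.log(px))
        mi += np.where(p > 0, term, 0.0).sum(axis=0)
    return np.maximum(mi, 0.0)


def pairwise_mutual_information(
    B: np.ndarray, y: np.ndarray | None = None, alpha: float = 1.0
) -> np.ndarray:
    """Symmetric plug-in mutual-information matrix in nats.

    Rows/columns 0..m-1 are the binary peak variables; if `y` is given an
    extra final row/column holds MI between each variable and the class.
    Smoothed joint frequencies use pseudocount `alpha` per cell; with
    ``alpha=0`` degenerate 0/0 cells contribute 0.
    """
    B = np.asarray(B)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ValueError("need a 2-d binary matrix with at least 2 rows")
    m = B.shape[1]
    ff = _binary_pair_mi(B, alpha)
    if y is None:
        return ff
    out = np.zeros((m + 1, m + 1))
    out[:m, :m] = ff
    cf = _class_feature_mi(B, np.asarray(y), alpha)
    out[:m, m] = cf
    out[m, :m] = cf
    return out


def _max_weight_spanning_tree(W: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal maximum-weight spanning tree with a deterministic tie-break:
    among equal weights, the edge with the smaller (min index, max index)
    pair wins."""
    m = W.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    w = W[iu, ju]
    order = np.lexsort((ju, iu, -w))  # primary: weight desc; then (i, j) asc
    parent = np.arange(m)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int]] = []
    for idx in order:
        a, b = int(iu[idx]), int(ju[idx])
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b))
            if len(edges) == m - 1:
                break
    return edges


@dataclass
class TreeBN:
    """Fitted tree Bayesian network, rooted at the identity variable.

    ``parent[i]`` is the parent node of feature i: ``CLASS_NODE`` when the
    parent is the identity variable, else another feature index.
    ``cpt_class_child[i]`` (shape K) holds p(x_i=1 | y=k) for features whose
    parent is the class; ``cpt_feature_child[i]`` (shape 2) holds
    p(x_i=1 | x_parent=b) otherwise.  ``class_log_prior`` has length K.
    """

    parent: np.ndarray
    class_log_prior: np.ndarray
    class_states: list
    cpt_class_child: dict[int, np.ndarray]
    cpt_feature_child: dict[int, np.ndarray]
    alpha: float

    @property
    def n_features(self) -> int:
        return self.parent.size

    @property
    def edges(self) -> list[tuple[int | str, int]]:
        """Directed edges (parent, child); the class node is ``"identity"``."""
        return [
            ("identity" if self.parent[i] == CLASS_NODE else int(self.parent[i]), i)
            for i in range(self.n_features)
        ]

    def log_joint(self, B: np.ndarray) -> np.ndarray:
        """log p(mask, y=k) for each sample (rows of B) and class state k."""
        B = np.atleast_2d(np.asarray(B))
        n = B.shape[0]
        K = self.class_log_prior.size
        out = np.tile(self.class_log_prior, (n, 1))
        cc = sorted(self.cpt_class_child)
        if cc:
            P1 = np.stack([self.cpt_class_child[i] for i in cc], axis=1)  # K x |cc|
            with np.errstate(divide="ignore"):
                L1, L0 = np.log(P1), np.log1p(-P1)
            Bc = B[:, cc].astype(float)
            out += Bc @ L1.T + (1.0 - Bc) @ L0.T
        for i, p1 in self.cpt_feature_child.items():
            pb = B[:, int(self.parent[i])].astype(int)
            pr = np.where(B[:, i] == 1, p1[pb], 1.0 - p1[pb])
            with np.errstate(divide="ignore"):
                out += np.log(pr)[:, None]
        return out

    def predict_posterior(self, mask: np.ndarray) -> np.ndarray:
        """Posterior over class states for one mask or a stack of masks;
        rows sum to 1.  If every state has zero probability (possible only
        with ``alpha=0``), the class prior is returned with a warning."""
        lj = self.log_joint(mask)
        bad = ~np.isfinite(lj).any(axis=1)
        if bad.any():
            warnings.warn(
                "zero-probability evidence for some samples; returning prior"
            )
            lj[bad] = self.class_log_prior
        post = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
        return post[0] if np.asarray(mask).ndim == 1 else post

    def to_sif(self, path: str | Path, feature_names: list[str] | None = None) -> None:
        """Export the directed edge list in .sif format (parent dep child)."""
        def name(node) -> str:
            if node == "identity":
                return "identity"
            return feature_names[node] if feature_names else f"x{node}"
        lines = [f"{name(p)}\tdep\t{name(c)}" for p, c in self.edges]
        Path(path).write_text("\n".join(lines) + "\n")

    def cpts_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "class_states": [str(s) for s in self.class_states],
            "class_prior": np.exp(self.class_log_prior).tolist(),
            "alpha": self.alpha,
            "parent": self.parent.tolist(),
            "cpt_class_child": {str(i): p.tolist() for i, p in self.cpt_class_child.items()},
            "cpt_feature_child": {str(i): p.tolist() for i, p in self.cpt_feature_child.items()},
        }, indent=1))


def learn_tree_bn(B: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> TreeBN:
    """Chow-Liu structure learning plus CPT estimation.

    Builds the maximum-weight spanning tree over the pairwise MI matrix of
    all binary variables and the class, orients edges away from the class
    node, and fills conditional probability tables with pseudocount
    `alpha`.  Constant features attach somewhere with MI 0; the network
    remains a valid spanning tree.
    """
    B = np.asarray(B)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to learn a classifier network")
    n, m = B.shape
    W = pairwise_mutual_information(B, y, alpha=alpha)
    und = _max_weight_spanning_tree(W)

    # orient away from the class node (index m) by BFS
    adj: dict[int, list[int]] = {i: [] for i in range(m + 1)}
    for a, b in und:
        adj[a].append(b)
        adj[b].append(a)
    parent = np.full(m, CLASS_NODE, dtype=int)
    seen = {m}
    frontier = [m]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    parent[v] = CLASS_NODE if u == m else u
                    nxt.append(v)
        frontier = nxt

    K = classes.size
    nk = np.array([(y == c).sum() for c in classes], dtype=float)
    class_log_prior = np.log((nk + alpha) / (n + K * alpha))
    Y = (y[:, None] == classes[None, :]).astype(float)
    c1 = Y.T @ B.astype(float)  # K x m: count x_i=1 within class k
    cpt_class_child: dict[int, np.ndarray] = {}
    cpt_feature_child: dict[int, np.ndarray] = {}
    for i in range(m):
        p = int(parent[i])
        if p == CLASS_NODE:
            cpt_class_child[i] = (c1[:, i] + alpha) / (nk + 2.0 * alpha)
        else:
            xi, xp = B[:, i].astype(float), B[:, p].astype(float)
            n11 = float(xi @ xp)
            n1 = float(xp.sum())
            p1_given = np.array([
                (xi.sum() - n11 + alpha) / (n - n1 + 2.0 * alpha),
                (n11 + alpha) / (n1 + 2.0 * alpha),
            ])
            cpt_feature_child[i] = p1_given
    return TreeBN(
        parent, class_log_prior, list(classes),
        cpt_class_child, cpt_feature_child, alpha,
    )


class ChowLiuBNClassifier(ClassifierMixin, BaseEstimator):
    """Discrete Bayesian-network classifier on binarized peak fingerprints.

    Parameters
    ----------
    fraction:
        Per-sample top fraction of positive peaks kept when binarizing
        (default 0.3: the 30% most abundant peaks become 1, the rest 0).
    alpha:
        Laplace pseudocount used both in the mutual-information estimates
        and in the conditional probability tables.
    binarize:
        If False, inputs are assumed to already be 0/1 masks.
    """

    def __init__(self, fraction: float = 0.3, alpha: float = 1.0, binarize: bool = True):
        self.fraction = fraction
        self.alpha = alpha
        self.binarize = binarize

    def _masks(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if not self.binarize:
            return X.astype(np.int8)
        return np.stack([binarize_top_fraction(x, self.fraction) for x in X])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ChowLiuBNClassifier":
        y = np.asarray(y)
        B = self._masks(X)
        self.tree_ = learn_tree_bn(B, y, alpha=self.alpha)
        self.classes_ = np.asarray(self.tree_.class_states)
        self.n_features_in_ = B.shape[1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "tree_")
        B = self._masks(X)
        return np.atleast_2d(self.tree_.predict_posterior(B))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def predict_ranked(self, X: np.ndarray) -> np.ndarray:
        """Class labels ranked by descending posterior, one row per sample.

        Ties are broken by class order for determinism.
        """
        proba = self.predict_proba(X)
        order = np.argsort(-proba, axis=1, kind="stable")
        return self.classes_[order]
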