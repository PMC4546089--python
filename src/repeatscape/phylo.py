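"""Phylogenetic signal and comparative regression for TE traits.

Implements Felsenstein's independent contrasts, Blomberg's K with a
PIC-variance permutation test (one-sided: low contrast variance means
strong signal), phylogenetic GLS under the Brownian covariance of the
tree, and an ordinary GLS trend test of a trait against ordinal
phylogenetic position.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_EPS_BL = 1e-8

TraitLike = Union[dict, "pd.Series"]


@dataclass
class KResult:
    K: float
    p: float
    n_perm: int
    obs_pic_variance: float


@dataclass
class GLSResult:
    coefficients: np.ndarray  # [intercept, slope, ...]
    r_squared: float
    p_value: float
    covariance_mode: str


class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self, length: float, label: Optional[str] = None):
        self.children: list[_Node] = []
        self.length = length
        self.label = label


def _to_struct(tree: dendropy.Tree, pad_eps: bool = True) -> _Node:
    """Binary working copy: polytomies resolved to zero-length branches.

    With ``pad_eps`` non-positive branch lengths (including the new
    zero-length resolution branches) are replaced by a small epsilon,
    which the contrast computation needs; the covariance matrix does
    not, and skipping the padding keeps star phylogenies exactly
    diagonal.
    """
    resolved = 0
    padded = 0
    fill = _EPS_BL if pad_eps else 0.0

    def convert(node: dendropy.Node, is_root: bool) -> _Node:
        nonlocal resolved, padded
        length = node.edge.length
        if is_root:
            length = 0.0
        elif length is None or length <= 0:
            length = fill
            padded += 1
        if node.is_leaf():
            return _Node(length, node.taxon.label)
        out = _Node(length)
        out.children = [convert(c, False) for c in node.child_nodes()]
        while len(out.children) > 2:
            merged = _Node(fill)
            merged.children = out.children[:2]
            out.children = [merged] + out.children[2:]
            resolved += 1
        return out

    root = convert(tree.seed_node, True)
    if resolved:
        logger.info("resolved %d multifurcations with zero-length branches", resolved)
    if padded:
        logger.info("replaced %d non-positive branch lengths with %g", padded, _EPS_BL)
    return root


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _trait_array(trait, labels: Sequence[str]) -> np.ndarray:
    missing = [l for l in labels if l not in trait]
    if missing:
        raise ValueError(f"trait values missing for tips: {missing}")
    return np.array([float(trait[l]) for l in labels])


def pic_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Contrast coefficient matrix M with contrasts = M @ trait_vector.

    Rows follow a deterministic postorder of the (resolved) tree; the
    tip order of the columns is the sorted tip labels, also returned.
    Contrasts are linear in the trait, so this matrix lets permutation
    tests recompute all contrasts with one matrix product.
    """
    labels = _tip_labels(tree)
    if len(labels) < 2:
        raise ValueError("need at least 2 tips for contrasts")
    pos = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    rows: list[np.ndarray] = []

    def prune(node: _Node) -> tuple[np.ndarray, float]:
        if not node.children:
            coef = np.zeros(n)
            coef[pos[node.label]] = 1.0
            return coef, node.length
        (c1, b1), (c2, b2) = (prune(ch) for ch in node.children)
        rows.append((c1 - c2) / math.sqrt(b1 + b2))
        coef = (b2 * c1 + b1 * c2) / (b1 + b2)
        return coef, node.length + b1 * b2 / (b1 + b2)

    prune(_to_struct(tree))
    return np.vstack(rows), labels


def pic(tree: dendropy.Tree, trait: TraitLike) -> np.ndarray:
    """Standardized independent contrasts (n-1 values, postorder)."""
    M, labels = pic_matrix(tree)
    return M @ _trait_array(trait, labels)


def vcv_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance C: C[i,j] = root-to-MRCA(i,j) path length."""
    labels = _tip_labels(tree)
    pos = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    def walk(node: _Node, depth: float) -> list[int]:
        depth += node.length
        if not node.children:
            i = pos[node.label]
            C[i, i] = depth
            return [i]
        groups = [walk(ch, depth) for ch in node.children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        C[i, j] = C[j, i] = depth
        return [i for g in groups for i in g]

    walk(_to_struct(tree, pad_eps=False), 0.0)
    return C, labels


def blomberg_k(tree: dendropy.Tree, trait: TraitLike) -> float:
    """Blomberg's K: observed MSE0/MSE over its Brownian expectation.

    K = 1 under pure Brownian motion; K > 1 means relatives resemble
    each other more than BM predicts.  Invariant to affine transforms
    of the trait.
    """
    C, labels = vcv_matrix(tree)
    x = _trait_array(trait, labels)
    n = len(x)
    if n < 4:
        warnings.warn("Blomberg's K with fewer than 4 tips is unreliable",
                      stacklevel=2)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Brownian covariance (zero-length structure)") from exc
    ones = np.ones(n)
    denom = ones @ Cinv @ ones
    ahat = (ones @ Cinv @ x) / denom
    resid = x - ahat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ Cinv @ resid / (n - 1)
    if mse <= 0 or mse0 == 0:
        raise ValueError("trait has no variance; K undefined")
    expected_ratio = (np.trace(C) - n / denom) / (n - 1)
    return float((mse0 / mse) / expected_ratio)


def k_significance(
    tree: dendropy.Tree,
    trait: TraitLike,
    n_perm: int = 999,
    seed: int = 0,
) -> KResult:
    """Permutation significance of phylogenetic signal via PIC variance.

    Trait values are shuffled across tips; p = (1 + #{null variance <=
    observed}) / (n_perm + 1).  Lower observed contrast variance than
    the null means stronger signal (one-sided test).
    """
    if n_perm < 99:
        warnings.warn("fewer than 99 permutations gives a coarse p-value",
                      stacklevel=2)
    M, labels = pic_matrix(tree)
    x = _trait_array(trait, labels)
    obs = float(np.var(M @ x, ddof=1))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    null = np.var(perms @ M.T, axis=1, ddof=1)
    p = (1 + int(np.sum(null <= obs))) / (n_perm + 1)
    return KResult(K=blomberg_k(tree, trait), p=p, n_perm=n_perm,
                   obs_pic_variance=obs)


def _gls_r_squared(y: np.ndarray, X: np.ndarray, C: np.ndarray,
                   beta: np.ndarray) -> float:
    L = np.linalg.cholesky(C)
    wy = np.linalg.solve(L, y)
    wX = np.linalg.solve(L, X)
    rss = float(np.sum((wy - wX @ beta) ** 2))
    # intercept-only GLS fit supplies the total sum of squares
    w1 = np.linalg.solve(L, np.ones_like(y))
    mu = float((w1 @ wy) / (w1 @ w1))
    tss = float(np.sum((wy - mu * w1) ** 2))
    return 1.0 - rss / tss if tss > 0 else float("nan")


def pgls(
    tree: dendropy.Tree,
    response: TraitLike,
    predictor: TraitLike,
    log_transform: bool = False,
) -> GLSResult:
    """Phylogenetic GLS regression of response on predictor.

    The error covariance is the Brownian matrix of the tree.  With a
    star phylogeny (diagonal C) the estimates reduce to OLS.
    """
    C, labels = vcv_matrix(tree)
    y = _trait_array(response, labels)
    x = _trait_array(predictor, labels)
    if log_transform:
        if np.any(y <= 0) or np.any(x <= 0):
            raise ValueError("log transform requires positive trait values")
        y, x = np.log(y), np.log(x)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant (collinear with intercept)")
    X = sm.add_constant(x)
    fit = sm.GLS(y, X, sigma=C).fit()
    return GLSResult(
        coefficients=np.asarray(fit.params),
        r_squared=_gls_r_squared(y, X, C, np.asarray(fit.params)),
        p_value=float(fit.pvalues[1]),
        covariance_mode="brownian",
    )


def gls_trend(
    values: Sequence[float], order: Optional[Sequence[float]] = None
) -> GLSResult:
    """Linear trend of a trait along ordinal phylogenetic position.

    ``order`` defaults to 0..n-1 (outgroup first, most derived last);
    the covariance is the identity, i.e. ordinary least squares.  A
    constant trait returns slope 0 with r-squared not available.
    """
    y = np.asarray(values, dtype=float)
    if len(y) < 3:
        raise ValueError("trend test needs at least 3 species")
    x = np.arange(len(y), dtype=float) if order is None else np.asarray(order, float)
    if np.ptp(y) == 0:
        return GLSResult(coefficients=np.array([y[0], 0.0]),
                         r_squared=float("nan"), p_value=float("nan"),
                         covariance_mode="identity")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return GLSResult(
        coefficients=np.asarray(fit.params),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        covariance_mode="identity",
    )
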