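"""Phylogenetic distinctiveness: fair proportion (ED), equal splits (ES), QE weights.

ED apportions each branch equally among the tips descending from it; ES
halves (more generally, divides by the child count) a branch's value at
every node passed on the way down. Both sum to the tree's total PD.

The QE index is the tip-weight vector maximizing Rao's quadratic entropy
``w' D w / 2`` on the patristic distance matrix over the probability
simplex: originality weights concentrating on evolutionarily isolated
lineages. Tree metrics are conditionally negative definite, so the
objective is concave on the simplex and the active-set solver below finds
the global optimum; at it, every species with positive weight has the same
expected distance to the weighted assemblage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .treeio import Phylogeny

__all__ = [
    "ed_scores",
    "es_scores",
    "qe_scores",
    "distinctiveness_scores",
    "distinctiveness_risk_correlation",
]


def ed_scores(tree: Phylogeny) -> pd.Series:
    """Fair-proportion (evolutionary distinctiveness) score per tip, in My."""
    bs = tree.branch_structure()
    A = bs.incidence.astype(float)
    per_tip_share = bs.lengths / A.sum(axis=1)
    return pd.Series(A.T @ per_tip_share, index=tree.tip_labels, name="ed")


def es_scores(tree: Phylogeny) -> pd.Series:
    """Equal-splits score per tip, dividing by the child count at each node."""
    scores = {}
    for leaf in tree.root.leaf_iter():
        total, prod, node = 0.0, 1.0, leaf
        while node.parent_node is not None:
            total += node.edge.length / prod
            node = node.parent_node
            if node.parent_node is not None:
                prod *= len(node.child_nodes())
        scores[str(leaf.taxon.label).strip()] = total
    return pd.Series(scores, name="es").reindex(list(tree.tip_labels))


def qe_scores(tree: Phylogeny, *, tol: float = 1e-9, max_iter: int | None = None) -> pd.Series:
    """Tip weights maximizing Rao's quadratic entropy on patristic distances.

    Solved by an active-set method on the simplex: on the current support the
    stationarity condition ``(Dw)_i = λ`` is a linear system; negative weights
    are removed and Karush-Kuhn-Tucker violations ``(Dw)_j > λ`` re-enter the
    support. Weights of duplicate zero-distance tips are split arbitrarily by
    the least-squares solve.
    """
    if tree.n_tips < 2:
        raise ValueError("QE weights need at least 2 tips")
    D = tree.patristic_matrix().values
    n = D.shape[0]
    support = np.ones(n, dtype=bool)
    max_iter = max_iter or 20 * n + 50
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        idx = np.flatnonzero(support)
        k = idx.size
        # KKT system: D_SS w_S - λ 1 = 0,  1' w_S = 1
        M = np.zeros((k + 1, k + 1))
        M[:k, :k] = D[np.ix_(idx, idx)]
        M[:k, k] = -1.0
        M[k, :k] = 1.0
        rhs = np.zeros(k + 1)
        rhs[k] = 1.0
        sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        w_s, lam = sol[:k], sol[k]
        if np.min(w_s) < -tol:
            support[idx[np.argmin(w_s)]] = False
            continue
        w = np.zeros(n)
        w[idx] = np.clip(w_s, 0.0, None)
        grad = D @ w
        outside = np.flatnonzero(~support)
        if outside.size and np.max(grad[outside]) > lam + max(tol, 1e-7):
            support[outside[np.argmax(grad[outside])]] = True
            continue
        w /= w.sum()
        return pd.Series(w, index=tree.tip_labels, name="qe")
    raise RuntimeError(
        f"QE active-set did not converge in {max_iter} iterations "
        f"(n={n}, last support size {support.sum()})"
    )


def rao_qe(weights: np.ndarray, D: np.ndarray) -> float:
    """Rao's quadratic entropy w'Dw/2 for a weight vector on distances D."""
    w = np.asarray(weights, dtype=float)
    return float(w @ D @ w / 2.0)


def distinctiveness_scores(tree: Phylogeny) -> pd.DataFrame:
    """All three indices as one table (columns ed, es, qe)."""
    return pd.concat([ed_scores(tree), es_scores(tree), qe_scores(tree)], axis=1)


def distinctiveness_risk_correlation(scores: pd.DataFrame, risk_ranks: pd.Series) -> dict:
    """Spearman rho of each distinctiveness index with the ordinal risk ranks.

    Returns ``{index_name: {"rho": float|None, "p": float|None}}``; an index
    or a risk vector without variance yields ``None`` (not computable).
    """
    common = scores.index.intersection(risk_ranks.index)
    if len(common) < 3:
        raise ValueError("need at least 3 species shared between scores and risks")
    y = risk_ranks.loc[common].values
    out = {}
    for name in scores.columns:
        x = scores.loc[common, name].values
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[name] = {"rho": None, "p": None}
            continue
        rho, p = spearmanr(x, y)
        out[name] = {"rho": float(rho), "p": float(p)}
    return out
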