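"""Threat-diversity statistics: Phi co-occurrence, Moran's I, structure-corrected tests.

"Threat diversity" is the number of distinct major threat classes recorded
for a species. Its autocorrelation over a proximity structure (phylogenetic,
geographic or habitat) is measured with Moran's I; its association with the
ordinal risk scale is tested with Spearman correlations whose null
distributions come from restricted permutations that respect the proximity
structure, and with an exact (enumeration-based) test comparing mean threat
counts between adjacent risk categories.

Restricted permutations follow a similarity-biased sequential assignment:
values are placed one by one, and the probability of placing value v at a
free position is proportional to ``1 + strength *`` (the proximity-weighted
average similarity of v to the values already placed nearby). With uniform
proximities every position weight is equal, so the scheme reduces exactly to
free permutation.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata, spearmanr

from .permutation import PermutationTestResult, permutation_p
from .treeio import Phylogeny

__all__ = [
    "phi_matrix",
    "threat_counts",
    "morans_i",
    "corrected_rank_correlation",
    "mean_shift_test",
    "order_level_correlation",
    "build_proximity",
]


# ------------------------------------------------------------ co-occurrence

def phi_matrix(threats: pd.DataFrame) -> pd.DataFrame:
    """Phi coefficients between all pairs of binary threat-occurrence vectors.

    Phi equals the product-moment correlation of the 0/1 vectors; constant
    columns yield undefined (NaN) entries. Diagonal is 1.
    """
    X = threats.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 species")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X.values, rowvar=False)
    C = np.atleast_2d(C)
    const = X.values.std(axis=0) == 0
    C[const, :] = np.nan
    C[:, const] = np.nan
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=X.columns, columns=X.columns)


def threat_counts(threats: pd.DataFrame) -> pd.Series:
    """Number of distinct threat classes per species (row sums)."""
    return threats.astype(int).sum(axis=1).rename("n_threats")


# ----------------------------------------------------------------- Moran's I

def _moran_stat(z: np.ndarray, W: np.ndarray) -> float:
    n = z.size
    return float(n / W.sum() * (z @ W @ z) / (z @ z))


def morans_i(
    values: pd.Series,
    w: pd.DataFrame,
    *,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
) -> PermutationTestResult:
    """Moran's I of ``values`` under proximity matrix ``w``, permutation p-value.

    I = (n/ΣW) (z'Wz)/(z'z) with z mean-centered; the null shuffles values
    across species. One-tailed for positive autocorrelation by default.
    """
    common = values.index.intersection(w.index)
    if len(common) != len(values) or len(common) != len(w):
        raise ValueError("values and proximity matrix must index the same species")
    x = values.loc[common].astype(float).values
    W = w.loc[common, common].values.astype(float)
    _check_proximity(W)
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant values")
    z = x - x.mean()
    obs = _moran_stat(z, W)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(z) for _ in range(n_perm)])
    denom = float(z @ z)
    null = (len(z) / W.sum()) * np.einsum("pi,ij,pj->p", perms, W, perms) / denom
    return permutation_p(obs, null, tail=tail, seed=seed)


# --------------------------------------------- restricted (Lapointe-style) null

def _similarity(values: np.ndarray) -> np.ndarray:
    """Pairwise similarity of values: 1 − normalized rank distance, in [0,1]."""
    r = rankdata(values)
    span = max(np.ptp(r), 1.0)
    return 1.0 - np.abs(r[:, None] - r[None, :]) / span


def restricted_permutation(
    values: np.ndarray,
    W: np.ndarray,
    rng: np.random.Generator,
    *,
    strength: float = 1.0,
) -> np.ndarray:
    """One structure-respecting permutation of ``values``.

    Sequential assignment: values are processed in random order; each is
    placed at a free position with probability proportional to
    ``1 + strength * s``, where ``s`` is the proximity-weighted mean
    similarity of the value to the values already placed (similarity = 1 −
    normalized rank distance). Uniform proximities give free permutation.
    """
    n = values.size
    sim = _similarity(values)
    order = rng.permutation(n)
    placed_pos: list[int] = []
    placed_val: list[int] = []
    out = np.empty(n, dtype=values.dtype)
    free = np.ones(n, dtype=bool)
    Wn = W / max(W.max(), 1e-300)
    for v_idx in order:
        free_pos = np.flatnonzero(free)
        if placed_pos:
            s = Wn[np.ix_(free_pos, placed_pos)] @ sim[v_idx, placed_val]
            s = s / len(placed_pos)
            wts = 1.0 + strength * s
        else:
            wts = np.ones(free_pos.size)
        probs = wts / wts.sum()
        j = rng.choice(free_pos, p=probs)
        out[j] = values[v_idx]
        free[j] = False
        placed_pos.append(j)
        placed_val.append(v_idx)
    return out


def corrected_rank_correlation(
    x: pd.Series,
    y: pd.Series,
    w: pd.DataFrame | None,
    *,
    n_perm: int = 999,
    seed: int | None = None,
    strength: float = 1.0,
    tail: str = "two-sided",
) -> PermutationTestResult:
    """Spearman correlation of x and y with a structure-corrected permutation null.

    The null permutes ``x`` with the similarity-biased restricted scheme so
    that arrangements concordant with the proximity structure ``w`` are
    favoured; ``w=None`` (or an all-zero ``w``) falls back to free
    permutation.
    """
    common = x.index.intersection(y.index)
    xv = x.loc[common].astype(float).values
    yv = y.loc[common].astype(float).values
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for constant input")
    W = None
    if w is not None:
        W = w.loc[common, common].values.astype(float)
        _check_proximity(W, allow_zero=True)
        if W.max() == 0:
            warnings.warn("proximity matrix is all zero; using free permutation")
            W = None
    obs, _ = spearmanr(xv, yv)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        if W is None:
            xp = rng.permutation(xv)
        else:
            xp = restricted_permutation(xv, W, rng, strength=strength)
        null[i], _ = spearmanr(xp, yv)
    return permutation_p(float(obs), null, tail=tail, seed=seed)


# ------------------------------------------------------------ mean-shift test

def mean_shift_test(
    x: pd.Series,
    groups: pd.Series,
    *,
    low: str,
    high: str,
    w: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    strength: float = 1.0,
    tail: str = "greater",
    exact_limit: int = 1_000_000,
) -> PermutationTestResult:
    """Exact/permutation test that mean(x | high) exceeds mean(x | low).

    T is the standardized mean difference: (mean_high − mean_low) divided by
    the standard deviation of that difference over the permutation
    distribution. When the number of distinct label assignments is at most
    ``exact_limit`` and no proximity correction is requested, the null is
    enumerated exhaustively; otherwise ``n_perm`` Monte-Carlo (optionally
    structure-restricted) label permutations are drawn.
    """
    mask = groups.isin([low, high])
    g = groups[mask]
    xx = x.loc[g.index].astype(float).values
    lab = (g == high).values  # True = high group
    n_high, n_low = int(lab.sum()), int((~lab).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(f"empty group: {low}={n_low}, {high}={n_high}")
    n = lab.size

    def diff(mask_high: np.ndarray) -> float:
        return float(xx[mask_high].mean() - xx[~mask_high].mean())

    obs_diff = diff(lab)
    n_comb = math.comb(n, n_high)
    if w is None and n_comb <= exact_limit:
        diffs = np.empty(n_comb)
        for i, pos in enumerate(combinations(range(n), n_high)):
            m = np.zeros(n, dtype=bool)
            m[list(pos)] = True
            diffs[i] = diff(m)
        sd = float(diffs.std())
        T = obs_diff / sd if sd > 0 else 0.0
        if tail == "greater":
            p = float(np.mean(diffs >= obs_diff - 1e-12))
        elif tail == "less":
            p = float(np.mean(diffs <= obs_diff + 1e-12))
        else:
            m0 = diffs.mean()
            p = float(np.mean(np.abs(diffs - m0) >= abs(obs_diff - m0) - 1e-12))
        return PermutationTestResult(
            statistic=T, null=diffs / sd if sd > 0 else diffs, p_value=p,
            direction="+" if obs_diff >= 0 else "-",
            n_perm=n_comb, seed=seed, tail=tail,
        )

    W = None
    if w is not None:
        W = w.loc[g.index, g.index].values.astype(float)
        _check_proximity(W, allow_zero=True)
        if W.max() == 0:
            W = None
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_perm)
    lab_f = lab.astype(float)
    for i in range(n_perm):
        if W is None:
            lp = rng.permutation(lab_f)
        else:
            lp = restricted_permutation(lab_f, W, rng, strength=strength)
        diffs[i] = diff(lp.astype(bool))
    sd = float(diffs.std())
    T = obs_diff / sd if sd > 0 else 0.0
    res = permutation_p(obs_diff, diffs, tail=tail, seed=seed)
    res.statistic = T
    res.null = diffs / sd if sd > 0 else diffs
    return res


# -------------------------------------------------- order-level correlation

def order_level_correlation(
    clade_mean_threats: pd.Series, clade_pd_loss: pd.Series
) -> dict:
    """Pearson and rank correlations of per-clade mean threat count vs PDloss.

    Returns both the raw-data and rank-transformed correlations with their t
    statistics (df = n − 2) and two-sided p-values.
    """
    common = clade_mean_threats.index.intersection(clade_pd_loss.index)
    if len(common) < 3:
        raise ValueError("need at least 3 clades (df = n − 2 > 0)")
    a = clade_mean_threats.loc[common].astype(float).values
    b = clade_pd_loss.loc[common].astype(float).values
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant vector")
    n = len(common)
    df = n - 2

    def block(u, v):
        r, p = pearsonr(u, v)
        t = r * math.sqrt(df / (1 - r**2)) if abs(r) < 1 else math.inf
        return {"r": float(r), "t": float(t), "df": df, "p": float(p)}

    return {
        "n_clades": n,
        "raw": block(a, b),
        "rank": block(rankdata(a), rankdata(b)),
    }


# ----------------------------------------------------------- proximity builders

def _check_proximity(W: np.ndarray, *, allow_zero: bool = False) -> None:
    if W.shape[0] != W.shape[1]:
        raise ValueError("proximity matrix must be square")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("proximity matrix must be symmetric")
    if np.any(W < 0):
        raise ValueError("proximity weights must be nonnegative")
    if np.any(np.abs(np.diag(W)) > 1e-12):
        raise ValueError("proximity matrix must have zero diagonal")
    if not allow_zero and W.max() == 0:
        raise ValueError("proximity matrix needs at least one positive weight")


def build_proximity(kind: str, source) -> pd.DataFrame:
    """Build a species × species proximity matrix.

    ``kind="phylogenetic"`` takes a tree (or patristic DataFrame) and uses
    ``(d_max − d_ij)/d_max``; ``"geographic"``/``"habitat"`` take a binary
    species × label incidence table and use Jaccard similarity of label sets.
    The diagonal is zero. Species with empty label sets get zero rows (logged).
    """
    if kind == "phylogenetic":
        D = source.patristic_matrix() if isinstance(source, Phylogeny) else pd.DataFrame(source)
        dmax = float(D.values.max())
        if dmax <= 0:
            raise ValueError("patristic distances are all zero")
        W = (dmax - D.values) / dmax
    elif kind in ("geographic", "habitat"):
        inc = pd.DataFrame(source).astype(float)
        M = inc.values
        inter = M @ M.T
        sizes = M.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        empty = np.flatnonzero(sizes == 0)
        if empty.size:
            warnings.warn(
                f"{empty.size} species with empty label sets have zero proximity rows"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
        D = inc
    else:
        raise ValueError(f"unknown proximity kind {kind!r}")
    np.fill_diagonal(W, 0.0)
    idx = D.index
    out = pd.DataFrame(W, index=idx, columns=idx)
    out.attrs["kind"] = kind
    return out
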