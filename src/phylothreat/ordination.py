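"""Threat-type ordination: DPCoA on phylogenetic distances and correspondence analysis.

DPCoA (double principal coordinate analysis) embeds species by principal
coordinates of their pairwise phylogenetic distances, places each threat at
the centroid of the species it affects, and extracts the principal axes of
those centroids with threats weighted by the number of species each affects.
The axes' eigenvalues decompose the between-threat share of Rao's quadratic
entropy. Patristic distances are square-root transformed by default, which
makes any tree metric Euclidean-embeddable; a Cailliez additive correction
is available instead.

Correspondence analysis of a threats × areas (or habitats) contingency table
is the classical chi-square-metric SVD; total inertia equals the Pearson
chi-square statistic divided by the grand total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.ordination import ca as _skbio_ca

__all__ = [
    "OrdinationResult",
    "NonEuclideanDistanceError",
    "dpcoa",
    "correspondence_analysis",
    "build_threat_by_label_table",
]

_EIG_TOL = 1e-10


class NonEuclideanDistanceError(ValueError):
    """Distances are not Euclidean-embeddable under the configured transform."""


@dataclass
class OrdinationResult:
    """Eigenvalues, inertia fractions and row/column coordinates of an ordination.

    For DPCoA ``row_coords`` holds species and ``col_coords`` threats; for a
    correspondence analysis they hold the table's rows and columns, both in
    principal coordinates.
    """

    eigenvalues: np.ndarray
    proportions: np.ndarray
    total_inertia: float
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def _fix_signs(*coord_sets: np.ndarray) -> None:
    """Make the largest-magnitude loading on each axis positive (in place)."""
    if not coord_sets:
        return
    stacked = np.vstack(coord_sets)
    for a in range(stacked.shape[1]):
        col = stacked[:, a]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            for c in coord_sets:
                c[:, a] *= -1.0


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ D @ J
    d2 = -0.5 * J @ (D**2) @ J
    M = np.zeros((2 * n, 2 * n))
    M[:n, n:] = 2.0 * d2
    M[n:, :n] = -np.eye(n)
    M[n:, n:] = -4.0 * d1
    eig = np.linalg.eigvals(M)
    return float(max(0.0, np.max(eig.real)))


def dpcoa(
    threats: pd.DataFrame,
    distances: pd.DataFrame,
    *,
    transform: str = "sqrt",
) -> OrdinationResult:
    """DPCoA of binary species × threat incidence against species distances.

    Only species affected by at least one threat are retained; empty threat
    columns are dropped with a warning. Each threat is weighted by the number
    of species it affects. Eigenvalues are the between-threat inertias;
    ``proportions`` are their fractions of the between-threat total.
    """
    inc = threats.astype(float)
    if not set(inc.index) <= set(distances.index):
        missing = sorted(set(inc.index) - set(distances.index))
        raise ValueError(f"species without distances: {missing[:10]}")
    affected = inc.sum(axis=1) > 0
    inc = inc.loc[affected]
    if inc.empty:
        raise ValueError("no species is affected by any threat")
    empty = inc.columns[inc.sum(axis=0) == 0].tolist()
    if empty:
        warnings.warn(f"dropping empty threat columns: {empty}")
        inc = inc.drop(columns=empty)
    species = list(inc.index)
    D = distances.loc[species, species].values.astype(float)

    if transform == "sqrt":
        D2 = D.copy()  # squared transformed distances = raw patristic
    elif transform == "cailliez":
        c = _cailliez_constant(D)
        Dc = D + c
        np.fill_diagonal(Dc, 0.0)
        D2 = Dc**2
    elif transform == "none":
        D2 = D**2
    else:
        raise ValueError(f"unknown transform {transform!r}")

    n_per_threat = inc.sum(axis=0).values            # species per threat
    w_t = n_per_threat / n_per_threat.sum()          # threat weights
    P = inc.values / n_per_threat                    # species profile within threat
    mu = P @ w_t                                     # overall species weights

    # weighted principal coordinates of the species
    C = np.eye(len(species)) - np.outer(np.ones(len(species)), mu)
    G = -0.5 * C @ D2 @ C.T
    s = np.sqrt(mu)
    K = (G * s[None, :]) * s[:, None]
    eigval, eigvec = np.linalg.eigh(K)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval.size and eigval.min() < -_EIG_TOL * max(1.0, eigval.max()):
        raise NonEuclideanDistanceError(
            "distances are not Euclidean-embeddable under this transform; "
            "try transform='sqrt' or 'cailliez'"
        )
    keep = eigval > _EIG_TOL * max(1.0, abs(eigval).max())
    X = (eigvec[:, keep] / s[:, None]) * np.sqrt(eigval[keep])[None, :]

    # threat centroids in species principal-coordinate space
    Y = P.T @ X
    # principal axes of centroids, threats weighted by species counts
    Cov = (Y * w_t[:, None]).T @ Y
    bev, bax = np.linalg.eigh(Cov)
    order = np.argsort(bev)[::-1]
    bev, bax = bev[order], bax[:, order]
    keep_b = bev > _EIG_TOL * max(1.0, abs(bev).max()) if bev.size else np.array([], bool)
    bev, bax = bev[keep_b], bax[:, keep_b]
    threat_coords = Y @ bax
    species_coords = X @ bax
    _fix_signs(threat_coords, species_coords)

    total = float(bev.sum())
    props = bev / total if total > 0 else np.zeros_like(bev)
    axes = [f"axis{i+1}" for i in range(len(bev))]
    return OrdinationResult(
        eigenvalues=bev,
        proportions=props,
        total_inertia=total,
        row_coords=pd.DataFrame(species_coords, index=species, columns=axes),
        col_coords=pd.DataFrame(threat_coords, index=list(inc.columns), columns=axes),
    )


def correspondence_analysis(table: pd.DataFrame) -> OrdinationResult:
    """Classical correspondence analysis of a nonnegative contingency table.

    Rows and columns are returned in principal coordinates; total inertia is
    chi-square / grand total. All-zero rows/columns are dropped with a
    warning; a rank-one (independent) table yields a zero-inertia result.
    """
    T = table.astype(float)
    if (T.values < 0).any():
        raise ValueError("contingency table must be nonnegative")
    zr = T.index[T.sum(axis=1) == 0].tolist()
    zc = T.columns[T.sum(axis=0) == 0].tolist()
    if zr or zc:
        warnings.warn(f"dropping all-zero rows {zr} and columns {zc}")
        T = T.drop(index=zr, columns=zc)
    if T.empty or T.values.sum() <= 0:
        raise ValueError("contingency table has no positive entries")

    res = _skbio_ca(T, scaling=1)
    eigval = res.eigvals.values
    keep = eigval > _EIG_TOL
    eigval = eigval[keep]
    if eigval.size == 0:
        zeros = np.zeros((len(T.index), 0))
        return OrdinationResult(
            eigenvalues=np.array([]),
            proportions=np.array([]),
            total_inertia=0.0,
            row_coords=pd.DataFrame(zeros, index=T.index),
            col_coords=pd.DataFrame(np.zeros((len(T.columns), 0)), index=T.columns),
        )
    row = res.samples.values[:, keep]                      # principal (scaling=1)
    col = res.features.values[:, keep] * np.sqrt(eigval)   # standard -> principal
    _fix_signs(row, col)
    axes = [f"axis{i+1}" for i in range(eigval.size)]
    return OrdinationResult(
        eigenvalues=eigval,
        proportions=eigval / eigval.sum(),
        total_inertia=float(eigval.sum()),
        row_coords=pd.DataFrame(row, index=T.index, columns=axes),
        col_coords=pd.DataFrame(col, index=T.columns, columns=axes),
    )


def build_threat_by_label_table(
    threats: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Contingency table: species counts per (threat, area-or-habitat) cell.

    Cell (t, a) counts species carrying threat t AND label a; a species with
    several labels counts once per label.
    """
    common = threats.index.intersection(labels.index)
    if common.empty:
        raise ValueError("threat and label tables share no species")
    T = threats.loc[common].astype(int)
    L = labels.loc[common].astype(int)
    out = T.T @ L
    out.index.name = "threat"
    out.columns.name = labels.columns.name or "label"
    return out
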