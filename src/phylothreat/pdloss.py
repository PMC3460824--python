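"""Faith's PD, expected future PD under independent extinctions, and PDloss tests.

A branch of length :math:`L_b` is retained in the future tree iff at least
one tip descending from it survives. With independent per-species extinction
probabilities :math:`p_i`,

.. math:: \\mathrm{expPD} = \\sum_b L_b\\,\\bigl(1 - \\prod_{i \\prec b} p_i\\bigr),

and the relative expected loss is ``PDloss = (PD − expPD)/PD``.

The permutation test shuffles the extinction-probability vector across all
tips of the full tree and recomputes PDloss per clade on each clade's
subtree, asking whether a clade loses more (+) or less (−) diversity than
expected were risk independent of phylogeny.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .permutation import PermutationTestResult, permutation_p
from .treeio import Phylogeny

__all__ = [
    "PDLossResult",
    "faith_pd",
    "expected_pd",
    "pd_loss",
    "pdloss_permutation_test",
]

# log(p)=LOG_ZERO stands in for p=0: exp of any branch sum underflows to 0.0
_LOG_ZERO = -1e8


@dataclass(frozen=True)
class PDLossResult:
    pd: float
    exp_pd: float
    pd_loss: float


def faith_pd(tree: Phylogeny) -> float:
    """Total branch length of the tree (My); the stem convention is treeio's."""
    return tree.total_branch_length


def _aligned_probabilities(tree: Phylogeny, p_ext) -> np.ndarray:
    p = pd.Series(p_ext)
    missing = [t for t in tree.tip_labels if t not in p.index]
    if missing:
        raise ValueError(f"extinction probability missing for species: {missing[:10]}")
    vec = p.reindex(list(tree.tip_labels)).astype(float).values
    if np.any((vec < 0) | (vec > 1)):
        raise ValueError("extinction probabilities must lie in [0,1]")
    return vec


def _log_p(vec: np.ndarray) -> np.ndarray:
    out = np.full(vec.shape, _LOG_ZERO)
    pos = vec > 0
    out[pos] = np.log(vec[pos])
    return out


def _expected_loss(lengths: np.ndarray, incidence: np.ndarray, logp: np.ndarray) -> float:
    """Sum over branches of L_b times the probability all tips below go extinct."""
    return float(np.exp(incidence.astype(float) @ logp) @ lengths)


def expected_pd(tree: Phylogeny, p_ext) -> float:
    """Expected future PD (My) under independent per-species extinctions."""
    bs = tree.branch_structure()
    vec = _aligned_probabilities(tree, p_ext)
    return faith_pd(tree) - _expected_loss(bs.lengths, bs.incidence, _log_p(vec))


def pd_loss(tree: Phylogeny, p_ext) -> PDLossResult:
    """PD, expPD and the relative expected loss PDloss = (PD − expPD)/PD."""
    pd_total = faith_pd(tree)
    if pd_total <= 0:
        raise ValueError("PDloss undefined: total branch length is zero")
    exp_pd = expected_pd(tree, p_ext)
    return PDLossResult(pd=pd_total, exp_pd=exp_pd, pd_loss=(pd_total - exp_pd) / pd_total)


def pdloss_permutation_test(
    tree: Phylogeny,
    p_ext,
    clades: dict[str, set[str]] | None = None,
    *,
    n_perm: int = 200,
    seed: int | None = None,
    scope: str = "global",
    tail: str = "two-sided",
) -> dict[str, PermutationTestResult]:
    """Permutation test of PDloss for the whole tree and/or named clades.

    Extinction probabilities are shuffled across **all** tips of the full
    tree (``scope="global"``, the default); each permutation's PDloss is then
    recomputed for every requested clade on that clade's stem-excluded
    subtree. ``scope="within_clade"`` instead shuffles independently inside
    each clade. Results are keyed by clade name, with ``"whole_tree"`` always
    included.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scope not in ("global", "within_clade"):
        raise ValueError(f"unknown scope {scope!r}")
    bs = tree.branch_structure()
    labels = list(tree.tip_labels)
    vec = _aligned_probabilities(tree, p_ext)
    col = {t: i for i, t in enumerate(labels)}

    # per-group: (tip column indices, branch lengths, restricted incidence, PD)
    groups: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, float]] = {}
    whole_cols = np.arange(len(labels))
    groups["whole_tree"] = (whole_cols, bs.lengths, bs.incidence, float(bs.lengths.sum()))
    for name, members in (clades or {}).items():
        if len(members) < 2:
            warnings.warn(f"clade {name!r} has fewer than 2 tips; test still run")
            # stem-excluded subtree of a single tip is empty; fall back to the
            # pendant branch so the statistic (the species' own p) is defined
            (tip,) = members
            cols = np.array([col[tip]])
            groups[name] = (cols, np.ones(1), np.ones((1, 1), dtype=bool), 1.0)
            continue
        sub = tree.clade_subtree(members)
        sb = sub.branch_structure()
        cols = np.array([col[t] for t in sub.tip_labels])
        groups[name] = (cols, sb.lengths, sb.incidence, float(sb.lengths.sum()))

    rng = np.random.default_rng(seed)
    logp = _log_p(vec)
    perms = np.stack([rng.permutation(len(labels)) for _ in range(n_perm)])
    if scope == "within_clade":
        # independent shuffle of each clade's own probabilities (whole tree global)
        perms_by_group = {}
        for name, (cols, *_rest) in groups.items():
            local = np.stack([cols[rng.permutation(cols.size)] for _ in range(n_perm)])
            perms_by_group[name] = local

    results: dict[str, PermutationTestResult] = {}
    for name, (cols, lengths, incidence, pd_total) in groups.items():
        if pd_total <= 0:
            raise ValueError(f"group {name!r} has zero total branch length")
        A = incidence.astype(float)
        obs_loss = float(np.exp(A @ logp[cols]) @ lengths)
        obs = obs_loss / pd_total
        if scope == "global":
            perm_cols = perms[:, cols] if name != "whole_tree" else perms
            LogP = logp[perm_cols]  # (n_perm, n_group_tips)
        else:
            LogP = logp[perms_by_group[name]]
        null = (np.exp(LogP @ A.T) @ lengths) / pd_total
        results[name] = permutation_p(obs, null, tail=tail, seed=seed)
    return results


def pdloss_table(
    tree: Phylogeny,
    p_ext,
    clades: dict[str, set[str]] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Per-clade PDloss summary (clade, n_species, pd, exp_pd, pd_loss, p, direction)."""
    tests = pdloss_permutation_test(tree, p_ext, clades, **kwargs)
    rows = []
    for name, res in tests.items():
        members = (clades or {}).get(name)
        if name == "whole_tree":
            sub, n = tree, tree.n_tips
        else:
            sub, n = tree.clade_subtree(members), len(members)
        r = pd_loss(sub, pd.Series(p_ext))
        rows.append(
            {
                "clade": name,
                "n_species": n,
                "pd": r.pd,
                "exp_pd": r.exp_pd,
                "pd_loss": r.pd_loss,
                "p_value": res.p_value,
                "direction": res.direction,
            }
        )
    return pd.DataFrame(rows).set_index("clade")
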