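"""Rooted phylogenies: parsing, validation, patristic distances, clade extraction.

Trees are rooted, carry branch lengths in millions of years, and may contain
polytomies and zero-length branches. A clade's subtree excludes the stem
branch above its most recent common ancestor, so clade-level phylogenetic
diversity sums branch lengths strictly inside the clade.

dendropy provides the Newick grammar and the node/edge structure; this module
adds validation, a vectorized patristic matrix, and the branch-by-tip
incidence structure that the expected-diversity computations consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "TreeValidationError",
    "NewickParseError",
    "NonMonophyleticCladeError",
    "read_clade_map",
    "validate_clade_map",
]


class TreeValidationError(ValueError):
    """The tree violates a structural invariant (labels, lengths, rooting)."""


class NewickParseError(ValueError):
    """Malformed Newick input; carries the approximate character offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class NonMonophyleticCladeError(ValueError):
    """A requested tip set is not the complete descendant set of one node."""

    def __init__(self, message: str, extra_tips: tuple[str, ...] = ()):
        super().__init__(message)
        self.extra_tips = extra_tips


@dataclass
class _BranchStructure:
    """Per-branch lengths and the boolean tips-below-branch incidence."""

    lengths: np.ndarray          # (n_branches,)
    incidence: np.ndarray        # (n_branches, n_tips) bool
    tip_labels: tuple[str, ...]  # column order of ``incidence``


class Phylogeny:
    """A validated rooted phylogeny with branch lengths.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree``. Ownership passes to this object; the
        tree must not be mutated afterwards.
    impute_missing_lengths:
        If True, branches lacking a length are assigned 0 instead of being
        rejected.
    """

    def __init__(self, tree: dendropy.Tree, *, impute_missing_lengths: bool = False):
        self._tree = tree
        self._tree.is_rooted = True
        self._validate(impute_missing_lengths)
        self._branches: _BranchStructure | None = None

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str, *, impute_missing_lengths: bool = False) -> "Phylogeny":
        """Parse a Newick string into a validated phylogeny."""
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            if "Duplicate taxon labels" in str(exc):
                raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
            offset = getattr(exc, "col_num", None)
            raise NewickParseError(f"malformed Newick: {exc}", offset=offset) from exc
        return cls(tree, impute_missing_lengths=impute_missing_lengths)

    @classmethod
    def from_file(cls, path, **kwargs) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read(), **kwargs)

    def to_newick(self) -> str:
        """Canonical Newick with branch lengths to 10 significant digits."""
        out = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        )
        return out.strip() + ("" if out.strip().endswith(";") else ";")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------- basic queries

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._branch_structure().tip_labels

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def total_branch_length(self) -> float:
        """Sum of all branch lengths (root stem excluded)."""
        return float(self._branch_structure().lengths.sum())

    def branch_structure(self) -> _BranchStructure:
        """Branch lengths and the tips-below-branch incidence matrix."""
        return self._branch_structure()

    # -------------------------------------------------------- computations

    def patristic_matrix(self) -> pd.DataFrame:
        """Tip-to-tip path-length matrix (symmetric, zero diagonal)."""
        bs = self._branch_structure()
        A = bs.incidence.astype(float)
        L = bs.lengths
        # shared root-path length between i and j, then d = depth_i+depth_j-2*shared
        shared = A.T @ (L[:, None] * A)
        depth = np.diag(shared).copy()
        D = depth[:, None] + depth[None, :] - 2.0 * shared
        np.fill_diagonal(D, 0.0)
        D = np.maximum(D, 0.0)
        return pd.DataFrame(D, index=bs.tip_labels, columns=bs.tip_labels)

    def mrca(self, tips) -> dendropy.Node:
        tips = set(tips)
        missing = tips - set(self.tip_labels)
        if missing:
            raise TreeValidationError(f"tips not in tree: {sorted(missing)}")
        if len(tips) == self.n_tips:
            return self.root
        taxa = [t for t in self._tree.taxon_namespace if t.label in tips]
        node = self._tree.mrca(taxa=taxa)
        if node is None:
            raise TreeValidationError("could not locate MRCA")
        return node

    def clade_subtree(self, tips) -> "Phylogeny":
        """Rooted subtree below the MRCA of ``tips`` (stem branch excluded).

        Raises ``NonMonophyleticCladeError`` if ``tips`` is not the complete
        tip set of one node, naming the extra tips under the MRCA.
        """
        tips = set(tips)
        node = self.mrca(tips)
        below = {lf.taxon.label for lf in node.leaf_iter()}
        extra = below - tips
        if extra:
            raise NonMonophyleticCladeError(
                f"tip set is not monophyletic; MRCA also contains {sorted(extra)}",
                extra_tips=tuple(sorted(extra)),
            )
        return Phylogeny.from_newick(_node_newick(node) + ";")

    def prune_to(self, tips) -> "Phylogeny":
        """Tree restricted to an arbitrary tip subset (unifurcations collapsed).

        Unlike :meth:`clade_subtree`, the subset need not be monophyletic;
        path lengths among the retained tips are preserved.
        """
        tips = set(tips)
        missing = tips - set(self.tip_labels)
        if missing:
            raise TreeValidationError(f"tips not in tree: {sorted(missing)}")
        if not tips:
            raise TreeValidationError("cannot prune to an empty tip set")
        if tips == set(self.tip_labels):
            return self
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=tips, suppress_unifurcations=True
        )
        if sub.seed_node.edge.length:
            sub.seed_node.edge.length = None
        return Phylogeny(sub, impute_missing_lengths=True)

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        bs = self._branch_structure()
        depth = bs.incidence.astype(float).T @ bs.lengths
        return bool(np.ptp(depth) <= tol * max(1.0, float(depth.max())))

    # ----------------------------------------------------------- internals

    def _validate(self, impute_missing_lengths: bool) -> None:
        leaves = list(self._tree.leaf_node_iter())
        if not leaves:
            raise TreeValidationError("tree has no tips")
        labels = []
        for lf in leaves:
            label = lf.taxon.label if lf.taxon is not None else None
            if label is None or not str(label).strip():
                raise TreeValidationError("tip with empty or missing label")
            labels.append(str(label).strip())
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                if impute_missing_lengths:
                    node.edge.length = 0.0
                else:
                    raise TreeValidationError(
                        "branch without length (pass impute_missing_lengths=True to use 0)"
                    )
            if node.edge.length < 0:
                raise TreeValidationError(f"negative branch length {node.edge.length}")

    def _branch_structure(self) -> _BranchStructure:
        if self._branches is not None:
            return self._branches
        leaves = list(self._tree.leaf_node_iter())
        tip_labels = tuple(str(lf.taxon.label).strip() for lf in leaves)
        index = {lf: i for i, lf in enumerate(leaves)}
        n = len(leaves)
        lengths, rows = [], []
        # postorder: each node's tip set is the union of its children's
        below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(n, dtype=bool)
                mask[index[node]] = True
            else:
                mask = np.zeros(n, dtype=bool)
                for ch in node.child_nodes():
                    mask |= below[ch]
            below[node] = mask
            if node is not self._tree.seed_node:
                lengths.append(float(node.edge.length))
                rows.append(mask)
        self._branches = _BranchStructure(
            lengths=np.asarray(lengths, dtype=float),
            incidence=np.asarray(rows, dtype=bool),
            tip_labels=tip_labels,
        )
        return self._branches


def _node_newick(node: dendropy.Node) -> str:
    """Newick string of the subtree rooted at ``node`` (no stem length)."""
    if node.is_leaf():
        return _quote(node.taxon.label)
    parts = []
    for ch in node.child_nodes():
        sub = _node_newick(ch)
        parts.append(f"{sub}:{ch.edge.length:.10g}")
    return "(" + ",".join(parts) + ")"


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;[]' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# --------------------------------------------------------------- clade maps

def read_clade_map(path_or_buffer) -> dict[str, set[str]]:
    """Read a two-column CSV (clade,species) into a clade → tip-set map."""
    df = pd.read_csv(path_or_buffer)
    if df.shape[1] != 2:
        raise ValueError("clade map must have exactly two columns (clade,species)")
    df.columns = ["clade", "species"]
    out: dict[str, set[str]] = {}
    for clade, grp in df.groupby("clade", sort=True):
        out[str(clade)] = {str(s).strip() for s in grp["species"]}
    return out


def validate_clade_map(tree: Phylogeny, clades: dict[str, set[str]]) -> dict[str, set[str]]:
    """Check every clade is monophyletic in ``tree``; drop unknown species.

    Species listed in a clade but absent from the tree are dropped with a
    logged warning (mirroring the tables-vs-tree matching policy). Returns
    the cleaned map; raises for non-monophyletic clades.
    """
    tipset = set(tree.tip_labels)
    cleaned: dict[str, set[str]] = {}
    for name, members in clades.items():
        known = members & tipset
        dropped = members - tipset
        if dropped:
            logger.warning(
                "clade %s: %d species not in tree, dropped: %s",
                name, len(dropped), sorted(dropped)[:5],
            )
        if not known:
            logger.warning("clade %s has no members in the tree; skipped", name)
            continue
        tree.clade_subtree(known)  # raises NonMonophyleticCladeError if invalid
        cleaned[name] = known
    return cleaned


def write_clade_map(clades: dict[str, set[str]], path) -> None:
    rows = [(c, s) for c in sorted(clades) for s in sorted(clades[c])]
    pd.DataFrame(rows, columns=["clade", "species"]).to_csv(path, index=False)
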