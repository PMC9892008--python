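"""Per-SGB phylogenies and normalized phylogenetic distances (nGD).

The strain-identity signal is the leaf-to-leaf patristic distance in a
per-species tree, normalized by the total branch length of that tree (nGD).
Because any leaf-to-leaf path is a subset of the tree's branches, nGD is
bounded in [0, 1] and comparable across species with very different overall
diversity. Centred nGD additionally divides by the median off-diagonal nGD of
the same tree, putting the bulk of unrelated-strain distances at ~1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class NewickError(ValueError):
    """Malformed or unusable Newick input."""


@dataclass
class TreeData:
    """A parsed phylogeny with its leaf labels and total branch length."""

    tree: dendropy.Tree
    leaves: list[str]
    total_branch_length: float

    @property
    def degenerate(self) -> bool:
        """True when the tree carries no branch length at all."""
        return self.total_branch_length == 0.0


@dataclass
class SGBDistanceSet:
    """Symmetric nGD matrix for one SGB over an ordered leaf set.

    ``snv_rate`` is an optional long-format table (``id_a``, ``id_b``,
    ``snv_rate``) covering sample/food-reference pairs; it is only consumed
    by the food-origin strain filter.
    """

    sgb_id: str
    leaves: list[str]
    ngd: np.ndarray
    total_branch_length: float
    alignment_length: int | None = None
    snv_rate: pd.DataFrame | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ngd = np.asarray(self.ngd, dtype=float)
        n = len(self.leaves)
        if self.ngd.shape != (n, n):
            raise ValueError(
                f"{self.sgb_id}: ngd shape {self.ngd.shape} != ({n}, {n})"
            )
        self._index = {leaf: i for i, leaf in enumerate(self.leaves)}

    def distance(self, a: str, b: str) -> float:
        return float(self.ngd[self._index[a], self._index[b]])

    def pair_distances(self, pairs) -> np.ndarray:
        """nGD values for an iterable of (leaf, leaf) pairs."""
        idx = self._index
        return np.array([self.ngd[idx[a], idx[b]] for a, b in pairs], dtype=float)

    def to_long(self, centred: bool = True) -> pd.DataFrame:
        """Long-format table of all unordered leaf pairs."""
        iu = np.triu_indices(len(self.leaves), k=1)
        out = pd.DataFrame(
            {
                "sample_a": [self.leaves[i] for i in iu[0]],
                "sample_b": [self.leaves[j] for j in iu[1]],
                "ngd": self.ngd[iu],
            }
        )
        if centred:
            out["centred_ngd"] = centred_ngd(self.ngd)[iu]
        return out


def read_newick(path) -> TreeData:
    """Parse a Newick file into a :class:`TreeData`.

    Rejects duplicate leaf labels and negative branch lengths; a degenerate
    tree (total branch length 0) parses but is flagged via
    :attr:`TreeData.degenerate` and logged.
    """
    path = Path(path)
    text = path.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        offset = _error_offset(text, exc)
        raise NewickError(
            f"{path}: malformed Newick near byte offset {offset}: {exc}"
        ) from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickError(f"{path}: duplicate leaf labels: {dup[:5]}")
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        if edge.length < 0:
            raise NewickError(f"{path}: negative branch length {edge.length}")
        total += edge.length
    if total == 0.0:
        logger.warning("%s: degenerate tree (total branch length 0)", path)
    return TreeData(tree=tree, leaves=labels, total_branch_length=total)


def _error_offset(text: str, exc: Exception) -> int:
    line = getattr(exc, "line_num", None)
    col = getattr(exc, "col_num", None)
    if line is None or col is None:
        return 0
    lines = text.splitlines(keepends=True)
    return sum(len(l) for l in lines[: max(line - 1, 0)]) + max(col - 1, 0)


def patristic_matrix(tree_data: TreeData) -> np.ndarray:
    """Leaf-to-leaf path-length sums, in :attr:`TreeData.leaves` order."""
    leaves = tree_data.leaves
    if len(leaves) < 2:
        raise ValueError("patristic_matrix requires at least 2 leaves")
    pdm = tree_data.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree_data.tree.taxon_namespace}
    n = len(leaves)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        ti = taxa[leaves[i]]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(ti, taxa[leaves[j]])
            mat[i, j] = mat[j, i] = d
    return mat


def normalize_ngd(patristic: np.ndarray, total_branch_length: float) -> np.ndarray:
    """Divide patristic distances by the total branch length of the tree."""
    if total_branch_length <= 0:
        raise ValueError(
            f"total branch length must be positive, got {total_branch_length}"
        )
    return np.asarray(patristic, dtype=float) / float(total_branch_length)


def centred_ngd(ngd: np.ndarray) -> np.ndarray:
    """Divide off-diagonal nGD values by their median (diagonal stays 0)."""
    ngd = np.asarray(ngd, dtype=float)
    n = ngd.shape[0]
    if n < 2:
        raise ValueError("centred nGD requires at least 2 leaves")
    iu = np.triu_indices(n, k=1)
    med = float(np.median(ngd[iu]))
    if med == 0:
        raise ValueError("median off-diagonal nGD is 0 (degenerate tree)")
    out = ngd / med
    np.fill_diagonal(out, 0.0)
    return out


def ngd_from_tree(path, sgb_id: str | None = None) -> SGBDistanceSet:
    """Read a Newick file and assemble its nGD matrix.

    Degenerate trees (zero total branch length) are rejected: nGD would be
    0/0 for every pair.
    """
    path = Path(path)
    td = read_newick(path)
    if td.degenerate:
        raise NewickError(f"{path}: zero total branch length, nGD undefined")
    mat = patristic_matrix(td)
    ngd = normalize_ngd(mat, td.total_branch_length)
    return SGBDistanceSet(
        sgb_id=sgb_id if sgb_id is not None else path.stem,
        leaves=td.leaves,
        ngd=ngd,
        total_branch_length=td.total_branch_length,
    )


def scan_tree_directory(directory) -> dict[str, Path]:
    """Map SGB id -> Newick path for all ``<sgb_id>.nwk`` files in a directory."""
    directory = Path(directory)
    return {p.stem: p for p in sorted(directory.glob("*.nwk"))}
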