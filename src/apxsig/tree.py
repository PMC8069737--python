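"""Distance-tree surrogate for family-level clustering checks.

Builds a p-distance matrix from all-pairs global alignments, runs
neighbor joining, and asks whether the residue-signature families come
out as coherent clades.  This is deliberately a desk-scale surrogate:
p-distances and NJ only need to capture rank-order structure, not
evolutionary rates.
"""

from __future__ import annotations

import io as _io
import re

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .alignment import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, PairwiseAlignment, _make_aligner
from .records import ProteinRecord


def align_pair(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Global alignment of two arbitrary sequences (same scoring as the
    reference alignment)."""
    aligner = _make_aligner(gap_open, gap_extend)
    best = aligner.align(a, b)[0]
    return PairwiseAlignment(
        aligned_query=str(best[0]),
        aligned_reference=str(best[1]),
        score=float(best.score),
    )


def p_distance(alignment: PairwiseAlignment) -> float:
    """Fraction of mismatched aligned columns, gap columns excluded.

    Pairs sharing no gap-free column get distance 1.0.
    """
    shared = mismatch = 0
    for q, r in zip(alignment.aligned_query, alignment.aligned_reference):
        if q != "-" and r != "-":
            shared += 1
            if q != r:
                mismatch += 1
    return mismatch / shared if shared else 1.0


def sanitize_leaf_name(seq_id: str) -> str:
    return re.sub(r"\s+", "_", seq_id.strip())


def pairwise_distance_matrix(
    records: list[ProteinRecord],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> DistanceMatrix:
    """All-pairs p-distance matrix (requires at least 3 records)."""
    if len(records) < 3:
        raise ValueError(f"need at least 3 records, got {len(records)}")
    ids = [sanitize_leaf_name(rec.seq_id) for rec in records]
    n = len(records)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(
                align_pair(records[i].sequence, records[j].sequence, gap_open, gap_extend)
            )
            matrix[i, j] = matrix[j, i] = d
    return DistanceMatrix(matrix, ids)


def neighbor_joining(matrix: DistanceMatrix | tuple) -> str:
    """Neighbor-joining tree as newick text.

    Accepts a :class:`skbio.DistanceMatrix` or an ``(ids, ndarray)``
    pair; a non-symmetric matrix is an error.  Negative branch lengths
    are clamped to zero.
    """
    if not isinstance(matrix, DistanceMatrix):
        ids, data = matrix
        data = np.asarray(data, dtype=float)
        if not np.array_equal(data, data.T):
            raise ValueError("distance matrix is not symmetric")
        matrix = DistanceMatrix(data, list(ids))
    if len(matrix.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = nj(matrix, neg_as_zero=True)
    buffer = _io.StringIO()
    tree.write(buffer)
    return buffer.getvalue().strip()


def _parse_tree(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


def monophyly(newick: str, labels: dict[str, str]) -> dict[str, float]:
    """Per-label clade test on an unrooted tree.

    *labels* maps leaf name -> label.  A label scores 1.0 when its
    leaves form a clade of the unrooted tree — i.e. some edge splits
    exactly that leaf set from the rest — else 0.0.  Leaves named in
    *labels* but missing from the tree are an error.
    """
    tree = _parse_tree(newick)
    tip_names = {tip.name for tip in tree.tips()}
    missing = sorted(set(labels) - tip_names)
    if missing:
        raise ValueError(f"leaves absent from tree: {missing}")

    subtree_sets = []
    for node in tree.postorder():
        if node.is_tip():
            node._leafset = frozenset([node.name])
        else:
            node._leafset = frozenset().union(*(c._leafset for c in node.children))
        subtree_sets.append(node._leafset)

    result: dict[str, float] = {}
    for label in sorted(set(labels.values())):
        group = frozenset(k for k, v in labels.items() if v == label)
        complement = frozenset(tip_names) - group
        monophyletic = (
            len(group) <= 1
            or group in subtree_sets
            or complement in subtree_sets
        )
        result[label] = 1.0 if monophyletic else 0.0
    return result


def nontrivial_splits(newick: str) -> set[frozenset]:
    """Nontrivial bipartitions of an unrooted tree.

    Each split is canonicalized as the side that does not contain the
    lexicographically smallest leaf, so the representation is invariant
    to rooting.
    """
    tree = _parse_tree(newick)
    tips = sorted(tip.name for tip in tree.tips())
    anchor, n = tips[0], len(tips)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(tip.name for tip in node.tips())
        if len(side) <= 1 or len(side) >= n - 1:
            continue
        if anchor in side:
            side = frozenset(tips) - side
        if 1 < len(side) < n - 1:
            splits.add(side)
    return splits


def monophyly_rate(newick: str, truth) -> dict[str, float]:
    """Clade test keyed by true labels.

    *truth* is a list of objects with ``seq_id`` and ``true_label``
    attributes (or a mapping seq_id -> label).
    """
    if isinstance(truth, dict):
        labels = {sanitize_leaf_name(k): v for k, v in truth.items()}
    else:
        labels = {sanitize_leaf_name(t.seq_id): t.true_label for t in truth}
    return monophyly(newick, labels)
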