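"""Brute-force reference routines for validation.

Everything here is deliberately naive and independent of the package's
production code paths: full enumeration of gapped alignments, the
decision table re-derived tuple by tuple with every matching family
recorded, and least-squares topology fitting over all fifteen unrooted
five-leaf trees.  The test suite and the acceptance script use these as
ground truth; nothing in the pipeline itself calls them.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

ABSENT = "-"


# ---------------------------------------------------------------------------
# Alignment: exhaustive enumeration of all global alignments.

def enumerate_global_score(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix=None,
) -> float:
    """Optimum global alignment score by enumerating every alignment.

    Affine gaps: a run of k consecutive gap columns in one row costs
    ``gap_open + (k-1) * gap_extend``.  Exponential in the input sizes;
    intended for sequences of length <= 8.
    """
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    best = [-np.inf]

    def walk(i: int, j: int, last: str, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):  # gap in b
            cost = gap_extend if last == "D" else gap_open
            walk(i + 1, j, "D", score - cost)
        if j < len(b):  # gap in a
            cost = gap_extend if last == "I" else gap_open
            walk(i, j + 1, "I", score - cost)

    walk(0, 0, "", 0.0)
    return float(best[0])


# ---------------------------------------------------------------------------
# Decision table: every family predicate evaluated per tuple.

def matching_families(sig: tuple[str, str, str, str, str]) -> list[str]:
    """All family predicates satisfied by a (38,41,42,163,172) tuple.

    Deleted positions (``-``) count as "other" residues, except that a
    deleted catalytic position (38/41/42/163) disqualifies APX-R.
    """
    p38, p41, p42, p163, p172 = sig
    found = []
    if (p38, p41, p42, p163, p172) == ("R", "W", "H", "H", "R"):
        found.append("APX")
    if p38 == "R" and p41 == "F" and p42 == "H" and p163 == "H" and p172 != "R":
        found.append("APX-R")
    if (
        p38 != "R"
        and p41 != "W"
        and p41 != "F"
        and p42 != "H"
        and p163 != "H"
        and p172 != "R"
    ):
        found.append("APX-L")
    return found


def sweep_decision_table(alphabet: tuple[str, ...]) -> dict:
    """Evaluate every tuple over *alphabet* at the five positions.

    Returns counts of tuples matching 0/1/>1 family predicates and the
    per-tuple expected label (single match, or hybrid for no match).
    """
    expected: dict[tuple, str] = {}
    n_conflicts = 0
    for sig in itertools.product(alphabet, repeat=5):
        matches = matching_families(sig)
        if len(matches) > 1:
            n_conflicts += 1
            expected[sig] = "CONFLICT"
        else:
            expected[sig] = matches[0] if matches else "hybrid"
    return {"expected": expected, "n_conflicts": n_conflicts, "n": len(expected)}


# ---------------------------------------------------------------------------
# Trees: closed-form 3-taxon branch lengths and exhaustive 5-taxon
# least-squares topology fitting.

def three_taxon_branch_lengths(dab: float, dac: float, dbc: float) -> tuple[float, float, float]:
    """Branch lengths of the unique unrooted 3-leaf star (a, b, c)."""
    return (
        (dab + dac - dbc) / 2.0,
        (dab + dbc - dac) / 2.0,
        (dac + dbc - dab) / 2.0,
    )


def five_taxon_topologies(taxa: tuple[str, ...]) -> list[frozenset]:
    """All 15 unrooted binary 5-leaf topologies.

    Each topology is identified by its two cherries, returned as a
    frozenset of two disjoint 2-leaf frozensets.
    """
    assert len(taxa) == 5
    seen = set()
    for pair1 in itertools.combinations(taxa, 2):
        rest = [t for t in taxa if t not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            seen.add(frozenset([frozenset(pair1), frozenset(pair2)]))
    return sorted(seen, key=lambda t: sorted(sorted(p) for p in t))


def topology_distances(
    topology: frozenset, lengths: dict, taxa: tuple[str, ...]
) -> np.ndarray:
    """Additive pairwise distances for a cherry-pair topology.

    *lengths* maps each taxon to its pendant length, the middle taxon
    included, plus keys ``i1``/``i2`` for the two internal edges
    (cherry-to-center, in the sorted order of the cherries).
    """
    cherry1, cherry2 = sorted(topology, key=lambda p: sorted(p))
    middle = next(t for t in taxa if t not in cherry1 | cherry2)

    def internal(t: str) -> float:
        # path length from taxon's attachment node to the center node
        if t in cherry1:
            return lengths["i1"]
        if t in cherry2:
            return lengths["i2"]
        return 0.0

    n = len(taxa)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ti, tj = taxa[i], taxa[j]
        same_cherry = any(ti in ch and tj in ch for ch in (cherry1, cherry2))
        d = lengths[ti] + lengths[tj]
        if not same_cherry:
            d += internal(ti) + internal(tj)
        out[i, j] = out[j, i] = d
    return out


def least_squares_topology(
    distances: np.ndarray, taxa: tuple[str, ...]
) -> tuple[frozenset, float]:
    """Best-fit topology by ordinary least squares over all 15 trees.

    Returns (topology, residual sum of squares).  The design matrix has
    one row per taxon pair and one column per branch (five pendant, two
    internal).
    """
    pairs = list(itertools.combinations(range(5), 2))
    y = np.array([distances[i, j] for i, j in pairs])
    best = (None, np.inf)
    for topology in five_taxon_topologies(taxa):
        cherry1, cherry2 = sorted(topology, key=lambda p: sorted(p))
        columns = list(taxa) + ["i1", "i2"]
        design = np.zeros((len(pairs), len(columns)))
        for row, (i, j) in enumerate(pairs):
            ti, tj = taxa[i], taxa[j]
            design[row, i] = design[row, j] = 1.0
            same_cherry = any(ti in ch and tj in ch for ch in (cherry1, cherry2))
            if not same_cherry:
                for t, col_t in ((ti, i), (tj, j)):
                    if t in cherry1:
                        design[row, columns.index("i1")] += 1.0
                    elif t in cherry2:
                        design[row, columns.index("i2")] += 1.0
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((design @ coef - y) ** 2))
        if rss < best[1] - 1e-12:
            best = (topology, rss)
    return best
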