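"""Reference-anchored position mapping through pairwise global alignment.

Each query is aligned to the reference with a Gotoh affine-gap global
alignment under BLOSUM62 (defaults: gap open 10, gap extend 0.5; a gap
of length k costs ``open + (k-1)*extend``).  Signature positions are
then read off through the gapped columns: the query letter aligned to
reference position p becomes the profile entry for p, a gap becomes
``ABSENT`` and an ``X`` becomes ``AMBIGUOUS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from Bio.Align import PairwiseAligner, substitution_matrices

from .records import validate_sequence
from .reference import ReferenceScheme, SIGNATURE_POSITIONS

#: Sentinel for a signature position aligned to a gap (deleted in the query).
ABSENT = "-"
#: Sentinel for a signature position occupied by an ambiguous residue.
AMBIGUOUS = "X"

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

#: Queries covering fewer than this fraction of reference positions are
#: flagged; downstream classification returns ``ambiguous`` for them so
#: that fragments cannot masquerade as signature-less APX-L.
MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of one query against the reference."""

    aligned_query: str
    aligned_reference: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_reference):
            raise ValueError("aligned rows differ in length")
        for q, r in zip(self.aligned_query, self.aligned_reference):
            if q == "-" and r == "-":
                raise ValueError("alignment column gapped in both rows")

    @property
    def column_of_reference_position(self) -> dict[int, int]:
        """1-based reference position -> 1-based alignment column.

        Strictly increasing in reference position by construction.
        """
        mapping: dict[int, int] = {}
        pos = 0
        for col, letter in enumerate(self.aligned_reference, start=1):
            if letter != "-":
                pos += 1
                mapping[pos] = col
        return mapping

    def ungapped_query(self) -> str:
        return self.aligned_query.replace("-", "")

    def ungapped_reference(self) -> str:
        return self.aligned_reference.replace("-", "")


@dataclass(frozen=True)
class SignatureProfile:
    """Residues found at the seven reference signature positions.

    ``residue_at`` maps each position in {30, 32, 38, 41, 42, 163, 172}
    to a one-letter amino acid, :data:`ABSENT` or :data:`AMBIGUOUS`.
    """

    seq_id: str
    residue_at: dict[int, str]
    coverage_fraction: float

    def __post_init__(self) -> None:
        if tuple(sorted(self.residue_at)) != tuple(sorted(SIGNATURE_POSITIONS)):
            raise ValueError(
                f"profile must cover exactly positions {SIGNATURE_POSITIONS}, "
                f"got {tuple(sorted(self.residue_at))}"
            )

    @property
    def low_coverage(self) -> bool:
        return self.coverage_fraction < MIN_COVERAGE

    def classification_tuple(self) -> tuple[str, str, str, str, str]:
        """Residues at (38, 41, 42, 163, 172)."""
        return tuple(self.residue_at[p] for p in (38, 41, 42, 163, 172))


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    query: str,
    scheme: ReferenceScheme,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment of *query* against the scheme reference.

    Deterministic: the first traceback of the dynamic-programming
    optimum is returned; the score equals the DP optimum.  Raises on an
    empty or invalid query.
    """
    validate_sequence(query, "<query>")
    aligner = _make_aligner(gap_open, gap_extend)
    best = aligner.align(query, scheme.reference_sequence)[0]
    return PairwiseAlignment(
        aligned_query=str(best[0]),
        aligned_reference=str(best[1]),
        score=float(best.score),
    )


def map_positions(
    alignment: PairwiseAlignment,
    scheme: ReferenceScheme,
    seq_id: str = "<query>",
) -> SignatureProfile:
    """Extract the signature profile from a gapped alignment.

    For each signature position the query letter in that reference
    column is recorded (gap -> ABSENT, X -> AMBIGUOUS).  The coverage
    fraction counts reference positions aligned to non-gap query
    residues, over the whole reference.
    """
    if alignment.ungapped_reference() != scheme.reference_sequence:
        raise ValueError("alignment was not produced against this reference")
    columns = alignment.column_of_reference_position
    residue_at: dict[int, str] = {}
    for pos in scheme.all_positions:
        letter = alignment.aligned_query[columns[pos] - 1]
        if letter == "-":
            residue_at[pos] = ABSENT
        elif letter == "X":
            residue_at[pos] = AMBIGUOUS
        else:
            residue_at[pos] = letter
    n_ref = len(scheme.reference_sequence)
    covered = sum(
        1
        for pos in range(1, n_ref + 1)
        if alignment.aligned_query[columns[pos] - 1] != "-"
    )
    return SignatureProfile(
        seq_id=seq_id,
        residue_at=residue_at,
        coverage_fraction=covered / n_ref,
    )


def profile_sequence(
    query: str,
    scheme: ReferenceScheme,
    seq_id: str = "<query>",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> SignatureProfile:
    """Convenience: align then map in one call."""
    alignment = global_align(query, scheme, gap_open, gap_extend)
    return map_positions(alignment, scheme, seq_id)


def load_aligned_pair(path: str | Path, scheme: ReferenceScheme) -> PairwiseAlignment:
    """Import an externally computed two-row aligned FASTA (query first,
    reference second).  The reference row, once degapped, must equal the
    scheme's reference sequence.  The stored score is NaN (unknown)."""
    from Bio import SeqIO

    rows = list(SeqIO.parse(str(path), "fasta"))
    if len(rows) != 2:
        raise ValueError(
            f"aligned FASTA {path} must have exactly two rows, found {len(rows)}"
        )
    alignment = PairwiseAlignment(
        aligned_query=str(rows[0].seq).upper(),
        aligned_reference=str(rows[1].seq).upper(),
        score=math.nan,
    )
    if alignment.ungapped_reference() != scheme.reference_sequence:
        raise ValueError(
            f"second row of {path} does not degap to the reference sequence"
        )
    return alignment
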