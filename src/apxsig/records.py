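"""Core record types: curated protein sequences and curation settings.

A :class:`ProteinRecord` is the unit every pipeline stage consumes: one
amino-acid sequence plus species/taxon metadata.  Sequences are stored
ungapped over the 20 standard one-letter codes plus ``X`` (ambiguous
residue, common in transcriptome-derived proteins).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_LETTERS = frozenset(AMINO_ACIDS + "X")

#: Taxonomic groups used for prevalence reporting, in fixed display order.
TAXON_GROUPS = (
    "rhodophytes",
    "chlorophytes",
    "charophytes",
    "bryophytes",
    "gymnosperms",
    "angiosperms",
    "other",
)


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the amino-acid alphabet."""


def validate_sequence(sequence: str, seq_id: str = "<unnamed>") -> None:
    """Raise :class:`SequenceAlphabetError` unless *sequence* is a non-empty
    string over the 20 amino-acid letters plus X (no gap characters)."""
    if not sequence:
        raise SequenceAlphabetError(f"empty sequence for record {seq_id!r}")
    for pos, letter in enumerate(sequence, start=1):
        if letter not in VALID_LETTERS:
            raise SequenceAlphabetError(
                f"illegal character {letter!r} at position {pos} "
                f"of record {seq_id!r}"
            )


@dataclass
class ProteinRecord:
    """One curated protein sequence with species/taxon metadata.

    Parameters
    ----------
    seq_id :
        Unique identifier (first whitespace-delimited token of the FASTA
        header).
    sequence :
        Ungapped amino-acid sequence; uppercase letters plus ``X``.
    species :
        Binomial species name, empty until taxonomy is joined.
    taxon_group :
        One of :data:`TAXON_GROUPS`; defaults to ``"other"``.
    source :
        Free-text provenance (the remainder of the FASTA header, or a
        generator tag for simulated records).
    """

    seq_id: str
    sequence: str
    species: str = ""
    taxon_group: str = "other"
    source: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        validate_sequence(self.sequence, self.seq_id)
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(
                f"unknown taxon_group {self.taxon_group!r} for {self.seq_id!r}; "
                f"expected one of {TAXON_GROUPS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_taxonomy(self, species: str, taxon_group: str) -> "ProteinRecord":
        return replace(self, species=species, taxon_group=taxon_group)


@dataclass(frozen=True)
class CurationConfig:
    """Settings for redundancy removal and the incomplete-sequence filter.

    ``min_length_fraction`` is the fraction of the reference length below
    which a sequence is regarded as an incomplete fragment and discarded
    (default 0.5, strict inequality).  Redundancy is resolved within
    groups sharing ``redundancy_scope`` (the species by default), always
    keeping the longest sequence.
    """

    min_length_fraction: float = 0.5
    redundancy_scope: str = "species"
    keep_rule: str = "longest"

    def __post_init__(self) -> None:
        if not (0 < self.min_length_fraction <= 1):
            raise ValueError(
                "min_length_fraction must be in (0, 1], got "
                f"{self.min_length_fraction}"
            )
        if self.redundancy_scope not in ("species", "none"):
            raise ValueError(
                f"unsupported redundancy_scope {self.redundancy_scope!r}"
            )
        if self.keep_rule != "longest":
            raise ValueError("keep_rule is fixed to 'longest'")


def check_unique_ids(records: list[ProteinRecord]) -> None:
    """Raise ``ValueError`` if any seq_id occurs more than once."""
    seen: set[str] = set()
    for rec in records:
        if rec.seq_id in seen:
            raise ValueError(f"duplicate seq_id {rec.seq_id!r} in dataset")
        seen.add(rec.seq_id)
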