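"""Redundancy removal and the incomplete-fragment filter.

Mirrors the curation applied to public-database retrievals: within each
species, sequences identical to (or exact substrings of) a longer
sequence are redundant and dropped, keeping only the longest; sequences
shorter than half the reference length are regarded as incomplete and
discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict

from .records import CurationConfig, ProteinRecord

logger = logging.getLogger("apxsig")


def _redundancy_key(record: ProteinRecord, config: CurationConfig) -> str:
    return record.species if config.redundancy_scope == "species" else ""


def deduplicate(
    records: list[ProteinRecord], config: CurationConfig | None = None
) -> list[ProteinRecord]:
    """Drop sequences contained in a longer same-species sequence.

    A record is redundant when its sequence is identical to, or an exact
    substring of, another sequence in its redundancy group (same species
    by default).  Among exact duplicates the lexicographically smallest
    seq_id survives.  Output preserves input order of survivors;
    applying the operation twice equals applying it once.
    """
    config = config or CurationConfig()
    groups: dict[str, list[ProteinRecord]] = defaultdict(list)
    for rec in records:
        groups[_redundancy_key(rec, config)].append(rec)

    removed: dict[str, str] = {}  # removed seq_id -> kept seq_id
    for group in groups.values():
        # Longest first; among equal-length duplicates the smallest
        # seq_id sorts first and therefore absorbs the others.
        ranked = sorted(group, key=lambda r: (-len(r.sequence), r.seq_id))
        kept: list[ProteinRecord] = []
        for rec in ranked:
            absorber = next(
                (k for k in kept if rec.sequence in k.sequence), None
            )
            if absorber is not None:
                removed[rec.seq_id] = absorber.seq_id
                logger.info("DEDUP %s kept=%s", rec.seq_id, absorber.seq_id)
            else:
                kept.append(rec)
    return [rec for rec in records if rec.seq_id not in removed]


def length_filter(
    records: list[ProteinRecord],
    reference_length: int,
    config: CurationConfig | None = None,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (kept, discarded) by the fragment rule.

    A record is discarded iff ``len < min_length_fraction * reference_length``
    (strict inequality, so a sequence of exactly half the reference
    length is kept under the default 0.5).
    """
    if reference_length <= 0:
        raise ValueError(f"reference_length must be positive, got {reference_length}")
    config = config or CurationConfig()
    threshold = config.min_length_fraction * reference_length
    kept: list[ProteinRecord] = []
    discarded: list[ProteinRecord] = []
    for rec in records:
        if len(rec.sequence) < threshold:
            logger.info(
                "DISCARD %s length=%d threshold=%g", rec.seq_id, len(rec.sequence), threshold
            )
            discarded.append(rec)
        else:
            kept.append(rec)
    return kept, discarded


def curate(
    records: list[ProteinRecord],
    reference_length: int,
    config: CurationConfig | None = None,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Deduplicate then length-filter; returns survivors and a count report."""
    config = config or CurationConfig()
    n_in = len(records)
    unique = deduplicate(records, config)
    kept, discarded = length_filter(unique, reference_length, config)
    report = {
        "input": n_in,
        "redundant_removed": n_in - len(unique),
        "incomplete_discarded": len(discarded),
        "output": len(kept),
    }
    return kept, report
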