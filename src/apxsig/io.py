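"""FASTA and TSV input/output.

FASTA parsing/writing goes through Bio.SeqIO; sequences are validated
against the amino-acid alphabet on read (gaps are rejected — records are
stored ungapped, alignment happens downstream).  Taxonomy tables are
plain TSV with columns ``seq_id``, ``species``, ``taxon_group``.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ProteinRecord, SequenceAlphabetError, check_unique_ids

logger = logging.getLogger("apxsig")

TAXONOMY_COLUMNS = ["seq_id", "species", "taxon_group"]


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. an entry with no sequence lines)."""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The first whitespace-delimited token of each header becomes
    ``seq_id``; the remainder of the header is kept in ``source``.
    Taxonomy fields are left unset until :func:`join_taxonomy` is
    applied.

    Raises
    ------
    FastaParseError
        If an entry has no sequence lines.
    SequenceAlphabetError
        If a sequence contains a character outside the amino-acid
        alphabet (gap characters included).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        sequence = str(entry.seq)
        if not sequence:
            raise FastaParseError(
                f"FASTA entry {entry.id!r} in {path} has no sequence lines"
            )
        descr = entry.description
        source = descr[len(entry.id):].strip() if descr.startswith(entry.id) else descr
        records.append(ProteinRecord(seq_id=entry.id, sequence=sequence, source=source))
    check_unique_ids(records)
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, wrapping sequence lines at 60 columns."""
    entries = []
    for rec in records:
        entry = SeqRecord(Seq(rec.sequence), id=rec.seq_id, description=rec.source)
        entries.append(entry)
    with open(path, "w") as handle:
        SeqIO.write(entries, handle, "fasta")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV (columns seq_id, species, taxon_group).

    Raises ``ValueError`` on missing columns or duplicated seq_id rows.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, quoting=csv.QUOTE_NONE)
    missing = [c for c in TAXONOMY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"taxonomy table {path} lacks columns: {missing}")
    dupes = table["seq_id"][table["seq_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"taxonomy table {path} has duplicate seq_id rows: {dupes}")
    return table[TAXONOMY_COLUMNS]


def write_taxonomy(records: list[ProteinRecord], path: str | Path) -> None:
    table = pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in records],
            "species": [r.species for r in records],
            "taxon_group": [r.taxon_group for r in records],
        }
    )
    table.to_csv(path, sep="\t", index=False)


def join_taxonomy(
    records: list[ProteinRecord], table: str | Path | pd.DataFrame
) -> list[ProteinRecord]:
    """Fill species/taxon_group from a taxonomy table.

    Records absent from the table keep ``taxon_group="other"`` and a
    warning is logged.  Duplicate seq_id rows in the table are an error.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_taxonomy(table)
    else:
        if table["seq_id"].duplicated().any():
            raise ValueError("taxonomy table has duplicate seq_id rows")
    by_id = {row.seq_id: row for row in table.itertuples(index=False)}
    joined: list[ProteinRecord] = []
    for rec in records:
        row = by_id.get(rec.seq_id)
        if row is None:
            logger.warning(
                "no taxonomy for %s; assigning taxon_group=other", rec.seq_id
            )
            joined.append(rec.with_taxonomy(rec.species, "other"))
        else:
            joined.append(rec.with_taxonomy(str(row.species), str(row.taxon_group)))
    return joined
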