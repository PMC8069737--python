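"""Sequence I/O and curation: FASTA parsing, taxonomy joins, redundancy
removal and the incomplete-fragment filter."""

from __future__ import annotations

import logging

import pytest
from hypothesis import given, settings, strategies as st

from apxsig import (
    CurationConfig,
    ProteinRecord,
    deduplicate,
    join_taxonomy,
    length_filter,
    read_fasta,
    write_fasta,
)
from apxsig.records import SequenceAlphabetError


def rec(seq_id: str, sequence: str, species: str = "Pisum sativum") -> ProteinRecord:
    return ProteinRecord(seq_id=seq_id, sequence=sequence, species=species)


class TestReadWriteFasta:
    def test_parses_entries_and_headers(self, tmp_path):
        path = tmp_path / "in.fa"
        path.write_text(">a some description\nMKT\n>b\nMR\n")
        records = read_fasta(path)
        assert [(r.seq_id, r.sequence) for r in records] == [("a", "MKT"), ("b", "MR")]
        assert records[0].source == "some description"

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.fa"
        path.write_text("")
        assert read_fasta(path) == []

    def test_gap_character_rejected_with_position(self, tmp_path):
        path = tmp_path / "bad.fa"
        path.write_text(">a\nMK-T\n")
        with pytest.raises(SequenceAlphabetError, match=r"'-'.*position 3.*'a'"):
            read_fasta(path)

    def test_roundtrip_is_identity_and_wraps_at_60(self, tmp_path):
        records = [rec("long", "ACDEFGHIKLMNPQRSTVWY" * 7), rec("short", "MR")]
        path = tmp_path / "out.fa"
        write_fasta(records, path)
        lines = path.read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) == 60
        back = read_fasta(path)
        assert [(r.seq_id, r.sequence) for r in back] == [
            (r.seq_id, r.sequence) for r in records
        ]

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fa"
        path.write_text(">a\nMK\n>a\nMR\n")
        with pytest.raises(ValueError, match="duplicate seq_id"):
            read_fasta(path)


class TestJoinTaxonomy:
    def make_table(self, tmp_path, rows):
        path = tmp_path / "tax.tsv"
        path.write_text(
            "seq_id\tspecies\ttaxon_group\n"
            + "".join("\t".join(row) + "\n" for row in rows)
        )
        return path

    def test_matching_record_gets_group(self, tmp_path):
        table = self.make_table(
            tmp_path, [("a", "Klebsormidium nitens", "charophytes")]
        )
        (joined,) = join_taxonomy([rec("a", "MKT", species="")], table)
        assert joined.species == "Klebsormidium nitens"
        assert joined.taxon_group == "charophytes"

    def test_missing_record_defaults_to_other_with_warning(self, tmp_path, caplog):
        table = self.make_table(tmp_path, [("a", "x", "charophytes")])
        with caplog.at_level(logging.WARNING, logger="apxsig"):
            (joined,) = join_taxonomy([rec("b", "MR")], table)
        assert joined.taxon_group == "other"
        assert any("b" in message for message in caplog.messages)

    def test_duplicate_rows_rejected(self, tmp_path):
        table = self.make_table(
            tmp_path, [("a", "x", "charophytes"), ("a", "y", "bryophytes")]
        )
        with pytest.raises(ValueError, match="duplicate"):
            join_taxonomy([rec("a", "MKT")], table)


class TestDeduplicate:
    def test_exact_duplicates_keep_smallest_id(self):
        out = deduplicate([rec("b", "MKTAYIAK"), rec("a", "MKTAYIAK")])
        assert [r.seq_id for r in out] == ["a"]

    def test_fragment_of_longer_sequence_removed(self):
        out = deduplicate([rec("full", "MKTAYIAK"), rec("frag", "TAYI")])
        assert [r.seq_id for r in out] == ["full"]

    def test_identical_sequences_in_different_species_both_kept(self):
        out = deduplicate(
            [rec("a", "MKTAYIAK", "sp1"), rec("b", "MKTAYIAK", "sp2")]
        )
        assert [r.seq_id for r in out] == ["a", "b"]
        # brute-force containment check within species groups
        for i, x in enumerate(out):
            assert not any(
                x.sequence in y.sequence
                for j, y in enumerate(out)
                if i != j and y.species == x.species
            )

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["sp1", "sp2"]),
                st.text(alphabet="MKTR", min_size=1, max_size=6),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_idempotent_and_matches_containment_oracle(self, raw):
        records = [
            ProteinRecord(seq_id=f"s{i}", sequence=seq, species=sp)
            for i, (sp, seq) in enumerate(raw)
        ]
        once = deduplicate(records)
        assert deduplicate(once) == once
        survivors = {r.seq_id for r in once}
        for r in records:
            # oracle: a record may only be removed if some other same-species
            # record contains it (and is longer, or same length smaller id)
            if r.seq_id not in survivors:
                assert any(
                    o.species == r.species
                    and r.sequence in o.sequence
                    and (
                        len(o.sequence) > len(r.sequence)
                        or (len(o.sequence) == len(r.sequence) and o.seq_id < r.seq_id)
                    )
                    for o in records
                    if o.seq_id != r.seq_id
                )
        # and no within-species redundancy remains
        for r in once:
            assert not any(
                o.species == r.species and r.sequence in o.sequence
                for o in once
                if o.seq_id != r.seq_id
            )


class TestLengthFilter:
    def test_strictly_below_half_reference_discarded(self):
        kept, discarded = length_filter(
            [rec("x", "A" * 124), rec("y", "A" * 125)], reference_length=250
        )
        assert [r.seq_id for r in discarded] == ["x"]
        assert [r.seq_id for r in kept] == ["y"]

    def test_partition_is_exact(self):
        records = [rec(f"r{i}", "A" * (100 + i * 30)) for i in range(6)]
        kept, discarded = length_filter(records, reference_length=250)
        assert sorted(r.seq_id for r in kept + discarded) == sorted(
            r.seq_id for r in records
        )
        assert not {r.seq_id for r in kept} & {r.seq_id for r in discarded}

    def test_zero_fraction_rejected_at_config_construction(self):
        with pytest.raises(ValueError, match="min_length_fraction"):
            CurationConfig(min_length_fraction=0)
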