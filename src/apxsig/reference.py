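"""The reference numbering scheme for signature-residue extraction.

All residue positions in this package follow the numbering of cytosolic
ascorbate peroxidase 1 (APx1) of *Pisum sativum*.  Five positions carry
the family signature:

=========  ========  =====================================================
position   residue   role
=========  ========  =====================================================
38         Arg       distal arginine, heterolytic cleavage of H2O2
41         Trp       heme binding/coordination (Phe in APX-R, class II/III)
42         His       distal histidine
163        His       proximal histidine, hydrogen-bonded to the heme
172        Arg       ascorbate binding
=========  ========  =====================================================

Two auxiliary positions, Lys30 and Cys32, contribute weakly to ascorbate
binding and are annotated but never used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .records import ProteinRecord, validate_sequence

#: Synthetic 250-residue reference sequence modeled on pea cytosolic
#: APx1.  It is a constructed stand-in, not the database entry itself,
#: but it reproduces the numbering anchors every downstream computation
#: relies on (Lys30, Cys32, Arg38, Trp41, His42, His163, Arg172) and the
#: conserved proximal-helix context (SGGHTIG around His163); the
#: remaining positions provide realistic alignment background.
SYNTHETIC_APX1_REFERENCE = (
    "MGKSYPTVSPDYQKAIEKAKRKLRGFIAEKKCAPLILRLAWHSAGTFDSKTKTGGPFGTI"
    "KHQAELAHGANNGLDIAVRLLEPIKEQFPIVSYADFYQLAGVVAVEVTGGPEVPFHPGRE"
    "DKPEPPPEGRLPDATKGSDHLRDVFGKAMGLSDQDIVALSGGHTIGAAHKERSGFEGPWT"
    "SNPLIFDNSYFTELLSGEKEGLLQLPSDKALLTDSVFRPLVEKYAADEDVFFADYAEAHL"
    "KLSELGFAEA"
)

CLASSIFICATION_POSITIONS = (38, 41, 42, 163, 172)
AUXILIARY_POSITIONS = (30, 32)
SIGNATURE_POSITIONS = AUXILIARY_POSITIONS + CLASSIFICATION_POSITIONS

#: Residue the reference itself must carry at each signature position.
#: Failing this check at load means a wrong reference file.
REFERENCE_ANCHORS = {30: "K", 32: "C", 38: "R", 41: "W", 42: "H", 163: "H", 172: "R"}

#: Expected residues per family at the classification positions.  For
#: APX-R, position 172 may be anything except arginine (None marker).
FAMILY_EXPECTATIONS = {
    "APX": {38: "R", 41: "W", 42: "H", 163: "H", 172: "R"},
    "APX-R": {38: "R", 41: "F", 42: "H", 163: "H", 172: None},
}


@dataclass(frozen=True)
class ReferenceScheme:
    """Reference sequence plus the signature position set.

    Validates on construction that the reference carries the canonical
    residues at all seven signature positions.
    """

    reference_id: str = "APx1-ref"
    reference_sequence: str = SYNTHETIC_APX1_REFERENCE
    classification_positions: tuple[int, ...] = CLASSIFICATION_POSITIONS
    auxiliary_positions: tuple[int, ...] = AUXILIARY_POSITIONS
    expected: dict = field(default_factory=lambda: dict(FAMILY_EXPECTATIONS))

    def __post_init__(self) -> None:
        validate_sequence(self.reference_sequence, self.reference_id)
        n = len(self.reference_sequence)
        for pos in self.all_positions:
            if not (1 <= pos <= n):
                raise ValueError(
                    f"signature position {pos} outside reference (length {n})"
                )
        for pos, expected in REFERENCE_ANCHORS.items():
            found = self.residue_at(pos)
            if found != expected:
                raise ValueError(
                    f"reference {self.reference_id!r} carries {found} at position "
                    f"{pos}, expected {expected}: wrong reference file?"
                )

    @property
    def all_positions(self) -> tuple[int, ...]:
        return SIGNATURE_POSITIONS

    def residue_at(self, position: int) -> str:
        """1-based lookup into the reference sequence."""
        return self.reference_sequence[position - 1]

    def __len__(self) -> int:
        return len(self.reference_sequence)


def load_reference(path: str | Path | None = None) -> ReferenceScheme:
    """Build a :class:`ReferenceScheme`, from a FASTA file if given.

    With no argument the bundled synthetic APx1-numbering reference is
    used.  A supplied FASTA must contain exactly one entry whose
    sequence carries the canonical residues at the seven signature
    positions.
    """
    if path is None:
        return ReferenceScheme()
    from .io import read_fasta

    entries = read_fasta(path)
    if len(entries) != 1:
        raise ValueError(
            f"reference FASTA {path} must contain exactly one entry, "
            f"found {len(entries)}"
        )
    return ReferenceScheme(
        reference_id=entries[0].seq_id, reference_sequence=entries[0].sequence
    )


def reference_record(scheme: ReferenceScheme | None = None) -> ProteinRecord:
    scheme = scheme or ReferenceScheme()
    return ProteinRecord(
        seq_id=scheme.reference_id,
        sequence=scheme.reference_sequence,
        source="reference",
    )
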