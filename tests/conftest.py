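"""Shared fixtures: the reference scheme and signature-engineering helpers."""

from __future__ import annotations

import pytest

from apxsig import ProteinRecord, ReferenceScheme

CLASSIFICATION_POSITIONS = (38, 41, 42, 163, 172)


@pytest.fixture(scope="session")
def scheme() -> ReferenceScheme:
    return ReferenceScheme()


def edit_reference(
    scheme: ReferenceScheme,
    substitutions: dict[int, str] | None = None,
    deletions: tuple[tuple[int, int], ...] = (),
) -> str:
    """Reference sequence with point substitutions and/or deleted windows
    (inclusive 1-based reference coordinates, applied high-to-low)."""
    seq = list(scheme.reference_sequence)
    for pos, letter in (substitutions or {}).items():
        seq[pos - 1] = letter
    for start, end in sorted(deletions, reverse=True):
        del seq[start - 1:end]
    return "".join(seq)


def signature_record(
    scheme: ReferenceScheme,
    seq_id: str,
    sig: tuple[str, str, str, str, str],
) -> ProteinRecord:
    """Reference-background sequence presenting *sig* at (38,41,42,163,172).

    ``-`` entries are realized as deletions: positions 41/42 by removing
    the window 40-46 (keeps Arg38 anchored), positions 163/172 by the
    proximal windows 161-165 / 169-174.
    """
    subs: dict[int, str] = {}
    deletions: list[tuple[int, int]] = []
    for pos, letter in zip(CLASSIFICATION_POSITIONS, sig):
        if letter != "-":
            subs[pos] = letter
    if sig[1] == "-" or sig[2] == "-":
        assert sig[1] == sig[2] == "-", "N-terminal deletion removes both 41 and 42"
        deletions.append((40, 46))
    if sig[3] == "-":
        deletions.append((161, 165))
    if sig[4] == "-":
        deletions.append((169, 174))
    return ProteinRecord(
        seq_id=seq_id,
        sequence=edit_reference(scheme, subs, tuple(deletions)),
        source="engineered",
    )
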