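"""The residue-signature decision table.

Classification looks only at positions 38, 41, 42, 163 and 172:

* **APX** — exactly (Arg38, Trp41, His42, His163, Arg172).
* **APX-R** — Arg38, Phe41, His42, His163 all present, and position 172
  occupied by anything other than arginine (a deleted 172 qualifies; a
  deleted catalytic position does not — an enzyme cannot lack its
  catalytic residues).
* **APX-L** — every position occupied by "other" residues: 38 not R,
  41 neither W nor F, 42 not H, 163 not H, 172 not R.  A deleted
  position counts as "other" (APX-L proteins genuinely lack the sites;
  their loss traces to two small deletions around the proximal
  histidine).  Phe41 is excluded because it is the APX-R/class II/III
  hallmark and therefore family evidence, not decay.
* **hybrid** — any other arrangement (features of at least two
  families).
* **ambiguous** — any classification position is an X, or the query
  covers less than half the reference (fragment guard).

Hybrids carrying the two arrangements seen in basal streptophyte algae
get a subtype: **proto-APX-R** is the APX signature with the single
Trp41→Phe change; **proto-APX-L** additionally lost the distal
histidine and the ascorbate-binding arginine (Arg38/Phe41/His163
retained, 42 not H, 172 not R).

Positions 30 and 32 (Lys/Cys, minor ascorbate-binding contributors) are
carried through as annotation and never influence the label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignment import ABSENT, AMBIGUOUS, SignatureProfile, profile_sequence
from .records import ProteinRecord
from .reference import ReferenceScheme

logger = logging.getLogger("apxsig")

LABELS = ("APX", "APX-R", "APX-L", "hybrid", "ambiguous")
SUBTYPES = ("proto-APX-R", "proto-APX-L", "none")

CLASSIFICATION_ORDER = (38, 41, 42, 163, 172)


@dataclass(frozen=True)
class FamilyCall:
    """Classification result for one protein.

    ``evidence`` records, per classification position, the observed
    residue and each family's expectation; ``auxiliary`` holds the
    observed residues at 30 and 32 (annotation only).
    """

    seq_id: str
    label: str
    subtype: str = "none"
    evidence: dict[int, dict[str, str]] = field(default_factory=dict)
    auxiliary: dict[int, str] = field(default_factory=dict)
    coverage_fraction: float = 1.0
    note: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.subtype != "none" and self.label != "hybrid":
            raise ValueError("subtype applies to hybrid calls only")


def _is_apx(sig: tuple[str, ...]) -> bool:
    return sig == ("R", "W", "H", "H", "R")


def _is_apx_r(sig: tuple[str, ...]) -> bool:
    p38, p41, p42, p163, p172 = sig
    return (
        p38 == "R"
        and p41 == "F"
        and p42 == "H"
        and p163 == "H"
        and p172 != "R"
    )


def _is_apx_l(sig: tuple[str, ...]) -> bool:
    p38, p41, p42, p163, p172 = sig
    return (
        p38 != "R"
        and p41 not in ("W", "F")
        and p42 != "H"
        and p163 != "H"
        and p172 != "R"
    )


def label_signature(sig: tuple[str, str, str, str, str]) -> str:
    """Label a (38, 41, 42, 163, 172) residue tuple.

    Values are one-letter residues or :data:`ABSENT`; exactly one of
    the four family labels holds for every such tuple.
    """
    if _is_apx(sig):
        return "APX"
    if _is_apx_r(sig):
        return "APX-R"
    if _is_apx_l(sig):
        return "APX-L"
    return "hybrid"


def subtype_signature(sig: tuple[str, str, str, str, str], label: str) -> str:
    """Subtype for hybrid calls: proto-APX-R / proto-APX-L / none."""
    if label != "hybrid":
        return "none"
    p38, p41, p42, p163, p172 = sig
    if sig == ("R", "F", "H", "H", "R"):
        return "proto-APX-R"
    if p38 == "R" and p41 == "F" and p42 != "H" and p163 == "H" and p172 != "R":
        return "proto-APX-L"
    return "none"


def classify(profile: SignatureProfile, scheme: ReferenceScheme) -> FamilyCall:
    """Apply the decision table to a signature profile.

    An X at any classification position, or a low-coverage profile,
    yields ``ambiguous``; otherwise exactly one family label.
    """
    sig = profile.classification_tuple()
    evidence = {
        pos: {
            "observed": profile.residue_at[pos],
            "APX": scheme.expected["APX"][pos],
            "APX-R": scheme.expected["APX-R"][pos] or "not-R",
        }
        for pos in CLASSIFICATION_ORDER
    }
    auxiliary = {pos: profile.residue_at[pos] for pos in scheme.auxiliary_positions}
    common = dict(
        seq_id=profile.seq_id,
        evidence=evidence,
        auxiliary=auxiliary,
        coverage_fraction=profile.coverage_fraction,
    )
    if profile.low_coverage:
        return FamilyCall(label="ambiguous", note="low coverage", **common)
    if AMBIGUOUS in sig:
        return FamilyCall(
            label="ambiguous", note="X at classification position", **common
        )
    label = label_signature(sig)
    return FamilyCall(label=label, subtype=subtype_signature(sig, label), **common)


def classify_batch(
    records: list[ProteinRecord],
    scheme: ReferenceScheme,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> list[FamilyCall]:
    """Align, map and classify every record; never aborts the batch.

    Per-record failures (unalignable input and the like) degrade to an
    ``ambiguous`` call with the reason logged.
    """
    calls: list[FamilyCall] = []
    for rec in records:
        try:
            profile = profile_sequence(
                rec.sequence, scheme, rec.seq_id, gap_open, gap_extend
            )
            call = classify(profile, scheme)
        except Exception as exc:  # per-record isolation contract
            logger.warning("classification failed for %s: %s", rec.seq_id, exc)
            call = FamilyCall(
                seq_id=rec.seq_id,
                label="ambiguous",
                evidence={},
                auxiliary={},
                coverage_fraction=0.0,
                note=f"error: {exc}",
            )
        logger.info(
            "CALL %s label=%s subtype=%s sig=%s",
            call.seq_id,
            call.label,
            call.subtype,
            "".join(call.evidence[p]["observed"] for p in CLASSIFICATION_ORDER)
            if call.evidence
            else "?????",
        )
        calls.append(call)
    return calls


def calls_to_frame(calls: list[FamilyCall]) -> pd.DataFrame:
    """Tabular view of calls (ABSENT as '-', AMBIGUOUS as 'X')."""

    def sig(call: FamilyCall, pos: int) -> str:
        return call.evidence.get(pos, {}).get("observed", "?")

    rows = []
    for call in calls:
        rows.append(
            {
                "seq_id": call.seq_id,
                "label": call.label,
                "subtype": call.subtype,
                "sig38": sig(call, 38),
                "sig41": sig(call, 41),
                "sig42": sig(call, 42),
                "sig163": sig(call, 163),
                "sig172": sig(call, 172),
                "aux30": call.auxiliary.get(30, "?"),
                "aux32": call.auxiliary.get(32, "?"),
                "coverage": round(call.coverage_fraction, 3),
            }
        )
    return pd.DataFrame(rows)


def write_calls(calls: list[FamilyCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"seq_id": str})
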