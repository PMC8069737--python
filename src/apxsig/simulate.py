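"""Synthetic protein-family generator with known ground truth.

Sequences are built from the reference by planting the canonical
signature tuple of a requested family (or proto-subtype), then applying
three evolutionary operators:

* background substitutions — per-site mutation with probability
  ``background_substitution_rate``; a mutation proposes a residue
  uniformly over the 20 letters, so realized changes are uniform over
  the other 19 and occur at rate 19/20 of the nominal rate.  Windows of
  ``signature_windows_halfwidth`` residues around each signature
  position are protected unless protection is switched off (the
  switched-off mode drives signature-degradation experiments).
* a coordinate-shifting indel — with probability ``indel_rate``, one
  insertion or deletion of length 1-5 placed at least 10 residues from
  every signature position, so correct classification must survive the
  coordinate shift.
* the proximal-deletion operator — two short deletions (3-8 residues)
  removing the proximal histidine (163) and the ascorbate-binding
  arginine (172), the lesion that underlies APX-L loss of both sites.

Every sequence carries a :class:`TruthRecord` whose edit script,
replayed on the reference, reproduces it exactly; the true label is
derived from the residues actually planted at the five classification
positions, so truth and sequence can never disagree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import ABSENT
from .classify import label_signature, subtype_signature
from .records import AMINO_ACIDS, ProteinRecord, TAXON_GROUPS
from .reference import ReferenceScheme, SIGNATURE_POSITIONS

#: Signature substitutions defining each family/subtype template,
#: applied to the reference (position -> new residue).  APX-L
#: additionally loses positions 163 and 172 by deletion.
TEMPLATE_EDITS: dict[str, dict[int, str]] = {
    "APX": {},
    "APX-R": {41: "F", 172: "K"},
    "APX-L": {38: "A", 41: "L", 42: "N"},
    "proto-APX-R": {41: "F"},
    "proto-APX-L": {41: "F", 42: "N", 172: "G"},
}

#: Fixed deletion windows (inclusive, reference coordinates) used by the
#: deterministic APX-L template; the stochastic operator randomizes them.
TEMPLATE_DELETION_WINDOWS = ((161, 165), (169, 174))

#: Largest window the proximal-deletion operator may remove.
MIN_DELETION_WINDOW = 3
MAX_DELETION_WINDOW = 8

_SEQID_SLUG = {
    "APX": "apx",
    "APX-R": "apxr",
    "APX-L": "apxl",
    "proto-APX-R": "protoapxr",
    "proto-APX-L": "protoapxl",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    The defaults are the standard stress conditions used throughout the
    test battery: five planted categories at 80 sequences each, 20%
    per-site background mutation outside protected signature windows,
    and a coordinate-shifting indel in half the sequences.
    """

    composition: dict[str, int] = field(
        default_factory=lambda: {label: 80 for label in TEMPLATE_EDITS}
    )
    background_substitution_rate: float = 0.2
    indel_rate: float = 0.5
    proximal_deletion_probability: float = 1.0
    seed: int = 0
    signature_windows_halfwidth: int = 3
    protect_signature_windows: bool = True
    family_divergence_rate: float = 0.0
    taxa: tuple[str, ...] = TAXON_GROUPS[:-1]

    def __post_init__(self) -> None:
        for name in (
            "background_substitution_rate",
            "indel_rate",
            "proximal_deletion_probability",
            "family_divergence_rate",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for label, count in self.composition.items():
            if label not in TEMPLATE_EDITS:
                raise ValueError(f"unknown composition label {label!r}")
            if count < 0:
                raise ValueError(f"negative count for {label!r}")
        if self.signature_windows_halfwidth < 0:
            raise ValueError("signature_windows_halfwidth must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated sequence.

    ``edit_script`` is an ordered list of operations; applied in order
    to the reference (each in the coordinate system current at its
    step) it reproduces the sequence exactly.
    """

    seq_id: str
    true_label: str
    true_subtype: str
    edit_script: tuple[tuple, ...]
    planted_signature: tuple[str, str, str, str, str]


def replay_edits(reference: str, edit_script: tuple[tuple, ...]) -> str:
    """Apply an edit script to *reference* and return the sequence."""
    seq = list(reference)
    for op in edit_script:
        kind = op[0]
        if kind == "sub":
            _, pos, new = op
            seq[pos - 1] = new
        elif kind == "ins":
            _, pos, segment = op
            seq[pos - 1:pos - 1] = list(segment)
        elif kind == "del":
            _, pos, removed = op
            observed = "".join(seq[pos - 1:pos - 1 + len(removed)])
            if observed != removed:
                raise ValueError(
                    f"edit script mismatch: expected to delete {removed!r} "
                    f"at {pos}, found {observed!r}"
                )
            del seq[pos - 1:pos - 1 + len(removed)]
        else:
            raise ValueError(f"unknown edit op {kind!r}")
    return "".join(seq)


def make_template(label: str, scheme: ReferenceScheme | None = None) -> str:
    """Canonical sequence for a family or proto-subtype.

    The reference edited at exactly the classification positions; the
    APX-L template additionally carries the two fixed proximal
    deletions removing His163 and Arg172.
    """
    scheme = scheme or ReferenceScheme()
    if label not in TEMPLATE_EDITS:
        raise ValueError(
            f"unknown label {label!r}; expected one of {sorted(TEMPLATE_EDITS)}"
        )
    seq = list(scheme.reference_sequence)
    for pos, new in TEMPLATE_EDITS[label].items():
        seq[pos - 1] = new
    if label == "APX-L":
        for start, end in sorted(TEMPLATE_DELETION_WINDOWS, reverse=True):
            del seq[start - 1:end]
    return "".join(seq)


def _protected_mask(length: int, halfwidth: int) -> np.ndarray:
    """Boolean mask (0-based) of positions within *halfwidth* of a
    signature position."""
    mask = np.zeros(length, dtype=bool)
    for pos in SIGNATURE_POSITIONS:
        lo = max(0, pos - 1 - halfwidth)
        hi = min(length, pos + halfwidth)
        mask[lo:hi] = True
    # The proximal region is protected as one contiguous block spanning
    # everything the deletion operator can reach (windows up to
    # MAX_DELETION_WINDOW anchored on 163/172) plus the usual halfwidth.
    # A mutation to His or Arg on the immediate flank of the deleted
    # stretch slides into the vacated signature column at no alignment
    # cost (the gap merely shifts), which would make the planted truth
    # unidentifiable under alignment-based mapping.
    lo = 163 - 1 - halfwidth - (MAX_DELETION_WINDOW - 1)
    hi = 172 + halfwidth + (MAX_DELETION_WINDOW - 1)
    mask[max(0, lo):min(length, hi)] = True
    return mask


def _indel_allowed_starts(length: int, indel_len: int, is_deletion: bool) -> list[int]:
    """0-based start positions at least 10 residues from every signature
    position (for deletions, the whole removed window must be)."""
    span = indel_len if is_deletion else 1
    allowed = []
    limit = length - span if is_deletion else length
    for start in range(limit + 1 if not is_deletion else limit):
        window = range(start + 1, start + span + 1)  # 1-based touched positions
        if all(abs(p - s) >= 10 for p in window for s in SIGNATURE_POSITIONS):
            allowed.append(start)
    return allowed


def apply_proximal_deletions(
    sequence: str,
    scheme: ReferenceScheme,
    rng: np.random.Generator,
    positions: tuple[int, int] = (163, 172),
) -> tuple[str, tuple[tuple, ...]]:
    """Remove two short windows covering the proximal histidine and the
    ascorbate-binding arginine.

    Window sizes are drawn uniformly in 3-8; each window contains its
    target position but not the other, and the windows are disjoint.
    *positions* are coordinates in the supplied sequence (reference
    coordinates when the sequence has no upstream indels).  Returns the
    edited sequence and the deletion ops, higher window first so the
    script replays in sequence coordinates.
    """
    p163, p172 = positions
    if len(sequence) < p172:
        raise ValueError(
            f"sequence of length {len(sequence)} does not cover the proximal "
            f"region (needs at least {p172} residues)"
        )
    for _ in range(1000):
        s1 = int(rng.integers(MIN_DELETION_WINDOW, MAX_DELETION_WINDOW + 1))
        s2 = int(rng.integers(MIN_DELETION_WINDOW, MAX_DELETION_WINDOW + 1))
        o1, o2 = int(rng.integers(0, s1)), int(rng.integers(0, s2))
        w1 = (p163 - o1, p163 - o1 + s1 - 1)
        w2 = (p172 - o2, p172 - o2 + s2 - 1)
        between = sequence[w1[1]:w2[0] - 1]  # survivors between the windows
        if (
            w1[0] >= 1
            and w2[1] <= len(sequence)
            and w1[1] < w2[0]  # disjoint, in order
            and not (w1[0] <= p172 <= w1[1])
            and not (w2[0] <= p163 <= w2[1])
            # A histidine stranded between the windows (the reference has
            # a second His two turns downstream of the proximal one) can
            # be pulled onto the proximal column when affine scoring
            # merges the two gaps; such placements leave the deletion's
            # outcome ill-defined and are rejected.
            and "H" not in between
        ):
            break
    else:  # pragma: no cover - cannot happen for full-length input
        raise RuntimeError("failed to place proximal deletion windows")
    seq = list(sequence)
    ops = []
    for start, end in (w2, w1):  # higher first: coordinates stay valid
        removed = "".join(seq[start - 1:end])
        ops.append(("del", start, removed))
        del seq[start - 1:end]
    return "".join(seq), tuple(ops)


def _simulate_one(
    label: str,
    scheme: ReferenceScheme,
    config: SimulationConfig,
    rng: np.random.Generator,
    founder_edits: dict[int, str],
) -> tuple[str, tuple[tuple, ...], tuple[str, ...]]:
    """Build one sequence; returns (sequence, edit script, planted tuple)."""
    reference = scheme.reference_sequence
    length = len(reference)
    seq = list(reference)
    script: list[tuple] = []
    planted = {pos: reference[pos - 1] for pos in (38, 41, 42, 163, 172)}

    def substitute(pos: int, new: str) -> None:
        if seq[pos - 1] != new:
            seq[pos - 1] = new
            script.append(("sub", pos, new))
            if pos in planted:
                planted[pos] = new

    for pos, new in TEMPLATE_EDITS[label].items():
        substitute(pos, new)
    for pos, new in founder_edits.items():
        substitute(pos, new)

    protected = _protected_mask(length, config.signature_windows_halfwidth)
    rate = config.background_substitution_rate
    if rate > 0:
        hits = rng.random(length) < rate
        proposals = rng.integers(0, len(AMINO_ACIDS), size=length)
        for idx in np.nonzero(hits)[0]:
            if config.protect_signature_windows and protected[idx]:
                continue
            substitute(int(idx) + 1, AMINO_ACIDS[proposals[idx]])

    # Coordinate-shifting indel, away from every signature position.
    sig_coords = {pos: pos for pos in (163, 172)}
    if rng.random() < config.indel_rate:
        is_deletion = bool(rng.integers(0, 2))
        indel_len = int(rng.integers(1, 6))
        starts = _indel_allowed_starts(length, indel_len, is_deletion)
        start = int(starts[rng.integers(0, len(starts))])
        if is_deletion:
            removed = "".join(seq[start:start + indel_len])
            script.append(("del", start + 1, removed))
            del seq[start:start + indel_len]
            shift, indel_pos = -indel_len, start + 1
        else:
            segment = "".join(
                AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), indel_len)
            )
            script.append(("ins", start + 1, segment))
            seq[start:start] = list(segment)
            shift, indel_pos = indel_len, start + 1
        for pos in sig_coords:
            if indel_pos <= sig_coords[pos]:
                sig_coords[pos] += shift

    if label == "APX-L" and rng.random() < config.proximal_deletion_probability:
        edited, ops = apply_proximal_deletions(
            "".join(seq), scheme, rng, (sig_coords[163], sig_coords[172])
        )
        seq = list(edited)
        script.extend(ops)
        planted[163] = ABSENT
        planted[172] = ABSENT

    planted_tuple = tuple(planted[p] for p in (38, 41, 42, 163, 172))
    return "".join(seq), tuple(script), planted_tuple


def simulate_dataset(
    config: SimulationConfig | None = None,
    scheme: ReferenceScheme | None = None,
) -> tuple[list[ProteinRecord], list[TruthRecord]]:
    """Generate a labelled synthetic dataset.

    Deterministic: a fixed seed yields byte-identical records.  Species
    and taxon groups are assigned round-robin over ``config.taxa``.
    The true label/subtype is derived from the residues actually
    planted at the classification positions, so it remains correct even
    when signature protection is off and a planted signature mutates.
    """
    config = config or SimulationConfig()
    scheme = scheme or ReferenceScheme()
    rng = np.random.default_rng(config.seed)

    founder: dict[str, dict[int, str]] = {}
    protected = _protected_mask(len(scheme), config.signature_windows_halfwidth)
    for index, label in enumerate(sorted(TEMPLATE_EDITS)):
        edits: dict[int, str] = {}
        if config.family_divergence_rate > 0:
            frng = np.random.default_rng([config.seed, 1000 + index])
            hits = frng.random(len(scheme)) < config.family_divergence_rate
            proposals = frng.integers(0, len(AMINO_ACIDS), size=len(scheme))
            for idx in np.nonzero(hits)[0]:
                if not protected[idx]:
                    edits[int(idx) + 1] = AMINO_ACIDS[proposals[idx]]
        founder[label] = edits

    records: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    taxa = itertools.cycle(config.taxa)
    for label in sorted(config.composition):
        for i in range(config.composition[label]):
            seq_id = f"{_SEQID_SLUG[label]}_{i:04d}"
            sequence, script, planted = _simulate_one(
                label, scheme, config, rng, founder[label]
            )
            true_label = label_signature(planted)
            true_subtype = subtype_signature(planted, true_label)
            group = next(taxa)
            records.append(
                ProteinRecord(
                    seq_id=seq_id,
                    sequence=sequence,
                    species=f"Synthetica {group[:-1]}a",
                    taxon_group=group,
                    source=f"simulated {label}",
                )
            )
            truths.append(
                TruthRecord(
                    seq_id=seq_id,
                    true_label=true_label,
                    true_subtype=true_subtype,
                    edit_script=script,
                    planted_signature=planted,
                )
            )
    return records, truths


def write_truth(truths: list[TruthRecord], path) -> None:
    """Truth TSV: seq_id, true_label, true_subtype."""
    import pandas as pd

    pd.DataFrame(
        {
            "seq_id": [t.seq_id for t in truths],
            "true_label": [t.true_label for t in truths],
            "true_subtype": [t.true_subtype for t in truths],
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> dict[str, str]:
    """Truth TSV -> mapping seq_id -> true_label."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(table["seq_id"], table["true_label"]))
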