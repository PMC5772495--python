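"""UVB-signature classification of somatic substitutions.

Ultraviolet-B mutagenesis leaves a characteristic spectrum: C→T transitions
at dipyrimidine sites and, more specifically, tandem CC→TT dinucleotide
changes.  This module classifies substitutions into those two classes,
merges adjacent single-base C→T calls into tandem events, and summarizes
the UV-signature fraction of a record set.

By default the classes are counted exactly as written (literal C→T and
CC→TT on the reported strand).  ``normalize_strand=True`` additionally
folds the reverse-complement readings (G→A, GG→AA), the convention used in
trinucleotide-signature work; turning it on can only grow the UV count.

Flanking dipyrimidine-context checks are deliberately not applied — the
classification is purely substitution-based and needs no reference genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .io_formats import MutationRecord

__all__ = [
    "SignatureClass",
    "NonSubstitutionWarning",
    "TandemEvent",
    "SignatureSummary",
    "classify_substitution",
    "detect_tandem",
    "summarize_signature",
]


class SignatureClass(str, Enum):
    C_TO_T = "CtoT"
    CC_TO_TT_TANDEM = "CCtoTT_tandem"
    OTHER = "other"


class NonSubstitutionWarning(UserWarning):
    """Raised (as a warning) when an indel reaches the substitution classifier."""


def classify_substitution(
    record: MutationRecord, normalize_strand: bool = False
) -> SignatureClass:
    """Classify one record as C→T, tandem CC→TT, or other.

    Indels (len(ref) != len(alt)) are classified ``other`` with a
    :class:`NonSubstitutionWarning`, not an exception.  Pure function.
    """
    if not record.is_substitution:
        warnings.warn(
            f"indel {record.ref}>{record.alt} at {record.chrom}:{record.pos} "
            "classified as 'other'",
            NonSubstitutionWarning,
            stacklevel=2,
        )
        return SignatureClass.OTHER
    ref, alt = record.ref, record.alt
    if ref == "C" and alt == "T":
        return SignatureClass.C_TO_T
    if ref == "CC" and alt == "TT":
        return SignatureClass.CC_TO_TT_TANDEM
    if normalize_strand:
        if ref == "G" and alt == "A":
            return SignatureClass.C_TO_T
        if ref == "GG" and alt == "AA":
            return SignatureClass.CC_TO_TT_TANDEM
    return SignatureClass.OTHER


@dataclass(frozen=True)
class TandemEvent:
    """One CC→TT dinucleotide event.

    References either a single dinucleotide record or exactly two adjacent
    single-base C→T records from the same sample and chromosome.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based position of the first (5') base
    members: tuple[MutationRecord, ...]

    def __post_init__(self) -> None:
        if len(self.members) not in (1, 2):
            raise ValueError("a tandem event references one or two records")


def detect_tandem(
    records: Iterable[MutationRecord], normalize_strand: bool = False
) -> list[TandemEvent]:
    """Merge adjacent same-sample C→T pairs into CC→TT tandem events.

    Records are sorted by (sample, chrom, pos) and single-base C→T calls at
    positions p and p+1 are paired greedily left to right, so each record
    joins at most one event and the pairing is deterministic regardless of
    input order.  Dinucleotide CC→TT records are tandem events on their own.
    """
    records = sorted(records, key=lambda r: (r.sample_id, r.chrom, r.pos))
    events: list[TandemEvent] = []
    singles: list[MutationRecord] = []
    for rec in records:
        cls = _quiet_classify(rec, normalize_strand)
        if cls is SignatureClass.CC_TO_TT_TANDEM:
            events.append(
                TandemEvent(sample_id=rec.sample_id, chrom=rec.chrom, pos=rec.pos, members=(rec,))
            )
        elif cls is SignatureClass.C_TO_T and len(rec.ref) == 1:
            singles.append(rec)

    i = 0
    while i < len(singles) - 1:
        a, b = singles[i], singles[i + 1]
        if (
            a.sample_id == b.sample_id
            and a.chrom == b.chrom
            and b.pos == a.pos + 1
        ):
            events.append(
                TandemEvent(sample_id=a.sample_id, chrom=a.chrom, pos=a.pos, members=(a, b))
            )
            i += 2  # greedy: neither member can pair again
        else:
            i += 1
    events.sort(key=lambda e: (e.sample_id, e.chrom, e.pos))
    return events


def _quiet_classify(rec: MutationRecord, normalize_strand: bool) -> SignatureClass:
    if not rec.is_substitution:
        return SignatureClass.OTHER
    return classify_substitution(rec, normalize_strand)


@dataclass(frozen=True)
class SignatureSummary:
    """UV-signature content of a record set.

    ``basis`` records the counting unit: ``"record"`` counts every input
    record (both members of a tandem pair count), ``"event"`` counts a
    tandem pair as one mutational event.  ``fraction_uv`` is ``None`` for an
    empty input rather than a division error.
    """

    n_total: int
    n_uv: int
    n_tandem_events: int
    fraction_uv: float | None
    basis: str = "record"
    normalize_strand: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_uv <= max(self.n_total, 0):
            raise ValueError("n_uv must lie in [0, n_total]")


def summarize_signature(
    records: Sequence[MutationRecord],
    normalize_strand: bool = False,
    basis: str = "record",
) -> SignatureSummary:
    """Count UV-signature content of a record set.

    A record is UV if it classifies as C→T or CC→TT (tandem-pair members
    are single-base C→T records and are therefore included).  On the
    ``"event"`` basis each detected tandem pair is collapsed to one event
    in both numerator and denominator.
    """
    if basis not in ("record", "event"):
        raise ValueError(f"basis must be 'record' or 'event', got {basis!r}")
    records = list(records)
    events = detect_tandem(records, normalize_strand)
    classes = [_quiet_classify(r, normalize_strand) for r in records]
    uv_flags = [c in (SignatureClass.C_TO_T, SignatureClass.CC_TO_TT_TANDEM) for c in classes]

    n_total = len(records)
    n_uv = sum(uv_flags)
    if basis == "event":
        # collapse each two-member pair: one fewer row in numerator and denominator
        n_pairs = sum(1 for e in events if len(e.members) == 2)
        n_total -= n_pairs
        n_uv -= n_pairs
    fraction = (n_uv / n_total) if n_total > 0 else None
    return SignatureSummary(
        n_total=n_total,
        n_uv=n_uv,
        n_tandem_events=len(events),
        fraction_uv=fraction,
        basis=basis,
        normalize_strand=normalize_strand,
    )
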