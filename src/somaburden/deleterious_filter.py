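"""Filter annotated somatic calls down to likely-deleterious records.

The filter keeps nonsynonymous variants predicted deleterious (SIFT flag
``D``) and auto-passes truncating classes (nonsense, frameshift, splice),
which SIFT cannot score.  Population-frequency and conservation (GERP++)
thresholds exist as optional switches and are off by default: low variant
frequency (<0.001) and GERP++ > 2 are properties observed of retained
melanoma mutations rather than unambiguous filter rules, so neither is
asserted as a hard rule.

Rules are evaluated in a fixed order — synonymous, SIFT, frequency, GERP —
so exclusion-reason counts are deterministic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .io_formats import (
    TRUNCATING_CLASSES,
    MutationRecord,
    SiftPred,
    VariantClass,
)

__all__ = ["FilterConfig", "ExclusionReason", "FilterResult", "is_deleterious", "apply_filter"]


class ExclusionReason(str, Enum):
    SYNONYMOUS = "synonymous"
    SIFT_NOT_DELETERIOUS = "sift_not_deleterious"
    POP_FREQ = "pop_freq_above_threshold"
    GERP = "gerp_below_threshold"


@dataclass(frozen=True)
class FilterConfig:
    """Switches for the deleterious filter.

    Parameters
    ----------
    require_nonsynonymous
        Exclude synonymous variants.
    require_sift_deleterious
        Require SIFT prediction ``D`` for non-truncating nonsynonymous
        variants.  A missing SIFT call on such a variant excludes it
        (conservative: only flagged-D calls are kept).
    truncating_auto_deleterious
        Nonsense/frameshift/splice variants pass the SIFT rule regardless of
        (or without) a SIFT score.
    max_pop_freq
        If set, exclude records with population frequency above the
        threshold; records with no frequency annotation pass.
    min_gerp
        If set, exclude records with GERP++ below the threshold; records
        with no GERP annotation pass.
    """

    require_nonsynonymous: bool = True
    require_sift_deleterious: bool = True
    truncating_auto_deleterious: bool = True
    max_pop_freq: float | None = None
    min_gerp: float | None = None

    def __post_init__(self) -> None:
        for name in ("max_pop_freq", "min_gerp"):
            value = getattr(self, name)
            if value is not None and not math.isfinite(value):
                raise ValueError(f"{name} must be finite when enabled, got {value}")


def is_deleterious(
    record: MutationRecord, config: FilterConfig = FilterConfig()
) -> tuple[bool, ExclusionReason | None]:
    """Decide whether one record passes every enabled rule.

    Returns ``(True, None)`` or ``(False, reason)`` where *reason* is the
    first failing rule in the fixed evaluation order.  Pure function of
    ``(record, config)``.
    """
    if config.require_nonsynonymous and record.variant_class is VariantClass.SYNONYMOUS:
        return False, ExclusionReason.SYNONYMOUS
    truncating = record.variant_class in TRUNCATING_CLASSES
    if config.require_sift_deleterious and not (
        truncating and config.truncating_auto_deleterious
    ):
        if record.sift_pred is not SiftPred.DELETERIOUS:
            return False, ExclusionReason.SIFT_NOT_DELETERIOUS
    if config.max_pop_freq is not None:
        if record.pop_freq is not None and record.pop_freq > config.max_pop_freq:
            return False, ExclusionReason.POP_FREQ
    if config.min_gerp is not None:
        if record.gerp is not None and record.gerp < config.min_gerp:
            return False, ExclusionReason.GERP
    return True, None


@dataclass
class FilterResult:
    """Partition of the input into kept records and per-reason exclusions."""

    kept: list[MutationRecord]
    excluded: list[tuple[MutationRecord, ExclusionReason]]
    reason_counts: Counter = field(default_factory=Counter)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.excluded)


def apply_filter(
    records: Iterable[MutationRecord], config: FilterConfig = FilterConfig()
) -> FilterResult:
    """Partition records into kept and excluded-with-reason.

    Every input record lands either in ``kept`` or in exactly one
    exclusion-reason bucket; order is preserved within each part and the
    reason counts sum to the input size.
    """
    kept: list[MutationRecord] = []
    excluded: list[tuple[MutationRecord, ExclusionReason]] = []
    counts: Counter = Counter()
    for record in records:
        ok, reason = is_deleterious(record, config)
        if ok:
            kept.append(record)
        else:
            assert reason is not None
            excluded.append((record, reason))
            counts[reason.value] += 1
    return FilterResult(kept=kept, excluded=excluded, reason_counts=counts)
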