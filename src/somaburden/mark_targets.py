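"""Differential histone-mark regions → gene-body targets.

Given two sets of regions with reduced mark signal (one per comparison,
e.g. knockdown vs. control and mutant vs. control), this module finds the
regions reduced in *both* conditions, assigns them to gene bodies, and
compares target-gene sets across cellular contexts.

Two semantics for "reduced in both" are provided because differential-peak
overlap conventions vary:

``reference`` (default)
    Each region of set A that overlaps at least one region of set B (by at
    least ``min_overlap`` bp) is reported once, unclipped.  Counts are then
    comparable to A's region total ("N of A's regions are also reduced in B").
``intersection``
    The set-theoretic intersection of the two merged region sets, emitted
    as disjoint clipped intervals.  This mode is invariant to how input
    regions are split into adjacent pieces.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_formats import GeneModel, GenomicInterval

__all__ = [
    "OverlapStats",
    "TargetGeneReport",
    "regions_reduced_in_both",
    "assign_gene_targets",
    "gene_set_overlap",
    "derive_target_report",
]


def _trees_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _merge_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Union of intervals per chromosome as sorted disjoint (start, end) pairs.

    Adjacent (book-ended) pieces are merged, so splitting an input region
    into contiguous fragments does not change the union.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: list[tuple[int, int]] = []
        for start, end in spans:
            if out and start <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        merged[chrom] = out
    return merged


def regions_reduced_in_both(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    mode: str = "reference",
    min_overlap: int = 1,
) -> list[GenomicInterval]:
    """Regions with reduced signal in both conditions.

    See the module docstring for the two modes.  ``min_overlap`` is the
    minimum shared base pairs (default 1) for a pair of regions to count
    as overlapping; in intersection mode it is the minimum emitted piece
    length.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    if mode == "reference":
        b_merged = _merge_by_chrom(set_b)
        b_ends = {chrom: [end for _, end in spans] for chrom, spans in b_merged.items()}
        out = []
        for iv in set_a:
            spans = b_merged.get(iv.chrom, [])
            # spans are sorted and disjoint: only a contiguous window can overlap
            i = bisect.bisect_right(b_ends.get(iv.chrom, []), iv.start)
            hit = False
            while i < len(spans) and spans[i][0] < iv.end:
                if min(iv.end, spans[i][1]) - max(iv.start, spans[i][0]) >= min_overlap:
                    hit = True
                    break
                i += 1
            if hit:
                out.append(iv)
        return out
    if mode == "intersection":
        a_merged = _merge_by_chrom(set_a)
        b_merged = _merge_by_chrom(set_b)
        pieces: list[GenomicInterval] = []
        for chrom in sorted(set(a_merged) & set(b_merged)):
            ai = bi = 0
            a_spans, b_spans = a_merged[chrom], b_merged[chrom]
            while ai < len(a_spans) and bi < len(b_spans):
                start = max(a_spans[ai][0], b_spans[bi][0])
                end = min(a_spans[ai][1], b_spans[bi][1])
                if end - start >= min_overlap:
                    pieces.append(GenomicInterval(chrom, start, end))
                if a_spans[ai][1] <= b_spans[bi][1]:
                    ai += 1
                else:
                    bi += 1
        return pieces
    raise ValueError(f"unknown mode {mode!r} (expected 'reference' or 'intersection')")


def assign_gene_targets(
    regions: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    min_overlap: int = 1,
) -> set[str]:
    """Genes whose gene body overlaps at least one region by >= min_overlap bp.

    A region overlapping several gene bodies contributes to each; a gene hit
    by several regions is counted once.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene)
    targets: set[str] = set()
    for region in regions:
        tree = trees.get(region.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(region.start, region.end):
            if min(region.end, hit.end) - max(region.start, hit.begin) >= min_overlap:
                targets.add(hit.data)
    return targets


@dataclass(frozen=True)
class OverlapStats:
    shared: int
    fraction_of_a: float
    fraction_of_b: float
    jaccard: float


def gene_set_overlap(genes_a: Iterable[str], genes_b: Iterable[str]) -> OverlapStats:
    """Shared-gene count and fractions between two target-gene sets."""
    a, b = set(genes_a), set(genes_b)
    shared = len(a & b)
    union = len(a | b)
    return OverlapStats(
        shared=shared,
        fraction_of_a=shared / len(a) if a else 0.0,
        fraction_of_b=shared / len(b) if b else 0.0,
        jaccard=shared / union if union else 0.0,
    )


@dataclass
class TargetGeneReport:
    """Summary of the two-condition region comparison and target assignment."""

    n_regions_cond_a: int
    n_regions_cond_b: int
    n_regions_both: int
    genes_both: set[str]
    n_genes: int
    mode: str
    min_overlap: int
    overlap_with_other_context: OverlapStats | None = None

    def to_dict(self) -> dict:
        out = {
            "n_regions_cond_a": self.n_regions_cond_a,
            "n_regions_cond_b": self.n_regions_cond_b,
            "n_regions_both": self.n_regions_both,
            "n_genes": self.n_genes,
            "genes_both": sorted(self.genes_both),
            "mode": self.mode,
            "min_overlap": self.min_overlap,
        }
        if self.overlap_with_other_context is not None:
            o = self.overlap_with_other_context
            out["overlap_with_other_context"] = {
                "shared": o.shared,
                "fraction_of_a": o.fraction_of_a,
                "fraction_of_b": o.fraction_of_b,
                "jaccard": o.jaccard,
            }
        return out


def derive_target_report(
    regions_a: Sequence[GenomicInterval],
    regions_b: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    other_context_genes: Iterable[str] | None = None,
    mode: str = "reference",
    min_overlap: int = 1,
) -> TargetGeneReport:
    """Full downstream derivation: both-reduced regions → gene-body targets → overlap."""
    both = regions_reduced_in_both(regions_a, regions_b, mode=mode, min_overlap=min_overlap)
    genes = assign_gene_targets(both, gene_models, min_overlap=min_overlap)
    overlap = None
    if other_context_genes is not None:
        overlap = gene_set_overlap(genes, other_context_genes)
    return TargetGeneReport(
        n_regions_cond_a=len(regions_a),
        n_regions_cond_b=len(regions_b),
        n_regions_both=len(both),
        genes_both=genes,
        n_genes=len(genes),
        mode=mode,
        min_overlap=min_overlap,
        overlap_with_other_context=overlap,
    )
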