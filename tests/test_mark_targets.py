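"""Interval machinery against brute-force oracles; planted-truth recovery."""

import numpy as np
import pytest

from somaburden.io_formats import GeneModel, GenomicInterval, read_bed, read_gene_models, write_bed, write_gene_models
from somaburden.mark_targets import (
    assign_gene_targets,
    derive_target_report,
    gene_set_overlap,
    regions_reduced_in_both,
)
from somaburden.synthetic_data import RegionExperimentConfig, simulate_region_experiment


def iv(chrom, start, end, name=None):
    return GenomicInterval(chrom, start, end, name=name)


def random_intervals(rng, n, chroms=("c1", "c2"), span=5000, max_len=300):
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        out.append(
            iv(chroms[int(rng.integers(len(chroms)))], start, start + int(rng.integers(1, max_len)), name=f"r{i}")
        )
    return out


def brute_force_overlapping_a(set_a, set_b, min_overlap=1):
    """O(n*m) pairwise oracle for reference-mode counting."""
    out = []
    for a in set_a:
        if any(
            a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) >= min_overlap
            for b in set_b
        ):
            out.append(a)
    return out


def brute_force_basepair_intersection(set_a, set_b, span=6000):
    """Per-basepair boolean oracle for intersection mode."""
    pieces = []
    for chrom in sorted({x.chrom for x in set_a} | {x.chrom for x in set_b}):
        mask_a = np.zeros(span, dtype=bool)
        mask_b = np.zeros(span, dtype=bool)
        for x in set_a:
            if x.chrom == chrom:
                mask_a[x.start : x.end] = True
        for x in set_b:
            if x.chrom == chrom:
                mask_b[x.start : x.end] = True
        both = mask_a & mask_b
        # extract runs
        padded = np.concatenate([[False], both, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        pieces += [(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    return pieces


class TestRegionsReducedInBoth:
    def test_disjoint_sets_empty(self):
        a, b = [iv("c1", 100, 200)], [iv("c1", 300, 400)]
        assert regions_reduced_in_both(a, b) == []
        assert regions_reduced_in_both(a, b, mode="intersection") == []

    def test_reference_vs_intersection_semantics(self):
        a, b = [iv("c1", 100, 200)], [iv("c1", 150, 250)]
        assert regions_reduced_in_both(a, b) == a
        assert regions_reduced_in_both(a, b, mode="intersection") == [iv("c1", 150, 200)]

    def test_count_bounded_by_reference_set(self):
        a = [iv("c1", 0, 100), iv("c1", 50, 150)]
        b = [iv("c1", 40, 60), iv("c1", 90, 95), iv("c1", 120, 130)]
        both = regions_reduced_in_both(a, b)
        assert len(both) <= len(a) and both == a

    def test_min_overlap_threshold(self):
        a, b = [iv("c1", 100, 200)], [iv("c1", 195, 300)]
        assert regions_reduced_in_both(a, b, min_overlap=5) == a
        assert regions_reduced_in_both(a, b, min_overlap=6) == []

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            a = random_intervals(rng, int(rng.integers(0, 120)))
            b = random_intervals(rng, int(rng.integers(0, 120)))
            assert regions_reduced_in_both(a, b) == brute_force_overlapping_a(a, b)

    def test_intersection_matches_basepair_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = random_intervals(rng, int(rng.integers(1, 80)))
            b = random_intervals(rng, int(rng.integers(1, 80)))
            got = [(p.chrom, p.start, p.end) for p in regions_reduced_in_both(a, b, mode="intersection")]
            assert sorted(got) == sorted(brute_force_basepair_intersection(a, b))

    def test_intersection_invariant_to_splitting(self):
        a = [iv("c1", 100, 500)]
        a_split = [iv("c1", 100, 250), iv("c1", 250, 400), iv("c1", 400, 500)]
        b = [iv("c1", 200, 600)]
        assert regions_reduced_in_both(a, b, mode="intersection") == regions_reduced_in_both(
            a_split, b, mode="intersection"
        )

    def test_input_order_invariance(self):
        rng = np.random.default_rng(9)
        a = random_intervals(rng, 40)
        b = random_intervals(rng, 40)
        got1 = set(regions_reduced_in_both(a, b))
        got2 = set(regions_reduced_in_both(a[::-1], b[::-1]))
        assert got1 == got2


class TestAssignGeneTargets:
    def test_region_inside_gene_body(self):
        genes = [GeneModel("g", "c1", 0, 1000)]
        assert assign_gene_targets([iv("c1", 500, 600)], genes) == {"g"}

    def test_region_on_geneless_chromosome(self):
        genes = [GeneModel("g", "c1", 0, 1000)]
        assert assign_gene_targets([iv("c9", 500, 600)], genes) == set()

    def test_region_spanning_two_genes_hits_both_once(self):
        genes = [GeneModel("a", "c1", 0, 100), GeneModel("b", "c1", 150, 300)]
        regions = [iv("c1", 50, 200), iv("c1", 60, 90)]
        assert assign_gene_targets(regions, genes) == {"a", "b"}

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            regions = random_intervals(rng, int(rng.integers(0, 100)))
            genes = [
                GeneModel(f"g{i}", g.chrom, g.start, g.end)
                for i, g in enumerate(random_intervals(rng, int(rng.integers(1, 60))))
            ]
            expected = {
                g.gene
                for g in genes
                for r in regions
                if r.chrom == g.chrom and min(r.end, g.end) - max(r.start, g.start) >= 1
            }
            assert assign_gene_targets(regions, genes) == expected


class TestGeneSetOverlap:
    def test_identical_sets(self):
        stats = gene_set_overlap({"a", "b"}, {"a", "b"})
        assert (stats.shared, stats.fraction_of_a, stats.fraction_of_b, stats.jaccard) == (2, 1, 1, 1)

    def test_disjoint_sets(self):
        stats = gene_set_overlap({"a"}, {"b"})
        assert (stats.shared, stats.fraction_of_a, stats.fraction_of_b, stats.jaccard) == (0, 0, 0, 0)

    def test_published_scale_arithmetic(self):
        # |A|=1518 melanoma targets, |B|=1508 leukemia targets, 406 shared:
        # ~27% of either set
        a = {f"m{i}" for i in range(1518)}
        b = {f"m{i}" for i in range(406)} | {f"l{i}" for i in range(1102)}
        stats = gene_set_overlap(a, b)
        assert stats.shared == 406
        assert stats.fraction_of_a == pytest.approx(0.267, abs=5e-4)
        assert stats.fraction_of_b == pytest.approx(0.269, abs=5e-4)

    def test_symmetry(self):
        a, b = {"x", "y", "z"}, {"y", "q"}
        assert gene_set_overlap(a, b).shared == gene_set_overlap(b, a).shared
        assert gene_set_overlap(a, b).jaccard == gene_set_overlap(b, a).jaccard


class TestPlantedRecovery:
    def test_planted_shared_targets_recovered_exactly(self):
        exp = simulate_region_experiment(RegionExperimentConfig(seed=123))
        report = derive_target_report(
            exp.regions_a, exp.regions_b, exp.gene_models,
            other_context_genes=exp.truth.other_context_genes,
        )
        assert report.genes_both == exp.truth.shared_genes
        assert report.n_regions_both == len(exp.truth.shared_genes)
        assert report.overlap_with_other_context.shared == len(exp.truth.shared_genes) // 2

    def test_zero_planted_overlap_gives_empty(self):
        exp = simulate_region_experiment(
            RegionExperimentConfig(n_shared_targets=0, n_a_only=10, n_b_only=10, seed=5)
        )
        assert regions_reduced_in_both(exp.regions_a, exp.regions_b) == []

    def test_bed_round_trip_preserves_recovery(self, tmp_path):
        exp = simulate_region_experiment(RegionExperimentConfig(seed=77))
        write_bed(exp.regions_a, tmp_path / "a.bed")
        write_bed(exp.regions_b, tmp_path / "b.bed")
        write_gene_models(exp.gene_models, tmp_path / "g.bed")
        report = derive_target_report(
            read_bed(tmp_path / "a.bed"),
            read_bed(tmp_path / "b.bed"),
            read_gene_models(tmp_path / "g.bed"),
        )
        assert report.genes_both == exp.truth.shared_genes
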