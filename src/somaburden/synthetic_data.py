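"""Synthetic tumor cohorts and region experiments with ground truth.

The cohort generator emulates the statistical structure the burden analysis
assumes: per-gene per-sample Bernoulli deleterious-mutation occurrence at a
genome-wide background rate (default 0.011649), one or more driver genes at
an elevated rate (default 0.045), a UVB substitution spectrum dominated by
C→T with a minority of tandem CC→TT dinucleotide events, and passenger
noise records (synonymous or SIFT-tolerated) that the deleterious filter
must remove.  Every generated record carries a truth label, so the filter,
the supervariant collapse, and the signature summary can be checked exactly.

Coordinates live on toy chromosomes ``synth1``, ``synth2``, … so that no
code path can accidentally depend on a real reference genome.

Randomness: one master seed spawns per-component child generators (flags,
classes, coordinates, noise) via :class:`numpy.random.SeedSequence`, so the
draws of one component never perturb another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .burden import FlagMatrix
from .io_formats import (
    GeneModel,
    GenomicInterval,
    MutationRecord,
    SiftPred,
    VariantClass,
)

__all__ = [
    "SyntheticConfig",
    "RecordLabel",
    "SyntheticTruth",
    "simulate_flag_matrix",
    "simulate_cohort",
    "RegionExperimentConfig",
    "RegionExperiment",
    "simulate_region_experiment",
    "synthetic_gene_models",
]

_GENE_LEN = 10_000
_GENE_GAP = 5_000
_GENES_PER_CHROM = 50

# non-UV substitution alphabet: excludes C>T and its reverse-complement G>A
# so truth UV labels are unambiguous under either strand-normalization mode
_NON_UV_SUBS = (("A", "G"), ("G", "T"), ("A", "C"), ("T", "G"), ("C", "A"), ("T", "C"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generator parameters.

    Defaults are the study conditions of the melanoma cohort the analysis
    models: S = 470 tumor/normal pairs, background per-gene per-sample
    deleterious probability p0 = 0.011649, one driver gene at p1 = 0.045,
    and a UV fraction of 0.758 among deleterious substitutions.
    """

    G: int = 200
    S: int = 470
    p0: float = 0.011649
    drivers: tuple[tuple[int, float], ...] = ((0, 0.045),)
    f_uv: float = 0.758
    f_tandem: float = 0.10
    f_truncating: float = 0.10
    noise_rate: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G < 1 or self.S < 1:
            raise ValueError("G and S must be >= 1")
        for name in ("p0", "f_uv", "f_tandem", "f_truncating"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        for idx, p1 in self.drivers:
            if not 0 <= idx < self.G:
                raise ValueError(f"driver index {idx} outside [0, {self.G})")
            if not self.p0 <= p1 <= 1.0:
                raise ValueError(f"driver probability {p1} must be in [p0, 1]")

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.G)]

    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.S)]

    def rates(self) -> np.ndarray:
        p = np.full(self.G, self.p0)
        for idx, p1 in self.drivers:
            p[idx] = p1
        return p


def synthetic_gene_models(n_genes: int, gene_ids: Sequence[str] | None = None) -> list[GeneModel]:
    """Lay out ``n_genes`` non-overlapping gene bodies on toy chromosomes."""
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    models = []
    for i in range(n_genes):
        chrom = f"synth{i // _GENES_PER_CHROM + 1}"
        offset = (i % _GENES_PER_CHROM) * (_GENE_LEN + _GENE_GAP)
        models.append(
            GeneModel(gene=gene_ids[i], chrom=chrom, start=offset, end=offset + _GENE_LEN)
        )
    return models


def _child_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_flag_matrix(config: SyntheticConfig) -> FlagMatrix:
    """Draw the ground-truth supervariant flag matrix d_{g,s} ~ Bernoulli(p_g).

    Uses the same ``flags`` child stream as :func:`simulate_cohort`, so the
    matrix drawn here equals the truth matrix of a full cohort simulation
    with the same config.
    """
    rng = _child_rngs(config.seed, ["flags"])["flags"]
    d = (rng.random((config.G, config.S)) < config.rates()[:, None]).astype(np.uint8)
    return FlagMatrix(
        genes=tuple(config.gene_ids()), samples=tuple(config.sample_ids()), d=d
    )


@dataclass(frozen=True)
class RecordLabel:
    """Ground-truth label for one generated record."""

    deleterious: bool
    uv_class: str  # "CtoT", "CCtoTT_tandem", or "other"


@dataclass
class SyntheticTruth:
    """Everything the generator knows: flags, per-record labels, drivers, config."""

    flag_matrix: FlagMatrix
    labels: list[RecordLabel]
    drivers: tuple[tuple[int, float], ...]
    config: SyntheticConfig


def simulate_cohort(config: SyntheticConfig) -> tuple[list[MutationRecord], SyntheticTruth]:
    """Generate an annotated mutation table plus its ground truth.

    Each flagged (gene, sample) cell materializes exactly one deleterious
    record: a C→T missense (SIFT D) or a CC→TT dinucleotide with
    probability ``f_uv`` (split by ``f_tandem``), otherwise a non-UV
    substitution that is either truncating (nonsense, SIFT unavailable,
    probability ``f_truncating``) or missense SIFT D.  Deleterious records
    get population frequency < 0.001 and GERP++ > 2, matching the annotation
    profile of retained calls.  Passenger noise records (synonymous or
    missense SIFT T, Poisson(``noise_rate``) per sample) are guaranteed to
    fail the default filter.

    Output is sorted by (sample, gene, position) and is byte-identical for
    a fixed config.
    """
    rngs = _child_rngs(config.seed, ["flags", "classes", "coords", "noise"])
    d = (
        rngs["flags"].random((config.G, config.S)) < config.rates()[:, None]
    ).astype(np.uint8)
    genes = config.gene_ids()
    samples = config.sample_ids()
    models = {m.gene: m for m in synthetic_gene_models(config.G, genes)}
    matrix = FlagMatrix(genes=tuple(genes), samples=tuple(samples), d=d)

    class_rng, coord_rng, noise_rng = rngs["classes"], rngs["coords"], rngs["noise"]
    tagged: list[tuple[MutationRecord, RecordLabel]] = []

    for gi in range(config.G):
        model = models[genes[gi]]
        for si in range(config.S):
            if not d[gi, si]:
                continue
            is_uv = class_rng.random() < config.f_uv
            # 1-based position within the gene body; leave room for a dinucleotide
            pos = int(coord_rng.integers(model.start + 1, model.end - 1))
            gerp = float(np.round(2.0 + 4.0 * coord_rng.random(), 3))
            freq = float(np.round(coord_rng.random() * 9.9e-4, 6))
            if is_uv:
                if class_rng.random() < config.f_tandem:
                    ref, alt = "CC", "TT"
                    uv_class = "CCtoTT_tandem"
                else:
                    ref, alt = "C", "T"
                    uv_class = "CtoT"
                vclass, sift = VariantClass.MISSENSE, SiftPred.DELETERIOUS
            else:
                uv_class = "other"
                ref, alt = _NON_UV_SUBS[int(class_rng.integers(len(_NON_UV_SUBS)))]
                if class_rng.random() < config.f_truncating:
                    vclass, sift = VariantClass.NONSENSE, SiftPred.MISSING
                else:
                    vclass, sift = VariantClass.MISSENSE, SiftPred.DELETERIOUS
            tagged.append(
                (
                    MutationRecord(
                        sample_id=samples[si],
                        gene=genes[gi],
                        chrom=model.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        variant_class=vclass,
                        sift_pred=sift,
                        gerp=gerp,
                        pop_freq=freq,
                    ),
                    RecordLabel(deleterious=True, uv_class=uv_class),
                )
            )

    # passenger noise: synonymous or SIFT-tolerated missense, fails the filter
    n_noise = noise_rng.poisson(config.noise_rate, size=config.S)
    for si in range(config.S):
        for _ in range(int(n_noise[si])):
            gi = int(noise_rng.integers(config.G))
            model = models[genes[gi]]
            pos = int(noise_rng.integers(model.start + 1, model.end + 1))
            ref, alt = _NON_UV_SUBS[int(noise_rng.integers(len(_NON_UV_SUBS)))]
            if noise_rng.random() < 0.5:
                vclass, sift = VariantClass.SYNONYMOUS, SiftPred.MISSING
            else:
                vclass, sift = VariantClass.MISSENSE, SiftPred.TOLERATED
            tagged.append(
                (
                    MutationRecord(
                        sample_id=samples[si],
                        gene=genes[gi],
                        chrom=model.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        variant_class=vclass,
                        sift_pred=sift,
                        gerp=float(np.round(noise_rng.random() * 2.0, 3)),
                        pop_freq=float(np.round(noise_rng.random() * 0.05, 6)),
                    ),
                    RecordLabel(deleterious=False, uv_class="other"),
                )
            )

    tagged.sort(key=lambda pair: (pair[0].sample_id, pair[0].gene, pair[0].pos, pair[0].ref))
    records = [rec for rec, _ in tagged]
    labels = [lab for _, lab in tagged]
    truth = SyntheticTruth(
        flag_matrix=matrix, labels=labels, drivers=config.drivers, config=config
    )
    return records, truth


@dataclass(frozen=True)
class RegionExperimentConfig:
    """Parameters for the two-condition differential-region simulation."""

    n_genes: int = 50
    n_shared_targets: int = 20
    n_a_only: int = 10
    n_b_only: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_shared_targets + self.n_a_only + self.n_b_only > self.n_genes:
            raise ValueError("planted gene groups exceed the gene universe")


@dataclass
class RegionTruth:
    shared_genes: set[str]
    a_only_genes: set[str]
    b_only_genes: set[str]
    other_context_genes: set[str]
    config: RegionExperimentConfig


@dataclass
class RegionExperiment:
    regions_a: list[GenomicInterval]
    regions_b: list[GenomicInterval]
    gene_models: list[GeneModel]
    truth: RegionTruth


def simulate_region_experiment(config: RegionExperimentConfig) -> RegionExperiment:
    """Plant differential regions so the downstream derivation is exactly known.

    Shared-target genes get one region in each condition, mutually
    overlapping inside the gene body; condition-private genes get a region
    in only one condition.  An "other cellular context" gene list is built
    from half of the shared targets plus context-private names, so the
    cross-context overlap count is known by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    models = synthetic_gene_models(config.n_genes)
    order = rng.permutation(config.n_genes)
    n_sh, n_a, n_b = config.n_shared_targets, config.n_a_only, config.n_b_only
    shared_idx = order[:n_sh]
    a_idx = order[n_sh : n_sh + n_a]
    b_idx = order[n_sh + n_a : n_sh + n_a + n_b]

    regions_a: list[GenomicInterval] = []
    regions_b: list[GenomicInterval] = []
    for gi in shared_idx:
        m = models[gi]
        start = int(rng.integers(m.start, m.end - 2000))
        shift = int(rng.integers(200, 600))  # partial overlap between conditions
        regions_a.append(GenomicInterval(m.chrom, start, start + 1000, name=f"A_{m.gene}"))
        regions_b.append(
            GenomicInterval(m.chrom, start + shift, start + shift + 1000, name=f"B_{m.gene}")
        )
    for gi in a_idx:
        m = models[gi]
        start = int(rng.integers(m.start, m.end - 1000))
        regions_a.append(GenomicInterval(m.chrom, start, start + 800, name=f"A_{m.gene}"))
    for gi in b_idx:
        m = models[gi]
        start = int(rng.integers(m.start, m.end - 1000))
        regions_b.append(GenomicInterval(m.chrom, start, start + 800, name=f"B_{m.gene}"))

    shared_genes = {models[i].gene for i in shared_idx}
    half = sorted(shared_genes)[: len(shared_genes) // 2]
    other_context = set(half) | {f"CTX{i:04d}" for i in range(25)}
    truth = RegionTruth(
        shared_genes=shared_genes,
        a_only_genes={models[i].gene for i in a_idx},
        b_only_genes={models[i].gene for i in b_idx},
        other_context_genes=other_context,
        config=config,
    )
    return RegionExperiment(
        regions_a=regions_a, regions_b=regions_b, gene_models=models, truth=truth
    )
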