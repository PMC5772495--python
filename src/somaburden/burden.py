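"""Gene-based burden testing of per-gene deleterious supervariant flags.

A *supervariant* collapses all qualifying variants of a gene in one sample
into a single binary flag: d_{g,s} = 1 if sample *s* carries at least one
deleterious mutation in gene *g*, else 0.  Each gene's flagged fraction
k_g / S is tested against the cohort-wide background rate

    r̄ = (1/G) Σ_g k_g / S = (Σ d) / (G · S),

the mean per-gene deleterious rate over the full gene universe (genes with
no qualifying mutation contribute zero flags and dilute the background).

The default test is the exact one-sided binomial upper tail
P(X ≥ k | n = S, p = r̄), evaluated via the survival function so that tail
probabilities far below 1e-12 remain accurate; a Poisson-tail alternative
(λ = S·r̄) is available.  Multiple testing is controlled by
Benjamini–Hochberg across all genes in the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MutationRecord, ValidationError

__all__ = [
    "FlagMatrix",
    "BurdenResult",
    "collapse_supervariants",
    "background_rate",
    "burden_test",
    "run_burden",
]


@dataclass(frozen=True)
class FlagMatrix:
    """Genes × samples binary deleterious supervariant flags."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    d: np.ndarray  # shape (G, S), values in {0, 1}

    def __post_init__(self) -> None:
        if len(self.genes) < 1 or len(self.samples) < 1:
            raise ValidationError("FlagMatrix needs at least one gene and one sample")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene ids must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample ids must be unique")
        d = np.asarray(self.d)
        if d.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"flag matrix shape {d.shape} does not match "
                f"({len(self.genes)}, {len(self.samples)})"
            )
        if not np.isin(d, (0, 1)).all():
            raise ValidationError("flags must be 0 or 1")
        object.__setattr__(self, "d", d.astype(np.uint8))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def flagged_counts(self) -> np.ndarray:
        """Per-gene number of flagged samples, k_g."""
        return self.d.sum(axis=1).astype(int)


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    k: int
    S: int
    rate: float
    background: float
    p: float
    q: float


def collapse_supervariants(
    records: Iterable[MutationRecord],
    cohort_samples: Sequence[str],
    gene_universe: Sequence[str] | None = None,
    strict: bool = True,
) -> FlagMatrix:
    """Collapse kept records into one binary supervariant flag per (gene, sample).

    d_{g,s} = 1 iff at least one record maps to (g, s); multiple records in
    the same cell still count once.  Samples with no records appear as
    all-zero columns, and genes in ``gene_universe`` with no records appear
    as all-zero rows (they dilute the background exactly as a full gene
    universe does).

    With ``strict=True`` a record whose sample is not in ``cohort_samples``
    raises; with ``strict=False`` the cohort is extended in order of first
    appearance.
    """
    records = list(records)
    samples = list(dict.fromkeys(cohort_samples))
    if len(samples) != len(cohort_samples):
        raise ValidationError("cohort_samples contains duplicates")
    sample_index = {s: i for i, s in enumerate(samples)}

    genes_seen = list(dict.fromkeys(r.gene for r in records))
    if gene_universe is None:
        genes = genes_seen
    else:
        genes = list(dict.fromkeys(gene_universe))
        if len(genes) != len(gene_universe):
            raise ValidationError("gene_universe contains duplicates")
        missing = set(genes_seen) - set(genes)
        if missing:
            raise ValidationError(
                f"records name gene(s) outside the universe: {sorted(missing)[:5]}"
            )
    if not genes:
        raise ValidationError("no genes: provide records or a gene_universe")
    gene_index = {g: i for i, g in enumerate(genes)}

    for rec in records:
        if rec.sample_id not in sample_index:
            if strict:
                raise ValidationError(
                    f"sample {rec.sample_id!r} not in cohort (strict mode)"
                )
            sample_index[rec.sample_id] = len(samples)
            samples.append(rec.sample_id)

    d = np.zeros((len(genes), len(samples)), dtype=np.uint8)
    for rec in records:
        d[gene_index[rec.gene], sample_index[rec.sample_id]] = 1
    return FlagMatrix(genes=tuple(genes), samples=tuple(samples), d=d)


def background_rate(matrix: FlagMatrix) -> float:
    """Mean per-gene deleterious rate: (Σ flags) / (G · S).

    Computed as an exact integer flag count divided by the integer product
    G·S, so the result is the correctly rounded float of a rational number.
    """
    total = int(matrix.d.sum())
    return total / (matrix.n_genes * matrix.n_samples)


def burden_test(k: int, S: int, background: float, method: str = "binomial") -> float:
    """One-sided upper-tail p-value for k flagged samples out of S.

    ``binomial`` (default): exact P(X ≥ k), X ~ Binomial(S, background).
    ``poisson``: P(X ≥ k), X ~ Poisson(S · background) — a large-cohort
    approximation for comparison.

    p = 1 when k = 0 (the upper tail at zero is the whole distribution).
    """
    if not 0 <= k <= S:
        raise ValueError(f"k must satisfy 0 <= k <= S, got k={k}, S={S}")
    if not 0.0 <= background <= 1.0:
        raise ValueError(f"background rate must be in [0, 1], got {background}")
    if k == 0:
        return 1.0
    if method == "binomial":
        p = float(stats.binom.sf(k - 1, S, background))
    elif method == "poisson":
        p = float(stats.poisson.sf(k - 1, S * background))
    else:
        raise ValueError(f"unknown method {method!r} (expected 'binomial' or 'poisson')")
    return min(p, 1.0)


def run_burden(
    matrix: FlagMatrix,
    method: str = "binomial",
    background: float | None = None,
    leave_one_out: bool = False,
) -> list[BurdenResult]:
    """Test every gene in the matrix against the background rate.

    The background defaults to :func:`background_rate` over all genes,
    including the tested gene; ``leave_one_out=True`` recomputes the
    background per gene excluding that gene's own flags (a sensitivity
    analysis).  An explicit ``background`` overrides both.

    q-values are Benjamini–Hochberg across all G genes.  Results are sorted
    by p ascending with gene id as a stable tie-break.
    """
    ks = matrix.flagged_counts()
    S = matrix.n_samples
    G = matrix.n_genes
    total = int(ks.sum())

    pvals = np.empty(G)
    backgrounds = np.empty(G)
    for i, k in enumerate(ks):
        if background is not None:
            bg = background
        elif leave_one_out and G > 1:
            bg = (total - int(k)) / ((G - 1) * S)
        else:
            bg = total / (G * S)
        backgrounds[i] = bg
        pvals[i] = burden_test(int(k), S, bg, method=method)

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        BurdenResult(
            gene=matrix.genes[i],
            k=int(ks[i]),
            S=S,
            rate=int(ks[i]) / S,
            background=float(backgrounds[i]),
            p=float(pvals[i]),
            q=float(qvals[i]),
        )
        for i in range(G)
    ]
    results.sort(key=lambda r: (r.p, r.gene))
    return results
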