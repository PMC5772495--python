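# somaburden

Gene-based somatic-mutation burden analysis for tumor cohorts, built around
the question: *is a given gene hit by deleterious somatic mutations more
often than the genome-wide average?* The package grew out of the melanoma
case of the histone methyltransferase gene *DOT1L*, which is recurrently
inactivated by ultraviolet-signature mutations, but every stage is generic.

It provides four analysis stages plus a ground-truth simulator:

1. **Deleterious filtering** — reduce annotated somatic calls (MAF-like
   TSV) to likely-deleterious records: synonymous calls are excluded,
   nonsynonymous calls must carry a SIFT "D" (deleterious) prediction, and
   truncating classes (nonsense / frameshift / splice) auto-pass because
   SIFT cannot score them. Optional population-frequency and GERP++
   conservation thresholds are available as switches.
2. **Supervariant burden testing** — collapse all qualifying variants of a
   gene in a sample into one binary flag d_{g,s} ∈ {0,1}; a gene's
   deleterious rate is k_g/S (flagged samples over cohort size) and the
   genome-wide background is r̄ = (Σ d)/(G·S). Each gene is tested with the
   exact one-sided binomial upper tail P(X ≥ k | n=S, p=r̄) (Poisson tail
   optional), with Benjamini–Hochberg control across genes.
3. **UVB-signature classification** — classify substitutions as C→T,
   tandem CC→TT (adjacent same-sample C→T calls are merged
   deterministically), or other, and summarize the UV fraction. Literal
   strand reading by default; reverse-complement folding (G→A) is a switch.
4. **Histone-mark target assignment** — from two BED sets of regions with
   reduced mark signal (e.g. MACS2 `bdgdiff` output for H3K79me2 under
   DOT1L knockdown vs. mutation), find regions reduced in both conditions,
   assign them to gene bodies (≥1 bp overlap, configurable), and compare
   target-gene sets across cellular contexts.

The synthetic-data module generates cohorts with per-gene Bernoulli
mutation occurrence (background 0.011649, driver genes at 0.045 by
default), a UV-dominated substitution spectrum (75.8% C→T/CC→TT), and
passenger noise that the filter must remove — with full ground truth, so
every stage is validated end to end without external downloads.

## Worked example

```python
from somaburden import (apply_filter, collapse_supervariants, burden_test,
                        summarize_signature)
from somaburden.datasets import (dot1l_like_annovar_table,
                                 dot1l_like_missense_table, COHORT_SIZE)

calls = dot1l_like_annovar_table()            # 37 annotated somatic calls
result = apply_filter(calls)
print(f"kept {len(result.kept)}/{len(calls)} likely-deleterious records")

samples = sorted({r.sample_id for r in result.kept})
cohort = samples + [f"PAD-{i:03d}" for i in range(COHORT_SIZE - len(samples))]
matrix = collapse_supervariants(result.kept, cohort)
k = int(matrix.flagged_counts()[0])
print(f"supervariant rate: {k}/{COHORT_SIZE} = {k / COHORT_SIZE:.3f}")
print(f"exact binomial upper tail vs background 0.011649: "
      f"p = {burden_test(k, COHORT_SIZE, 0.011649):.3g}")

summary = summarize_signature(dot1l_like_missense_table())
print(f"UV signature: {summary.n_uv}/{summary.n_total} "
      f"({100 * summary.fraction_uv:.1f}%), {summary.n_tandem_events} tandem events")
```

prints

```
kept 23/37 likely-deleterious records
supervariant rate: 21/470 = 0.045
exact binomial upper tail vs background 0.011649: p = 2.71e-07
UV signature: 25/33 (75.8%), 2 tandem events
```

Reading the numbers: of 37 annotated calls in the gene, 23 survive the
deleterious filter; they fall in 21 distinct tumors of the 470-sample
cohort, a per-gene rate of 4.5% against a genome-wide background of 1.16%,
which an exact binomial test calls significant at p ≈ 2.7×10⁻⁷. Three in
four of the missense calls carry the UVB fingerprint. The
`dot1l_like_*` tables are synthetic reconstructions that match the
published marginal counts of the melanoma *DOT1L* analysis; see their
docstrings.

The same stages are exposed on the command line:

```bash
somaburden simulate --out-dir sim/ --seed 1
somaburden filter --in sim/muts.tsv --out kept.tsv --report reasons.json
somaburden burden --muts kept.tsv --out burden.tsv
somaburden signature --muts kept.tsv --out signature.json
somaburden targets --cond-a sim/regions_a.bed --cond-b sim/regions_b.bed \
    --genes sim/genes.bed --out targets.json
somaburden run --config run.yaml        # all stages from one YAML config
```

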