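# Methods

## The statistical model

The unit of analysis is the **supervariant**: for gene *g* and sample *s*,
d_{g,s} = 1 if the sample carries at least one likely-deleterious somatic
mutation in the gene, else 0. Collapsing to a binary flag makes the
per-gene statistic a sample count rather than a mutation count, so a
hypermutated sample contributes at most once per gene.

With G genes and S samples the genome-wide background rate is the mean
per-gene rate

    r̄ = (1/G) Σ_g k_g / S = (Σ_{g,s} d_{g,s}) / (G·S),

where k_g is gene *g*'s flagged-sample count. The estimate includes the
tested gene (a leave-one-out variant exists as a sensitivity analysis);
genes with no qualifying mutation contribute zero flags, so supplying the
full gene universe — not just mutated genes — matters for the denominator.
The computation is an integer flag total divided by the integer G·S, i.e.
the correctly rounded float of an exact rational.

Each gene is tested one-sided against the background:

    p_g = P(X ≥ k_g),  X ~ Binomial(S, r̄),

evaluated through the survival function so tails far below 1e-12 keep full
relative accuracy (verified against arbitrary-precision rational summation).
p = 1 at k = 0 by construction. The binomial is the natural model when the
background is a per-sample probability; a Poisson tail with λ = S·r̄ is
available behind a flag for comparison with rate-based conventions. The
test treats r̄ as known; with ~19,500 genes estimating it, the plug-in
error is negligible for any single gene, but p-values for the very genes
that dominate the flag total are slightly conservative under leave-one-out.

Multiple testing uses Benjamini–Hochberg across all G genes in the matrix.
The published single-gene analysis reported only a raw p; FDR control
across the gene universe is this package's own addition and the q column is
labelled as such in the output.

Because the test statistic is discrete, the attained size at level α is
P(X ≥ k*) for the smallest k* with a tail ≤ α, which is strictly below α
(0.0238 at α = 0.05 for S = 470, r̄ = 0.011649). Calibration tests
therefore compare the empirical rejection rate to the attained size, not to
α, and additionally check it never exceeds α.

## Deleterious filter

Rules are applied in a fixed order — synonymous → SIFT → population
frequency → GERP++ — so exclusion-reason counts are deterministic:

1. synonymous variants are excluded;
2. other variants need SIFT prediction "D", except truncating classes
   (nonsense, frameshift, splice), which auto-pass: a stop-gain such as the
   recurrent Q1017X-type truncation has no SIFT score yet is unambiguously
   damaging. A missing SIFT call on a missense variant excludes it
   (conservative: only flagged-D calls are kept);
3. optional thresholds: population frequency ≤ `max_pop_freq`, GERP++ ≥
   `min_gerp`. Both default **off**: very low variant frequency (<0.001)
   and high conservation (GERP++ > 2) are reported properties of retained
   melanoma calls, not clearly stated selection rules, so the package
   supports both readings without asserting either. Records missing the
   annotation pass an enabled threshold (the thresholds filter on observed
   evidence only).

## UV-signature classification

A substitution is a UVB-signature event if it is C→T or a tandem CC→TT
dinucleotide change. Adjacent single-base C→T calls (same sample, same
chromosome, positions p and p+1) are merged into one tandem event by a
greedy left-to-right scan over records sorted by (sample, chromosome,
position); each record joins at most one event and the pairing is
order-invariant. Summaries can count per record (both members of a pair
count; the default, which matches mutation-table accounting) or per event.

`normalize_strand=False` is the default: the classes are counted exactly as
written. The reverse-complement fold (G→A, GG→AA) used in
trinucleotide-signature work is a switch; on the reference missense table
the literal reading reproduces the published 25/33 count while folding
gives 27/33, which is what fixes the default. Dipyrimidine flanking-context
checks are deliberately out of scope — they need a reference sequence and
the classification rule here is purely substitution-based.

## Region → gene-body target assignment

"Reduced in both conditions" has two selectable semantics because
differential-peak overlap conventions vary and no single rule is canonical:

* `reference` (default): count each region of condition A that overlaps the
  merged condition-B set by ≥ `min_overlap` bp (default 1). Counts are then
  directly comparable to A's region total.
* `intersection`: the set intersection of the two merged region sets,
  emitted as disjoint clipped pieces; invariant to splitting inputs into
  adjacent fragments.

A gene is a target when ≥1 both-reduced region overlaps its gene body — the
annotated start-to-end interval supplied in the gene-model BED; the package
does not derive gene bodies from transcript structure. A region spanning
several gene bodies contributes to each; genes are counted once. Cross-
context comparison reports the shared count, the fraction of each set, and
Jaccard.

Reproducing the published ChIP-seq-scale numbers (4425 and 1947 reduced
regions, 1647 in both, 1518 melanoma target genes, 406 genes shared with
leukemia) additionally requires the raw GEO data (GSE89029), read
alignment, and MACS2 `bdgdiff` with a logLR cutoff of 3 upstream, plus
annotation choices those analyses did not fully specify; this package
implements the downstream operations exactly but makes no claim about
those counts. They are exercised here on synthetic region sets with
planted truth instead.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions of the melanoma cohort the analysis
models: S = 470 samples, background p0 = 0.011649 per gene per sample, one
driver gene at p1 = 0.045, UV fraction f_uv = 0.758 among deleterious
substitutions. Two parameters have no published value and were fixed once
at field-plausible levels: f_tandem = 0.10 (tandem CC→TT is the rarer UV
hallmark, a minor fraction of UV events) and noise_rate = 2.0 passenger
records per sample (enough that an unfiltered analysis would be visibly
wrong). The default G = 200 genes keeps simulated matrices small; the
background is a per-gene probability, so results scale to larger universes.

Draw order is per component — flags, then classes, then coordinates, then
noise — with child seeds derived from the master seed, so the flag matrix
drawn by the fast path (`simulate_flag_matrix`) is bit-identical to the
truth matrix of a full cohort simulation with the same config.

Deliberate simplifications, and hence limits on what passing tests show
about real data:

* flags are independent across genes and samples — no hypermutator
  samples, no covariation with replication timing or expression, no
  per-sample mutation-load adjustment;
* each flagged cell emits exactly one deleterious record (multi-hit cells
  are exercised by handcrafted tests instead);
* non-UV substitutions are drawn from an alphabet excluding both C→T and
  G→A, so UV truth labels are unambiguous under either strand mode;
* coordinates are uniform within toy gene bodies on `synth*` chromosomes —
  no trinucleotide context, no real genome;
* deleterious records are annotated with frequency < 0.001 and GERP++ > 2,
  matching the observed profile of retained calls, so the optional
  thresholds do not remove true positives in simulation.

The reference fixtures in `somaburden.datasets` are labelled synthetic
reconstructions: they reproduce the published marginal counts (37 calls →
23 kept over 21 samples with one recurrent position in two samples; 33
missense with 25 UV) while sample identifiers, positions and alleles are
invented.

## Numerical and design notes

* Mutation positions are 1-based inclusive (MAF convention); all interval
  work is 0-based half-open (BED convention). Conversions happen only at
  module boundaries. Chromosome names are opaque strings — no "chr"
  normalization, to avoid silent cross-build mixing.
* Burden results are sorted by p ascending with gene id as the stable
  tie-break; sample or record order never changes a result.
* The published analysis quoted p = 6.44×10⁻⁸ for the 21/470 gene without
  naming the test; the exact one-sided binomial with those inputs gives
  2.71×10⁻⁷ (verified by rational-arithmetic summation). The package
  asserts its own exact value and makes no attempt to reverse-engineer the
  published figure.
* The published cohort size appears as both 470 and 473 in different
  places; cohort size is always an explicit input here, and 470 is used in
  the examples and acceptance runs.
* Acceptance simulations use G = 200 genes, 500 null cohorts for type-I
  calibration and 2000 replicates for power, sizes at which Monte-Carlo
  intervals are tight enough to detect a miscalibrated test while the whole
  script completes in seconds.
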