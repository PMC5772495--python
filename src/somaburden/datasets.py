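"""Built-in reference fixtures for the DOT1L-style melanoma analysis.

These tables are **synthetic reconstructions**: the original supplementary
mutation lists are not redistributed here, so the fixtures are constructed
to match the published marginal counts exactly —

* an ANNOVAR-style table of 37 annotated DOT1L somatic calls, of which 23
  pass the deleterious filter (synonymous and SIFT-tolerated calls are
  excluded, the Q1017X-style truncation auto-passes), spanning 21 distinct
  flagged samples, with one recurrent position (chr19:2225413) seen in two
  samples;
* a 33-record missense table in which 25 records (75.8%) are literal C→T
  or CC→TT UVB-signature mutations, including one tandem pair of adjacent
  C→T calls and one CC→TT dinucleotide call.

Individual sample identifiers, residue-level positions and allele choices
are invented; only the headline counts are faithful.
"""

from __future__ import annotations

from .io_formats import MutationRecord, SiftPred, VariantClass

__all__ = ["dot1l_like_annovar_table", "dot1l_like_missense_table", "COHORT_SIZE"]

#: Cohort size of the melanoma tumor/normal cohort the fixtures emulate.
COHORT_SIZE = 470

_GENE = "DOT1L"
_CHROM = "chr19"


def _rec(sample, pos, ref, alt, vclass, sift, gerp=None, freq=None) -> MutationRecord:
    return MutationRecord(
        sample_id=sample,
        gene=_GENE,
        chrom=_CHROM,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=vclass,
        sift_pred=sift,
        gerp=gerp,
        pop_freq=freq,
    )


def dot1l_like_annovar_table() -> list[MutationRecord]:
    """Synthetic 37-row ANNOVAR-style DOT1L mutation table.

    23 rows pass the default deleterious filter (22 missense SIFT-D rows —
    including the recurrent chr19:2225413 C→T observed in two samples — and
    one nonsense truncation without a SIFT score), across 21 distinct
    samples: MEL-01 and MEL-02 each carry two deleterious rows.  The other
    14 rows are the excluded calls: 7 synonymous and 7 SIFT-tolerated
    missense.
    """
    M, D, T = VariantClass.MISSENSE, SiftPred.DELETERIOUS, SiftPred.TOLERATED
    rows = [
        # recurrent position in two samples
        _rec("MEL-01", 2225413, "C", "T", M, D, gerp=4.9, freq=0.0002),
        _rec("MEL-03", 2225413, "C", "T", M, D, gerp=4.9, freq=0.0002),
        # second deleterious mutations for the two doubly-hit samples
        _rec("MEL-01", 2164961, "C", "T", M, D, gerp=3.8, freq=0.0003),
        _rec("MEL-02", 2171204, "C", "T", M, D, gerp=4.1, freq=0.0001),
        _rec("MEL-02", 2184330, "G", "T", M, D, gerp=2.9, freq=0.0004),
        # singleton deleterious missense calls, one per sample
        _rec("MEL-04", 2165378, "C", "T", M, D, gerp=5.2, freq=0.0001),
        _rec("MEL-05", 2168822, "C", "T", M, D, gerp=3.3, freq=0.0002),
        _rec("MEL-06", 2173015, "C", "T", M, D, gerp=4.6, freq=0.0001),
        _rec("MEL-07", 2175940, "CC", "TT", M, D, gerp=5.0, freq=0.0001),
        _rec("MEL-08", 2179511, "C", "T", M, D, gerp=2.7, freq=0.0005),
        _rec("MEL-09", 2183062, "C", "T", M, D, gerp=3.9, freq=0.0002),
        _rec("MEL-10", 2187777, "G", "A", M, D, gerp=4.4, freq=0.0001),
        _rec("MEL-11", 2190248, "C", "T", M, D, gerp=5.6, freq=0.0001),
        _rec("MEL-12", 2194605, "C", "T", M, D, gerp=3.1, freq=0.0003),
        _rec("MEL-13", 2198122, "C", "T", M, D, gerp=4.0, freq=0.0002),
        _rec("MEL-14", 2202489, "C", "T", M, D, gerp=2.8, freq=0.0006),
        _rec("MEL-15", 2206934, "C", "T", M, D, gerp=5.1, freq=0.0001),
        _rec("MEL-16", 2210357, "G", "A", M, D, gerp=3.5, freq=0.0003),
        _rec("MEL-17", 2214706, "C", "T", M, D, gerp=4.8, freq=0.0001),
        _rec("MEL-18", 2218943, "C", "T", M, D, gerp=3.6, freq=0.0002),
        _rec("MEL-19", 2222851, "C", "T", M, D, gerp=4.2, freq=0.0002),
        _rec("MEL-20", 2228130, "C", "T", M, D, gerp=2.5, freq=0.0004),
        # Q1017X-style truncation: no SIFT score, auto-passes as truncating
        _rec("MEL-21", 2226485, "C", "T", VariantClass.NONSENSE, SiftPred.MISSING,
             gerp=5.4, freq=0.0001),
        # excluded: synonymous
        _rec("MEL-22", 2166100, "C", "T", VariantClass.SYNONYMOUS, SiftPred.MISSING),
        _rec("MEL-23", 2170412, "G", "A", VariantClass.SYNONYMOUS, SiftPred.MISSING),
        _rec("MEL-24", 2176933, "C", "T", VariantClass.SYNONYMOUS, SiftPred.MISSING),
        _rec("MEL-05", 2181258, "T", "C", VariantClass.SYNONYMOUS, SiftPred.MISSING),
        _rec("MEL-25", 2189704, "C", "T", VariantClass.SYNONYMOUS, SiftPred.MISSING),
        _rec("MEL-26", 2199381, "A", "G", VariantClass.SYNONYMOUS, SiftPred.MISSING),
        _rec("MEL-27", 2207846, "C", "T", VariantClass.SYNONYMOUS, SiftPred.MISSING),
        # excluded: missense predicted tolerated
        _rec("MEL-28", 2167555, "C", "T", M, T, gerp=1.2, freq=0.0020),
        _rec("MEL-29", 2174090, "A", "G", M, T, gerp=0.8, freq=0.0015),
        _rec("MEL-12", 2185521, "C", "A", M, T, gerp=1.9, freq=0.0008),
        _rec("MEL-30", 2192263, "G", "T", M, T, gerp=0.3, freq=0.0031),
        _rec("MEL-31", 2200918, "C", "T", M, T, gerp=1.5, freq=0.0012),
        _rec("MEL-32", 2212379, "T", "A", M, T, gerp=0.6, freq=0.0044),
        _rec("MEL-33", 2220104, "C", "T", M, T, gerp=1.1, freq=0.0009),
    ]
    assert len(rows) == 37
    return rows


def dot1l_like_missense_table() -> list[MutationRecord]:
    """Synthetic 33-record DOT1L missense table with 25 UV-signature calls.

    UV content as written on the reported strand: 22 isolated C→T records,
    one tandem pair of adjacent C→T records in the same sample
    (chr19:2203410-2203411), and one CC→TT dinucleotide record — 25 records
    in total.  The 8 non-UV records include two G→A transitions, so
    strand-normalized counting would give 27/33 instead: the literal
    (non-normalized) rule is the one that reproduces 25/33.
    """
    M, D = VariantClass.MISSENSE, SiftPred.DELETERIOUS
    uv_positions = [
        2164961, 2165378, 2168822, 2171204, 2173015, 2175940, 2179511,
        2183062, 2187777, 2190248, 2194605, 2198122, 2202489, 2206934,
        2210357, 2214706, 2218943, 2222851, 2225413, 2226485, 2228130,
        2230019,
    ]
    rows = [_rec(f"MM-{i + 1:02d}", pos, "C", "T", M, D, gerp=4.0, freq=0.0002)
            for i, pos in enumerate(uv_positions)]
    # tandem pair: adjacent single-base C>T calls in one sample
    rows.append(_rec("MM-23", 2203410, "C", "T", M, D, gerp=4.7, freq=0.0001))
    rows.append(_rec("MM-23", 2203411, "C", "T", M, D, gerp=4.7, freq=0.0001))
    # dinucleotide CC>TT call
    rows.append(_rec("MM-24", 2216088, "CC", "TT", M, D, gerp=5.1, freq=0.0001))
    # non-UV missense: note the two G>A rows fold into C>T only under
    # strand normalization
    rows.append(_rec("MM-25", 2166702, "G", "A", M, D, gerp=3.2, freq=0.0003))
    rows.append(_rec("MM-26", 2169914, "G", "A", M, D, gerp=2.9, freq=0.0002))
    rows.append(_rec("MM-27", 2177305, "C", "A", M, D, gerp=3.8, freq=0.0004))
    rows.append(_rec("MM-28", 2186420, "C", "A", M, D, gerp=2.6, freq=0.0002))
    rows.append(_rec("MM-29", 2193577, "G", "T", M, D, gerp=3.4, freq=0.0001))
    rows.append(_rec("MM-30", 2205249, "T", "C", M, D, gerp=2.8, freq=0.0005))
    rows.append(_rec("MM-31", 2213668, "A", "C", M, D, gerp=3.0, freq=0.0002))
    rows.append(_rec("MM-32", 2224091, "G", "C", M, D, gerp=2.4, freq=0.0003))
    assert len(rows) == 33
    return rows
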