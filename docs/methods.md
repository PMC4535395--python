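# Methods

## The measurement model

Bisulfite treatment of RNA deaminates unmethylated cytosine to uracil;
after cDNA synthesis and sequencing an unmethylated C reads as T while
5-methylcytosine (and any other conversion-resistant cytosine
modification) reads as C. At a reference cytosine covered by reads, percent
methylation is estimated as

    m̂ = n_C / (n_C + n_T)

where `n_C` and `n_T` are the (fractionally weighted) counts of reads
showing C and T at that position. Bases other than C/T are treated as
sequencing noise and excluded from the denominator. With conversion
efficiency `e` (probability an unmethylated C reads T) and over-conversion
`o` (probability a methylated C reads T), the expected observed fraction at
a site of true methylation `m` is

    E[m̂] = m·(1 − o) + (1 − m)·(1 − e)

so at `e = 0.99` an unmethylated site floats near 1% observed methylation —
far below the 20% calling threshold. Sites passing the thresholds are
reported as *candidate* m⁵C sites: the assay cannot distinguish m⁵C from
other bisulfite-resistant cytosine modifications.

## Thresholds and quality gates

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 5 reads | below this a site is `no_call` (blank in heatmaps, never 0%) |
| `min_methylation` | 0.20 | calling threshold; the boundary is inclusive (≥) |
| `min_conversion` | 0.98 | spike-in gate; libraries below it are rejected before calling |
| `max_mismatch` | 2 | three-letter mismatch allowance per read |
| `identity` | 0.95 | isodecoder collapsing threshold (global identity) |
| reduced margin | 0.20 absolute | `reduced` call in genotype comparisons |

The conversion gate is an *aggregate* rate: pooled `ΣT / Σ(C+T)` over all
spike-in cytosines, not a per-cytosine minimum — a per-cytosine 98%
requirement is unattainable at realistic per-site depth, while the pooled
rate is a stable estimate of library-wide conversion. Per-cytosine rates
are still reported for inspection. Site calling from a failed library
raises rather than returning flagged calls, because every downstream count
would be confounded by non-conversion.

No multiple-testing correction is applied: sites are called by the hard
coverage/percentage thresholds. A one-sided binomial test against the
`1 − e` non-conversion null is available as an optional annotation
(`annotate_binomial`), not as the calling rule.

## Reference collapsing

tRNA genes are grouped by (amino acid, anticodon) and single-linkage
clustered at ≥ 95% global identity (pairwise global alignment; identity =
identical aligned pairs / longer length). Each cluster yields a consensus
by per-position majority vote, with exact ties written as IUPAC ambiguity
codes; members of non-modal length vote through a pairwise alignment to a
modal-length anchor, and insertions relative to the anchor do not vote.
The largest cluster in a group takes the plain `<aa>-<anticodon>` name;
minority isodecoders are suffixed `-1`, `-2`, … in decreasing size order
(ties broken by smallest member gene id). The genome-of-origin set of a
consensus is the union over members, so a sequence encoded identically in
two genomes becomes one consensus of ambiguous origin. Mature sequences
are expected intron-free; the 3′ CCA is included only if present in the
annotated input. N content above 10% is rejected.

## Alignment

Reads and references are compared in three-letter space: the read is C→T
collapsed and matched ungapped against C→T converted references, so an
unconverted methylated C aligns cleanly while a read C over a reference
non-C position still counts as a mismatch (sense-strand libraries only; no
G→A space). Alignment is a k-mer seed-and-extend index: for mismatch
allowance `M`, the read is split into `M + 1` disjoint seeds of length
`min(12, ⌊L/(M+1)⌋)`; by pigeonhole any placement with ≤ M mismatches
contains an exact seed, so the candidate set is lossless and the result
equals an exhaustive scan over every offset — which the test suite verifies
against an independent brute-force scorer. Ties within a reference resolve
to the leftmost offset; ties across references return all co-champions,
sorted lexicographically so results are independent of input order.
Ambiguous reads contribute `1/k` to each of their `k` co-champions'
pileups, preserving total counts without inventing a resolution rule.
Ungapped matching keeps the brute-force oracle exact; reads with indels
simply fail to align, which for 65–95 nt reads on short structural RNAs is
a negligible loss.

## Structural coordinates

tRNA sites are numbered on the classical cloverleaf frame (acceptor stem
1–7/66–72, anticodon 34–36, variable region after 43, T-arm through 72).
The scaffold is a coordinate frame rather than a sequence, so the mapping
is computed by deterministic segment anchoring: the anticodon triplet is
anchored at 34–36, the seven following bases take 37–43, the last 24 bases
take 49–72 (anchoring the acceptor end at 72), and the remaining middle
bases fill variable-region labels 44–48 — surplus bases are left unmapped
(long variable loops) and deficits skip labels. Sub-numbered insertion
positions (47a-style) are intentionally not assigned. When the anticodon
string occurs more than once, the placement whose flanking segment lengths
best fit the canonical frame wins; an exact tie is an error listing the
candidates rather than a silent choice.

rRNA sites are numbered on the anchor species' coordinates: each species
sequence is globally aligned to the anchor (match +1, mismatch −1, gap
open −5, extend −1) and positions lift through match/mismatch columns
only; gap columns are unmappable, and a lift under 50% identity is flagged
rather than rejected. Species lacking a curated rRNA sequence can derive
one from ordinary RNA-seq: reads are aligned to the anchor and the
majority base replaces the anchor base wherever depth reaches a minimum
(default 10), recovering species-specific SNPs; low-depth positions keep
the anchor base and are flagged.

## Conservation classes

A shared position methylated in at least one species is classified from the
per-species states: class 1 — methylated (≥ the 20% threshold) in every
classifiable species; class 2 — methylated in all but one, which carries a
SNP at the position; class 3 — methylated somewhere while the cytosine is
present but unmethylated elsewhere. Species below coverage are excluded
from the decision rather than counted as unmethylated, so depth artifacts
cannot demote a class; an ambiguous reference base (IUPAC) likewise
excludes its species. A site classifiable in fewer than three species
(configurable) is `unclassified`, as is a no-methylation pattern or one
with two or more SNP species. "Highly conserved" is operationalised as the
calling threshold itself; no separate conservation threshold is imposed.

## Methyl-chop / dCAPS prediction

PCR is modeled as deterministic single-amplicon extraction: each primer
must anneal uniquely within 2 mismatches, with the 3′-terminal two bases
exact, and primer bases (including dCAPS mismatches) overwrite the
template inside the primer footprints. The template (sense strand) is
bisulfite-converted before amplification with the diagnostic site
methylated or not; recognition sites are searched on both strands of the
product (for the palindromic-under-IUPAC HpyCH4IV and HinfI sites the two
scans coincide), and fragments are reported sorted, always summing to the
amplicon length. The bundled worked examples are synthetic templates
constructed to reproduce the classical assay geometry — a 72 bp
tRNA-Asp(GTC) amplicon whose single ACGT spans C38 (35 + 37 bp when
methylated, uncut otherwise) and a 155 bp rRNA window where a forward
dCAPS primer with a G at position four from the 3′ end completes GANTC
only over a protected cytosine (29 + 126 bp) — they are labelled synthetic
and are not the published reference sequences.

## The synthetic data generator

The simulator emulates a stranded, single-end small-RNA bisulfite library:
reads of 65–95 nt (gel size selection of the tRNA fraction; capped at the
reference length for shorter references), sources drawn by abundance
weight, a methylation-free spike-in mixed at a configurable fraction, and
per-cytosine conversion sampled from the channel above (defaults
`e = 0.99`, `o = 0.01`), followed by uniform substitution error
(default 0.001). The bundled spike-in control is rejection-sampled to
carry exactly 178 cytosines on a 1068-nt transcript, matching the scale of
a Renilla-luciferase-style control. Identical seed and configuration give
byte-identical FASTQ output; each read carries a ground-truth record of
its source, offset and per-cytosine conversion outcome.

What the generator does *not* model: PCR duplicates, adapter read-through,
indels, paired ends, base-quality variation (qualities are constant and
ignored), bisulfite-induced fragmentation bias, secondary-structure-driven
non-conversion (which in real data can cluster false positives, as dense
rRNA non-conversion runs illustrate), or antisense reads. Passing tests
therefore demonstrate correctness of the counting, gating and
classification machinery under the stated noise model — not robustness to
every artifact of a real library.

The over-conversion default of 0.01 is a free parameter of the simulator,
not an empirically anchored value; published work typically does not report
a false-negative methylation rate.

## Problem sizes and numerical choices

Validation experiments run at desk scale, chosen to keep binomial
uncertainty far from the thresholds being exercised: parameter recovery
uses 50 synthetic references × 20 cytosines = 1,000 sites at mean depth
~100 (mean absolute error is then ≈ 0.02–0.03, comfortably inside the 0.05
bound, with the 5-read/20% rule yielding zero false positives at true
zero); the QC gate is measured at > 10⁴ pooled control-cytosine
observations (standard error < 0.1 percentage points around the 98%
threshold); closed-form agreement uses 10⁴ covering reads per (m, e, o)
grid point; aligner exactness is checked on 50 references × 500 reads.
Fractional pileup counts are kept as floats throughout; methylation at
zero coverage is `None`/`NA`, never 0. The calling boundary is inclusive
(exactly 20% with exactly 5 reads is methylated). All stochastic code
paths flow from explicit integer seeds.

## Known limitations

- Ungapped alignment cannot place reads over indel variation between a
  sample and its consensus reference.
- The cloverleaf numbering is segment-anchored, not a curated per-family
  alignment; unusual architectures (e.g. extreme D-loop lengths) can shift
  labels on the 5′ side by design.
- Conversion-resistant modifications other than m⁵C are indistinguishable
  from methylation by construction of the assay.
- The conservation classifier assumes one homologous RNA per species panel
  invocation; paralog resolution is the caller's responsibility.
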