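# rbsmeth

RNA bisulfite sequencing (RBS-seq) analysis for detecting 5-methylcytosine
(m⁵C) in tRNAs and rRNAs at single-nucleotide resolution.

Sodium bisulfite deaminates unmethylated cytosine to uracil (read as T after
cDNA synthesis) while m⁵C resists conversion and still reads as C. Deep
sequencing of a converted RNA library therefore turns methylation detection
into a counting problem at every reference cytosine. `rbsmeth` implements
the computational side of such an experiment for the small structural RNAs
where plant m⁵C lives:

- **Reference construction** — collapse identical and highly similar tRNA
  isodecoder gene sequences (same amino acid and anticodon) into consensus
  references, keeping diverged minority isodecoders separate (`-1`, `-2`
  suffixes), and produce *in silico* C→T converted references with the
  original cytosine coordinates retained.
- **Three-letter alignment** — ungapped seed-and-extend matching of C→T
  collapsed reads against converted references, so a methylated
  (unconverted) C is not penalised as a mismatch; reads tying across
  references (e.g. a tRNA encoded identically by two genomes) are kept as
  ambiguous co-champions and count fractionally.
- **Methylation calling** — per-cytosine pileups; percent methylation
  `m = n_C / (n_C + n_T)`; a spike-in conversion control (a
  methylation-free in-vitro transcript) gates each library at ≥ 98%
  aggregate conversion; candidate m⁵C sites require ≥ 5 reads and ≥ 20%
  methylation; differential reports (lost / reduced / unchanged) between
  genotypes.
- **Structural mapping** — sites are numbered on the classical ~72-position
  tRNA cloverleaf (anticodon = 34–36, variable region after 43, acceptor
  end = 72) and rRNA sites on anchor-species coordinates via pairwise
  alignment, for cross-species comparison.
- **Conservation classification** — class 1 (methylated in all species),
  class 2 (all but one, which carries a SNP), class 3 (methylated in some,
  cytosine present but unmethylated in others).
- **Methyl-chop PCR / dCAPS prediction** — in-silico restriction digests of
  bisulfite-converted amplicons (HpyCH4IV `A^CGT`, HinfI `G^ANTC`),
  including dCAPS primers whose deliberate mismatch completes a site only
  for one conversion outcome.
- **Synthetic data** — a fully parameterised read simulator (per-site
  methylation fractions, conversion efficiency, over-conversion, sequencing
  error, spike-in fraction) with per-read ground truth, so every stage is
  testable against known truth without external data.

## Worked example

Run the bundled two-genotype synthetic study (a wild type and a mutant that
loses C38 methylation) end to end:

```
rbsmeth run --seed 1 --out run/
```

`run/samples/wild_type/sites.tsv` then contains the called sites; the
methylated ones for this seed are:

```
reference_id  position  structural_position  coverage  methylation
     Asp-GTC        38                   38     681.0     0.785609
     Glu-CTC        48                   48     690.0     0.426087
     Glu-CTC        50                   50     688.0     0.668605
     Gly-GCC        38                   38     673.0     0.683507
     Gly-GCC        48                   48     674.0     0.545994
     Gly-GCC        49                   49     675.0     0.885926
     Leu-CAA        48                   48     660.0     0.828788
     Leu-CAA        72                   72     212.0     0.301887
```

Each row is one reference cytosine: `coverage` is the (fractionally
weighted) number of informative reads, `methylation` the C/(C+T) fraction,
and `structural_position` the cloverleaf coordinate. The simulator planted
methylation at structural positions 38, 48, 49, 50 and 72 with fractions
0.30–0.90, which the calls recover; `differential_wild_type_vs_mutant.tsv`
reports both C38 sites as `lost` in the mutant. `qc.json` records each
library's spike-in conversion (≈ 99%, passing the 98% gate).

The methyl-chop assay for tRNA-Asp(GTC) C38 prints a virtual gel:

```python
from rbsmeth.assays import asp_chop_assay
from rbsmeth.chop import render_gel
print(render_gel(asp_chop_assay()))
```

```
  size   methylated  unmethylated
  72bp                  ======
  37bp     ======
  35bp     ======
assay: informative (HpyCH4IV)
```

The 72 bp amplicon is cut by HpyCH4IV into 35 + 37 bp only when C38 is
methylated (conversion of unmethylated C38 destroys the ACGT site); the
corresponding 155 bp dCAPS product for the 25S rRNA site is cut by HinfI
into 29 + 126 bp only when that cytosine is methylated.

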