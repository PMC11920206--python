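# fmscan

Population-genomic resolution of the chicken fibromelanosis (*FM*)
structural allele.

Fibromelanosis — the dramatic hyperpigmentation of Silkie, Ayam Cemani and
related breeds — is caused by a complex structural variant on chromosome 20
that upregulates *EDN3*: two large duplications, DUP1
(chr20:10,766,772–10,894,151; 127.4 kb) and DUP2
(chr20:11,306,686–11,477,501; ~170 kb), separated by a non-duplicated
412.54 kb intervening region (INT), with an inversion whose extent differs
between three long-standing candidate arrangements, FM-1, FM-2 and FM-3.
Short reads from both copies of a duplicated region collapse onto the
single reference copy, so standard assembly cannot settle the arrangement —
but the *population-genomic footprint* of each arrangement differs, and
that is what this package computes.

## The idea

Each candidate arrangement predicts which regions of the FM haplotype are
frozen by suppressed recombination. A frozen duplicated region behaves as a
single ancestral haplotype pair: at sites where the two copies differ,
*every* FM homozygote is called heterozygous with reference-allele
frequency exactly 0.5 ("fixed heterozygosity"); at other sites the cohort
is fixed. Site frequencies in FM homozygotes therefore pin to {0, 0.5, 1}
— an allele-frequency **bubble** — exactly over the frozen span, together
with reduced nucleotide diversity (π), elevated F_ST against wild type,
and elevated LD retention. Writing the bubble state of (DUP1, INT, DUP2)
as a boolean triple:

| arrangement | frozen span | predicted triple |
|---|---|---|
| WT | none | (0, 0, 0) |
| FM-1 | whole block | (1, 1, 1) |
| FM-2 | DUP1 + inverted DUP2 copy | (1, 0, 0) |
| FM-3 | DUP2 + inverted DUP1 copy | (0, 0, 1) |

The pipeline genotypes samples from relative sequence depth (region mean
depth / genome background ≈ 1.0, 1.5, 2.0 for N/N, FM/N, FM/FM), builds
the FM-homozygote frequency profile, flags bubbled regions, and matches
the observed triple against the four templates by Hamming distance.
Supporting evidence — windowed π and Weir–Cockerham F_ST with
genome-background Z scores and Benjamini–Hochberg FDR, pairwise dosage r²
with an LD block-boundary scan, a change-point scan for the break in fixed
heterozygosity, and neighbor-joining trees per duplication — is computed
alongside.

A synthetic-data generator produces populations segregating for any of the
four arrangements, including the collapsed-reference observation model
(depth-proportional Poisson read counts, binomial allele reads, an
allele-fraction genotype-calling band), so the whole inference is testable
end to end against known truth; real VCF + depth-table inputs run through
the same stages.

## Worked example

Simulate a population of 50 wild-type and 50 FM-homozygous birds under the
FM-2 arrangement (locus scaled 100-fold for speed), run every stage, and
call the arrangement:

```
$ fmscan run-all --out demo --configuration FM-2 --seed 7
configuration: FM-2 (confident)
```

`demo/summary.json` then contains (abridged):

```json
{
  "configuration_call": {
    "call": "FM-2",
    "status": "confident",
    "bubble_flags": [true, false, false],
    "distances": {"WT": 1, "FM-1": 2, "FM-2": 0, "FM-3": 2},
    "evidence": {
      "DUP1": {"fixed_fraction": 1.0, "fixed_het_fraction": 0.52, "ld_z": 134.5},
      "INT":  {"fixed_fraction": 0.12, "fixed_het_fraction": 0.08, "ld_z": -0.78},
      "DUP2": {"fixed_fraction": 0.10, "fixed_het_fraction": 0.05, "ld_z": 7.4}
    }
  }
}
```

Reading the numbers: every classified DUP1 site in the FM-homozygote
cohort is fixed-class (`fixed_fraction` 1.0) and about half of those sit
at frequency 0.5 (`fixed_het_fraction` 0.52) — the fixed-heterozygosity
bubble — while INT and DUP2 look like wild-type diversity
(`fixed_fraction` ≈ 0.1, no bubble). LD retention is ~134 background
standard deviations above the genome-wide mean in DUP1 and at background
level in INT. The observed triple (1,0,0) matches FM-2 exactly and no
other arrangement, so the call is confident: an inverted DUP2 copy between
two tandem DUP1 copies, with INT and the second DUP2 copy recombining
freely.

The output directory also holds the VCF and depth table, CNV calls
(`cnv_calls.tsv`), window statistics (`fst_windows.tsv`, `pi_*_windows.tsv`,
`ld_windows.tsv`), newick trees per duplication, and the simulation truth
sidecar.

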