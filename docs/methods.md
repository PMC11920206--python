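# Methods

This note documents the models, parameters and numerical choices behind
`fmscan`, and what its synthetic data can and cannot show about real
sequencing data.

## Locus model

The FM locus is represented by 1-based intervals with half-open extent
(`length = end − start`), so the published boundary coordinates are stored
verbatim and DUP1 (10,766,772–10,894,151), INT (10,894,151–11,306,686) and
DUP2 (11,306,686–11,477,501) tile the locus sharing boundary points. This
convention is what makes the printed region lengths come out exactly:
127,379 bp → 127.4 kb and 412,535 bp → 412.54 kb (kb values are rounded
decimal-half-up, since binary-float rounding turns 412.535 into 412.53).
The scan region is chr20:10.6–11.7 Mb; two background intervals of 550 kb
each (chr20:9.0–9.55 Mb and 12.0–12.55 Mb) stand in for the genome-wide
background of the depth and window statistics. `build_region_map(scale)`
divides every coordinate by `scale` with half-up rounding; the default
working scale for simulation and tests is 100 (scan region ≈ 11 kb), which
keeps per-region site counts in the hundreds while making a full pipeline
replicate run in under a second.

Each candidate arrangement is encoded by its copy layout and a suppression
state per region — which copies are frozen by the inversion's
recombination suppression. A region is predicted to show the
allele-frequency bubble exactly when *all* of its copies are frozen: WT
(0,0,0), FM-1 (1,1,1), FM-2 (1,0,0), FM-3 (0,0,1). For FM-1 the single INT
copy is encoded frozen (fixed 0/1 frequencies, no 0.5 class possible),
which is the minimal geometry consistent with a bubble spanning the whole
block and with INT not being duplicated.

## Synthetic-data generator

The generator emulates the statistical structure of a cohort-scale
short-read dataset at the locus, not the reads themselves.

* **Sites and founders.** Sites are placed by a Poisson process at
  `site_density` (default 1/200 per unscaled bp — per-region site counts
  are scale-invariant). Each site receives a founder reference-allele
  frequency drawn Beta(α, α) with α = 0.3, a U-shaped frequency spectrum
  concentrating mass near fixation as in a neutral SFS; `sfs_alpha=None`
  fixes all frequencies at 0.5 for controlled experiments. Wild-type
  haplotypes are sampled per site independently, so the founders carry
  **no background LD**: all elevated LD in the output is produced by the
  FM allele's identity by descent, which is the signal under study.
* **FM-allele birth.** The founding FM haplotype takes donor haplotype A
  throughout; in each duplicated region, copy 2 differs from copy 1 at
  each site with probability `donor_divergence` (default 0.3). This is a
  controlled total fixed-difference rate between the copies — the quantity
  that collapsed mapping later reads out as fixed heterozygosity — rather
  than divergence layered on top of two independent pool draws; the latter
  would make the frozen region *more* diverse than the eroded one under a
  U-shaped SFS and invert the diversity signal that distinguishes the
  arrangements.
* **Erosion.** Generations of recombination between FM and wild-type
  chromosomes are collapsed into one memoryless parameter: every *free*
  (unsuppressed) segment of every FM chromosome is independently replaced
  by the corresponding segment of a random wild-type haplotype with
  probability `erosion_p` (default 0.9), standing in for 1 − exp(−r·g).
  Frozen segments are never replaced. Wholesale per-segment replacement
  also gives eroded regions a realistic two-haplotype mixture structure
  (≈10% of FM chromosomes retain founder content), which is what creates
  detectable LD blocks around suppression boundaries.
* **Injections for controlled experiments.** `dup1_suppression_break=f`
  frees the DUP1 sites distal to fraction `f`, realizing the
  recombination-erosion interpretation of a break in fixed heterozygosity
  and producing a concomitant LD block boundary at the same position
  (the alternative interpretation — donors identical over a sub-interval —
  leaves the distal segment frozen and produces no LD boundary, so it is
  not used for the concordance experiments). `dup2_ref_span=(f0, f1)`
  forces the frozen DUP2 copy to match the reference inside the span and
  mismatch it outside, giving reference-consistent segments with sharp
  ends.
* **Randomness.** One root seed is split into three child streams consumed
  in a fixed order — (1) sites + founders, (2) FM-allele construction,
  (3) erosion — and the observation step uses its own stream (run seed +1
  in the pipeline), so simulation and sequencing noise vary independently.
  Outputs are byte-identical across runs at fixed seed.

Default cohort: 50 wild type, 0 heterozygotes, 50 FM homozygotes — the
configuration-recovery experiments follow the real analysis in contrasting
depth-deduced homozygote cohorts, and heterozygotes add no information to
the bubble triple.

## Observation model (collapsed reference)

For an individual with total copy number `c` at a site (2 outside
duplications; 3 for FM/N and 4 for FM/FM inside one) of which `d` copies
carry the reference allele: read count `n ~ Poisson(depth·c/2)` (default
depth 30), reference reads `~ Binomial(n, (d/c)(1−e) + (1−d/c)e)` with
sequencing error `e = 0.001`. Genotypes are called from the reference-read
fraction with a symmetric band: hom-alt below 0.2, hom-ref above 0.8, het
in between (band edges inclusive toward het), missing at `n = 0`. The band
is a deliberate surrogate for a full joint-calling pipeline: it reproduces
the het-at-0.5 behaviour of collapsed paralogs (an FM/FM fixed difference
has `d/c = 0.5` and is called het with probability ≈1 at 30×; the FM/N
fractions 1/3 and 2/3 also fall in the band) without modelling caller
internals. A `deterministic` mode replaces sampling with expectations so
genotype calls are an exact function of `(d, c)` for unit tests. Window
depths are the mean per-site read totals in tiling windows; the per-sample
background mean uses the background regions only.

## Inference stages

* **CNV genotyping.** Relative depth = region mean window depth /
  background mean. Per region: <1.25 → one copy per haplotype, [1.25,
  1.75) → het, ≥1.75 → hom; the thresholds are the midpoints between the
  expected ratios 1.0/1.5/2.0. DUP1 and DUP2 must agree or the sample is
  `ambiguous` (never silently forced); the INT ratio is reported as
  context but unused. At 30× and hundreds of sites per region the ratio
  standard error is ~0.01, so calls are essentially error-free.
* **Filtering.** Biallelic sites with minor-allele frequency ≥0.05 over
  all called alleles and call rate ≥0.9, computed across the full cohort.
* **Windows.** 1-based inclusive windows of 20 kb sliding by 10 kb at
  scale 1 (both divided by the map scale), first window at the region
  start, final partial window kept and flagged.
* **π and F_ST.** Windowed π sums per-site `n_ref·n_alt / C(n,2)` over
  called alleles and divides by window length in bp. F_ST is the Weir &
  Cockerham (1984) two-population estimator, window-aggregated as
  Σa / Σ(a+b+c); sites with zero denominator (monomorphic across both
  cohorts) carry no information and are excluded. Both are checked against
  independent brute-force/formula-literal oracles in the tests (1e-12).
* **Z / FDR.** Window values are Z-transformed against the mean and SD
  (ddof 1) of the background windows; p-values are one-sided upper-tail
  (the elevation test; a two-sided option exists), and Benjamini–Hochberg
  q-values are computed over the full tested family (scan plus background
  windows). Region-level summaries report the mean per-window z over
  windows whose midpoint falls in the region.
* **Site classes and bubble.** With cohort frequency `f` from ≥20 called
  alleles: FIXED_REF at `f ≥ 1−ε`, FIXED_ALT at `f ≤ ε`, FIXED_HET at
  `|f−0.5| ≤ ε` (ε = 0.05 — the idealized signal is exact but finite
  cohorts and 30× noise need a tolerance; ε ≥ 0.25 would overlap the
  classes and is rejected). A region with ≥10 classified sites is bubbled
  when its fixed-class fraction exceeds τ = 0.5; fewer sites give an
  explicit `insufficient` status, never a silent flag.
* **Breakpoint.** The fixed-class indicator series over a region is fitted
  with a single change-point by exhaustive two-segment Bernoulli maximum
  likelihood (the O(N) scan is both implementation and oracle at these
  site counts); the change is reported only when the likelihood-ratio
  statistic exceeds 10 (strong support). The reported position is the
  midpoint between the flanking sites. This detector is this package's
  formalization of a feature identified manually in real-data work, and is
  labelled as such in reports.
* **LD.** r² is the squared Pearson correlation of unphased genotype
  dosages (composite LD — inputs are genotype calls, not phased
  haplotypes) over samples called at both sites, undefined under 4 shared
  calls. LD retention is the mean defined pairwise r² within each window,
  Z/FDR-annotated like F_ST. The block boundary in a target interval is
  the split maximizing the contrast (within-block mean r² − cross-block
  mean r²), computed over all samples. Candidate splits leave at least
  max(5, 5% of sites) on each side — near-edge splits otherwise ride the
  sampling noise of a handful of sites up to contrasts of ~0.2 on
  perfectly homogeneous blocks. With edge splits excluded, homogeneous
  frozen blocks measure ≤~0.06 and genuine suppression boundaries
  ~0.14–0.21, so the reporting threshold defaults to 0.1 (midpoint of the
  two regimes; configurable). Minimizing the cross-block mean alone, an
  obvious alternative, degenerates: under the one-factor correlation
  structure of this data the cross mean factorizes into a product of side
  means and is minimized at an extreme split rather than the junction.
* **Configuration call.** The observed bubble triple is Hamming-matched
  against the four templates. A call is `confident` only on an exact,
  unique match; otherwise `ambiguous-nearest` with the tie recorded.
  Continuous evidence (fixed-het fraction, π ratio, LD z) is reported but
  deliberately not scored — the discrete triple is the documented
  discrimination logic, and inventing likelihood weights for the
  continuous signals would suggest a precision the model does not have.
  When depth genotyping finds no FM homozygotes at all (a wild-type
  population), the triple is (0,0,0) by construction and the call is WT.
* **Trees.** Allele-sharing distances `d_ij = mean |dosage_i −
  dosage_j|/2` over co-called region sites (the simplest distance
  computable from unphased genotypes; invariant to allele relabeling),
  neighbor-joining with the standard Q criterion, lexicographic label-pair
  tie-breaking for platform-independent topologies, negative branch
  lengths clamped to zero. NJ is exact on additive matrices
  (property-tested, and cross-checked against scikit-bio's implementation).
  The branch-length contrast — mean FM terminal branch length in the DUP1
  tree over the DUP2 tree — is reported descriptively, with no test
  attached: frozen regions collapse FM terminal branches toward zero.

## What the synthetic data does and does not show

The generator reproduces the features the inference relies on: the three
depth clusters, fixed heterozygosity at 0.5 under suppressed
recombination, bubble geography per arrangement, diversity reduction in
frozen spans, FM-driven LD elevation, and erosion outside the suppressed
span. It omits background LD among founders, demography, selection,
mapping-quality artifacts, GC/mappability bias, indels and genotype-caller
idiosyncrasies. Passing tests therefore demonstrate that the inference
recovers the generating architecture under its stated observation model —
not that any particular real dataset is free of confounders; on real
inputs the same statistics are computed and the same decision logic
applies, but thresholds (notably the CNV ratio cut-offs and the bubble τ)
may need inspection against the empirical clusters. Real-data cohort-level
Z magnitudes depend on sample size and are not comparable to desk-scale
simulations.

## Problem sizes used by the test suite

Simulation experiments run at scale 100 with ~5,500 scan-region sites and
100 individuals per replicate; configuration recovery uses 20 seeded
replicates per arrangement, breakpoint/boundary concordance 10, and the
oracle-equivalence suites 100 random instances each. These sizes put every
statistic's sampling error well inside the asserted margins while keeping
a full run of the suite under a minute.
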