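# Methods

`scifiatac` implements the computational side of a combinatorial fluidic
indexing single-cell ATAC-seq experiment: nuclei are pre-indexed in a
96-well plate with two-sided barcoded Tn5 (12 "A"/s7 row barcodes x 8
"B"/s5 column barcodes), then overloaded into a droplet microfluidics
device so that occupied droplets routinely carry more than one nucleus. A
cell's identity is the combination of the 16-bp gel-bead (droplet) barcode
and the Tn5 well barcode; two nuclei are indistinguishable — a *barcode
collision* — only when they share both. This note records the models, the
defaults and the numerical choices, module by module.

## Synthetic experiment generator

The generator exists so that every downstream stage can be scored against a
complete ground truth without external data.

**Reference.** A small multi-chromosome genome with non-overlapping genes
(random lengths 1–3 kb, placed by splitting each chromosome's slack into
random gaps), fixed-width ACRs (default 500 bp, 1200 of them on the 10-Mb
default genome, i.e. ~6% of the genome accessible), and a biallelic SNP
panel at 0.7 SNPs/kb — the density of the maize inbred panel this kind of
experiment genotypes against. Each SNP is homozygous-distinct: exactly one
genotype carries the alternate allele. 70% of ACRs are centred within
±200 bp of a gene TSS, so ACR enrichment of Tn5 insertions also produces
TSS enrichment, as in real chromatin. Organelle scaffolds carry no genes,
ACRs or SNPs.

**Droplet loading.** Nuclei are distributed over droplets with
zero-truncated Poisson occupancy (the standard microfluidics loading model;
only the occupancy distribution matters to the collision mathematics).
The default λ = 2 reproduces the heavily overloaded regime (mean
occupancies of roughly 1.6–3.4 nuclei per droplet are typical between 100k
and 300k loaded nuclei). Wells are assigned uniformly by default;
non-uniform per-well weights and a well → sample map (multiplexed mode) are
supported.

**Fragments.** Per-nucleus fragment counts are gamma-Poisson (mean 1000,
shape 8), giving ~2000 Tn5 insertion sites per nucleus — comfortably above
the 1000-site QC floor and enough to put ~90 informative SNP reads in a
typical cell, above the 50-read genotyping floor. Fragment centres fall
inside ACRs with a 5x density enrichment; sizes are a
nucleosome-free/mononucleosome Gaussian mixture (means 80/200 bp, weight
0.6); 5% of fragments land on organelle scaffolds. Sequence content outside
barcodes and SNP positions is placeholder; quality scores are constant —
nothing downstream reads either.

**Index hopping.** Each fragment independently acquires a wrong bead
barcode with probability `hopping_rate` (default 0.02). The destination
droplet is the droplet of a uniformly chosen *other* fragment — i.e.
hopping probability onto a bead barcode is proportional to that barcode's
read abundance, which is how index hopping behaves physically (free index
concentration scales with library share). This choice makes the hopped-in
read fraction of every cell equal to the hopping rate in expectation,
independent of droplet occupancy; a uniform-droplet destination would
instead inflate singleton droplets' contamination by the mean-occupancy
factor. Tn5 barcodes are untouched by hopping, which is exactly why the
well barcode separates hopped reads from genuine co-encapsulation.

**Allele errors.** A SNP-overlapping read reports the wrong allele with
probability `seq_error` (default 0.05, applied per informative read — the
same granularity at which the genotype model consumes it).

**What the generator does not emulate.** Realistic sequence composition,
mappability, PCR duplication structure (a flat duplication-rate knob only),
chromatin heterogeneity between cell types, and heavy-tailed occupancy
beyond the zero-truncated Poisson. Tests passing on this generator
demonstrate correctness of the *inference machinery* under its stated
model, not robustness to those real-data features.

## Demultiplexing

Barcodes are corrected against whitelists with a Hamming radius of 1;
ambiguous ties are rejected rather than guessed, because a mis-corrected
well barcode later masquerades as index hopping. The bundled default A/B
barcode lists are synthetic 5-mers with pairwise distance ≥ 3 (single
errors always correctable); schemas with smaller separation trigger a
warning at load. Rejection reasons are enumerated (`bad_bead`, `bad_a`,
`bad_b`, `invalid_pair`) and read counts are conserved across
retained/flagged/rejected.

A (bead, well) combination is a *candidate nucleus* if it holds at least
`min_reads = 100` reads and at least `min_frac = 5%` of its bead barcode's
reads; everything else is flagged as hopped background. The thresholds are
configurable: the trace-combo separation has no published operating point,
and the defaults sit two orders of magnitude below a genuine nucleus's
depth while comfortably above the per-combo hopped background (a droplet
receives hopped reads spread across all 96 wells).

## Insertion sites and QC

Fragments (0-based half-open BED convention) are converted to single-base
Tn5 integration sites at `start + 4` and `end - 5`, the two insertion
points of the 9-bp staggered transposition; fragments shorter than 10 bp
produce crossed or coincident sites and are flagged degenerate. Sites are
deduplicated per cell. Per-nucleus metrics: unique-site count, fraction
within ±2 kb of a TSS (endpoints inclusive), fraction inside ACRs (FRiP),
and fraction on organelle scaffolds, all computed over the cell's full
unique-site set (organelle sites included in the denominator — whether the
original workflows exclude them first is unstated, so the choice is
documented here). Pass thresholds are inclusive, matching their "a minimum
of / at least / a maximum of" phrasing: ≥ 1000 sites, ≥ 20% TSS, ≥ 20%
FRiP, ≤ 30% organelle.

## Genotype and collision calling

Per cell, each read overlapping a SNP contributes one count to the genotype
whose allele it carries at its first overlapped SNP; reads matching no
genotype, or an allele shared by several pooled genotypes, are ignored.
Cells need ≥ 50 informative reads to be called.

Likelihoods are per-read products evaluated in log space (multinomial
coefficients cancel in the posterior). With two genotypes: a singlet of g
matches with probability 1 − ε (ε = 0.05, a conservative per-read error
rate) and a collision is an equal mixture (match probability 0.5; the
mixing weight is configurable — equal contribution is the natural default
for two co-encapsulated nuclei). With k > 2 genotypes the singlet
hypothesis puts 1 − ε on its genotype and splits ε evenly over the rest;
the collision hypothesis is the best equal-mixture pair. Priors are flat,
so the posterior is the normalised likelihood; ties in the argmax are
conservatively unassigned. Contamination of a called singlet is the
fraction of its informative reads carrying another genotype's allele.

In multiplexed mode the expected genotype comes from the cell's Tn5 well
via the plate map, reads are reduced to expected-vs-other, and the same
binomial machinery tests expected singlet (1 − ε) against other singlet (ε)
and collision (0.5); the mismatch fraction of expected-called cells is the
index-hopping contamination estimate.

**Contamination accounting and the double barcode.** Under the hopping
model above, a hopped read lands in a *combined-barcode* cell only when its
well matches the destination droplet's nucleus — a ~1/96 dilution — so
combined-barcode singlet contamination stays near the allele-error floor.
Aggregating counts at the bead-barcode level instead (the standard droplet
scATAC accounting, where the bead barcode alone is the cell identity)
exposes the full hopped-in share: every cell then contains a fraction
`hopping_rate` of hopped reads, half of them from the other genotype in an
equal two-genotype pool, so mean singlet contamination converges to
`hopping_rate / 2`. The acceptance suite verifies that recovery in the
standard-loading regime (λ = 0.2), with the Monte-Carlo SE taken across
simulation replicates so that shared pool-composition fluctuations are
counted as error.

## Droplet occupancy and collision rates

Observed occupancy of a bead barcode is its number of distinct retained
wells — a lower bound on the nucleus count, since same-well nuclei merge
(the resulting underestimate of the dataset collision rate is ~4% relative
at λ = 2 and is covered by the acceptance tolerance).

For k nuclei assigned independently to wells with probabilities p:

- P(at least two share a well) = 1 − k!·e_k(p), with e_k the elementary
  symmetric polynomial, computed exactly for k ≤ 10 by the O(W·k) DP
  recurrence (numerically stabler than Newton's identities, identical
  result) and by seeded Monte Carlo beyond; the uniform case reduces to
  1 − ∏(W−i)/W.
- The expected *fraction of nuclei* losing identity is exact for every k by
  linearity of expectation: q(k) = 1 − Σ_w p_w (1 − p_w)^(k−1). The
  dataset-level rate is the nucleus-weighted mixture Σ P(k)·k·q(k) / Σ
  P(k)·k. (Enumeration/Monte-Carlo versions survive only as test oracles.)
  A single-occupancy mapping `{k: 1.0}` gives the fixed-occupancy variant,
  e.g. the "two of four nuclei share a well" probability at a mean loading
  of ~3.4.

Collision rates are defined at the nucleus level (fraction of recovered
nuclei involved), matching how collision percentages are reported against
recovered-nuclei counts. Well probabilities default to uniform but can be
estimated from per-well retained-nucleus counts when loading is uneven.

With g pooled genotypes at fractions f, only cross-genotype mixtures are
observable, so the total collision rate is `observed / (1 − Σ f_g²)`; for
two equal genotypes this doubles the observed rate — which is how the
identified 4.87% and 5.68% cross-genotype rates both imply a total of
about 10%.

## Accessibility scoring

Gene accessibility counts unique insertion sites in the gene body plus
500 bp upstream and 100 bp downstream, flanks applied relative to strand
(genomics convention; unstranded genes are treated as + with a warning).
Counts are CPM-normalised per group; Z-scores use the sample (n−1)
standard deviation across groups, zero-variance features getting Z = 0.
A feature is specific to a group when Z > 2; note that a single-group
signal among k groups caps at Z = (k−1)/√k, so the rule only has power for
k ≥ 7 groups — the multi-genotype / multi-cell-type regime it is used in.
ACR master lists are 500-bp summit-centred windows laid down greedily in
descending signal order with overlapping windows dropped (the original
consolidation script is unpublished; greedy-by-signal is the standard
iterative overlap removal, and the tie-break is the input order of equal
counts); windows below 3 CPM in every group are removed. Library
similarity is Spearman correlation with average ranks on ties; constant
columns are reported missing.

## Problem sizes and tolerances

The test and acceptance suites run on a 2.5-Mb reference (80 genes, 300
ACRs, ~1750 SNPs) with cohorts of 300–20,000 nuclei — sizes at which every
statistical check has the power it needs while the whole suite stays
desk-scale. Statistical assertions use 3 Monte-Carlo standard errors
(between-replicate SE where a shared simulation effect exists); exact
assertions (barcode combinatorics, the +4/−5 round trip, brute-force
refilters, rank-correlation oracles) are bitwise or at 1e-12. All
randomness flows through a single NumPy `default_rng` stream keyed by the
design seed; repeated runs are byte-identical.

## Known limitations

- Bead-barcode multiplets (two beads in one droplet) and GEM-generation
  efficiency are not modelled.
- De-novo genotype deconvolution without a SNP panel is out of scope; the
  allele counter requires known homozygous biallelic SNPs.
- The >2-genotype collision likelihood considers equal-mixture pairs only;
  triplet mixtures are called as the nearest pair.
- Occupancy reconstruction cannot see same-well co-encapsulation, so the
  occupancy histogram is a lower bound (see above).
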