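# Methods

This note documents the models, defaults and numerical choices behind
`petromine`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Translated search engine

Reads are translated in all six frames under the standard genetic code
(codons containing `N` become `X`; stops become `*`; the minus frames are the
forward frames of the reverse complement). Local alignment is affine-gap
Smith–Waterman over BLOSUM62 via Biopython's `PairwiseAligner`, with the
BLAST gap convention (a gap of length *k* costs `open + k·extend`; defaults
11/1). Alignments never cross a stop codon: peptides are split at `*` and
each open segment aligned separately. This matters statistically as well as
biologically — random reads translate into segments of ~21 residues on
average, which truncates the high-score tail of the null distribution and is
the main reason chance recruitment at E < 0.10 stays rare against a
desk-scale panel (measured: ~3.5% of 330-bp uniform-random reads).

E-values use fixed Karlin–Altschul constants λ = 0.267, K = 0.041 (the
published gapped BLOSUM62-11/1 values), with search space *m·n* where *m* is
the longest frame translation of the read in residues and *n* the total
database residues. Edge-effect length corrections are omitted; at the
thresholds this pipeline uses (0.10 and 10⁻⁵) and at these database sizes
the correction would not change any decision the pipeline makes. Lowercase
masking/composition statistics are not implemented.

### Seeded acceleration

`search_dataset` processes reads in equal-length batches with vectorized
translation, and only aligns a read against proteins with which it shares an
exact amino-acid 6-mer, restricted to the stop-free segment containing the
seed. Genuine homologs at the mutation rates this pipeline targets (≤ 5%
per base) essentially always contain exact 6-mers, so planted-read results
are identical to the exact path (asserted in tests). The tolerated
difference is that a fraction of *chance* alignments near the E = 0.10
boundary are dropped (measured on uniform-random reads: 0.1% of reads pass
the seeded search vs 3.5% for the exhaustive search). The exact path
(`prefilter_k=None`) remains the reference and is what the unit tests
exercise; the pipeline default is `prefilter_k=6`.

## Recruitment and confirmation

Recruitment keeps, per read and family, the best hit over all frames and
family members at E < 0.10. Confirmation re-searches recruited reads against
the confirmation database and keeps a read only when its single best hit
(bit score, then E-value, then database order — a deterministic tie-break)
is the recruiting family or an accepted synonym; the extradiol catechol
2,3-dioxygenase family accepts biphenyl-2,3-diol 1,2-dioxygenase
(EC 1.13.11.39) and 1,2-dihydroxynaphthalene dioxygenase. A read recruited
by several families keeps at most the record its best hit supports. The
search direction is reads-against-references (scores are symmetric; E-values
are computed on this search space). The 50-bp minimum alignment span is
applied in the whole-metagenome taxonomic profiler, not in recruitment.

**Known desk-scale limitation.** In the original procedure, confirmation
against the full non-redundant protein database discards weak chance
recruits because some unrelated protein in that enormous database outscores
the recruiting family. A desk-scale confirmation database (here: panel +
lineage homologs + synonym families + ≥ 20% decoys, ~90 proteins) cannot
reproduce that breadth: a read recruited by chance at raw score ~46 was
*selected* for scoring well against its recruiting family, and with few
competitors its best confirmation hit is usually that same family. Chance
recruits therefore survive confirmation here and form a uniform background
floor, proportional to dataset size, of roughly 0.05–0.1% of reads spread
across all families. Consequences: absolute per-100-genomes values in
full-pipeline runs sit above the planted loads by that floor; both
normalizations see the same floor, so their concordance is unaffected; and
truth-based recall/precision metrics are computed on planted reads, which
the floor does not touch. The `flag_weak_recruits` diagnostic (E > 10⁻³⁰
stratum) isolates the floor in any run.

## Synthetic data: what it emulates

* **Reference panel.** Eight families (alkane-1 monooxygenase, CYP153,
  protocatechuate 3,4- and 4,5-dioxygenase, catechol 1,2- and
  2,3-dioxygenase, gentisate and homogentisate 1,2-dioxygenase) with their
  EC numbers and reference accessions; one simulated ancestor per family
  (Robinson–Robinson-like composition, 300 residues) with members mutated at
  10% of positions, giving ~80% within-family identity (contract: ≥ 60%).
  The confirmation database adds one lineage-labelled homolog per (family,
  member taxon), synonym-family homologs derived from a 25%-diverged
  sub-ancestor, and ≥ 20% decoys (uniform composition, rejection-sampled so
  global identity to every family member stays < 25%).
* **Metagenomes.** Background reads are i.i.d. uniform nucleotides with
  normal length (sd = 15% of the mean, floor 60 bp). Planted reads are
  reverse-translated fragments of lineage-matched confirmation-database
  homologs — uniform synonymous codon choice (composition-neutral, no
  codon-usage signal), random strand and frame, per-base substitutions at
  `mutation_rate` (default 2%). Planting from the lineage-labelled homolog
  rather than the panel member itself is what lets confirmation recover the
  read's true taxon; the homolog is still ~80% identical to the panel, so
  recruitment behaves as for a real community gene. Counts per
  (family, taxon) are Poisson draws around the specified load. Artificial
  replicates are exact copies of already-emitted reads, 3′-truncated to
  70–100% of their length half the time, appended until the duplicate
  fraction (default 10%, a typical pyrosequencing burden) is reached.
* **Time course.** The four datasets (uncont/t0/t1m/t1y) default to the
  published post-dereplication sizes scaled by a user factor; emission is
  inflated by 1/(1 − duplicate_rate) so dereplication lands on the nominal
  size. Planted loads are stated per 100 genomes and converted to expected
  counts at each dataset size, making the planted signal scale-invariant;
  the default load profile mirrors the published time-course patterns
  (Gammaproteobacteria-dominant *alkB* at t=0/t=1m shifting to
  Actinobacteria/Alphaproteobacteria at t=1y; the uncontaminated control
  carries about one tenth of the t=0 *alkB* load).
* **qPCR.** Standards follow Ct = intercept − log₁₀(copies)/log₁₀(1 + eff)
  plus Gaussian noise; unknowns and the 10⁵ copies/µl lambda spike are
  attenuated by each sample's inhibition fraction before the same transform.

Not simulated: 454 homopolymer errors, quality scores, chimeras, rRNA genes,
per-replicate biological variability (replicates were pooled before
sequencing in the emulated design, and no per-replicate sequence
characteristics are available to calibrate against), and real protein
phylogenetic structure. Passing tests therefore demonstrate the pipeline's
correctness and its statistical behaviour under a neutral background — not
recruitment sensitivity against real environmental divergence, which
depends on reference breadth in ways a simulation cannot settle.

## Dereplication

Two reads are replicates when their first `prefix_len` bases (default 3)
match and the end-free identity of the shorter against the longer (edlib,
prefix-anchored, free 3′ end on the longer read — matching the shared-start,
3′-truncation artifact model) is ≥ 0.90. Clustering is greedy
longest-first against cluster representatives; the longest member is kept,
ties broken by input order. Above 5,000 reads, candidate clusters
additionally require 16 identical leading bases, which is exact for the
generator's replicate model (exact copies) and scales linearly; the
quadratic all-pairs path below that size is the reference behaviour.

## Normalization and statistics

Per-100-genomes values divide by read count (×750000/*n*_reads), not base
count — this is the convention that reproduces the published single-hit
increments (750000/364725 → 2.1, etc.). Reported values are rounded half
away from zero to one decimal, and table totals are sums of the rounded
per-group values (the printed tables add up this way; normalizing the
summed raw count directly gives the same answer only when rounding residues
cancel). Subsampling normalization reuses the full run's per-read outcomes:
the search is deterministic per read, so counting the full-run records that
fall inside a random subsample is identical to re-running the search on the
subsample, at a fraction of the cost. Spearman's ρ is computed internally
(average ranks for ties, Pearson on ranks); p-values use the large-sample t
approximation, or an exact permutation test below 10 pairs. Concordance
between the two normalizations is taken over all (family, sample) cells,
with families absent from one table counted as zero.

The whole-metagenome taxonomic profiler counts each read's best hit at
E ≤ 10⁻⁵ spanning ≥ 50 bp on the read, divides per-organism fragment counts
by genome size, and renormalizes.

## qPCR analysis

Standard curves are ordinary least squares of Ct on log₁₀(copies), requiring
≥ 3 points spanning ≥ 2 orders of magnitude; efficiency = 10^(−1/slope) − 1.
Spike correction divides by recovery only when recovery < 1 (a multiplicative
inhibition model — the standard spike-in assumption; over-recovery is
reported but never deflates a measurement). Correction uses recovered
*copies*, not Ct shifts. Curves are fitted per target per run with no
inter-run calibrator.

## Problem sizes and defaults

The full-scale pipeline (1.22M reads post-dereplication across four
samples, 17-protein panel, 86-protein confirmation database) runs in about
2.5 minutes on one CPU with the seeded search; this is the configuration the
acceptance script and the heavyweight acceptance test use. Unit tests use a
compact three-family panel (120-residue proteins) and datasets of hundreds
of reads with the exact search path. All randomness flows from
`numpy.random.default_rng` seeds; identical seeds give byte-identical
outputs, and every written table carries its seed and config digest.
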