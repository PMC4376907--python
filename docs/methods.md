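# Methods

gbskit implements the computational stages of a two-enzyme
genotyping-by-sequencing (GBS) workflow for germplasm characterization:
restriction-digest prediction for library design, barcode demultiplexing,
SNP-matrix construction and filtering, distance-based phylogenetics with
bootstrap support, and two downstream population checks (Evanno ΔK and a
germplasm authenticity audit). This note records the models, the parameter
choices that matter, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## In silico digestion

A restriction enzyme is a recognition site over the IUPAC alphabet plus a
top-strand cut offset. The built-ins are ApeKI (G^CWGC), PstI (CTGCA^G) and
MspI (C^CGG); all three are palindromic under IUPAC complement, so scanning
one strand finds every site. Matching conventions:

- **Overlapping matches are all reported.** Degenerate 4–6-mers can overlap
  themselves (e.g. GCWGC in `GCTGCTGC` at 0 and 3); dropping overlaps would
  undercount cut sites.
- **`N` never matches a concrete pattern letter.** Draft assemblies contain
  gap runs; letting N match would fabricate sites inside gaps. A pattern
  `N` matches anything, including sequence `N`.
- Cut coordinates are `site_start + cut_offset`; cuts at the very ends of a
  sequence (coordinate 0 or `len`) are not cuts, so fragments always tile
  `[0, len)` exactly. Fragment ends are classified by the cut that produced
  them (RARE / COMMON in a double digest, SINGLE in a single digest,
  TERMINUS at sequence ends).
- A coordinate cut by both enzymes of a pair cannot be classified by origin
  and is reported as an error rather than silently resolved.

`compare_protocols` scores a one-enzyme protocol on its internal
(SINGLE–SINGLE) fragments and a rare/common protocol on RARE–COMMON
fragments — the class that amplifies in a two-enzyme library, where each
sequenced template needs one end of each kind — and reports
`reduction = 1 − two/one`. Whether to count the sequenced class or all
fragments is configurable (`count_class`), since complexity-reduction
figures in the literature do not always say which was counted. A fragment
length window is available but off by default. Organellar scaffolds are not
treated specially; exclude them from the input FASTA if desired.

## Demultiplexing

A read pair is assigned to a sample when read 1 starts with that sample's
barcode immediately followed by the rare cutter's remnant (TGCAG for PstI)
and read 2 starts with the common cutter's remnant (CGG for MspI). Both
remnant checks are exact; a configurable number of mismatches
(`max_mismatch`, default 0) is tolerated inside the barcode only. Real GBS
barcode sets are designed with Hamming separation, so 0 is the safe
default. Matching is longest-barcode-first; a pair matching two barcodes of
the same length is rejected as `ambiguous`. Rejection reasons are
`no_barcode`, `bad_rare_remnant`, `bad_common_remnant`, `ambiguous`, and
the report enforces `assigned + rejected = input`.

The barcode is trimmed from read 1; the rare remnant is genome-adjacent
sequence and is retained for alignment. Read 2 is untrimmed. Only read
starts are validated — internal chimeric restriction sites are an
alignment-stage concern, not a demultiplexing one. Barcode tables are
checked at load time for duplicates and for the one prefix ambiguity that
longest-first matching cannot resolve: a barcode that is a proper prefix of
another whose next base equals the remnant's first base.

Technical replicates (same sample, different barcode/reaction) are merged
by `merge_replicates` before variant calling, because reaction-to-reaction
read depth is uneven; merging is order-insensitive and preserves read ids.

## The genotype matrix and filter cascade

Per-sample VCFs are merged into one samples × sites matrix of alternate-
allele dosages {0, 1, 2} with −1 for missing. Sites are keyed by
(sequence, position, ref, alt); only biallelic SNPs are kept (multi-allelic
and indel records are dropped with counts logged); a position called with
conflicting REF alleles across files is an error. A sample lacking a record
at a site is missing there — with low-coverage GBS data this is the single
largest source of missingness.

The cascade runs in the order repeat mask → (optional quality) →
missingness → MAF → LD, the order in which such datasets are prepared for
phylogenetics, and every stage emits an accounting row for which
`sites_in − sites_removed = sites_out` is enforced, with stages composing
exactly.

- **Repeat masking.** A site at VCF (1-based) position p is removed when
  p−1 falls in a BED (0-based, half-open) interval on the same sequence.
  Intervals are merged internally; unsorted input is fine; negative
  coordinates are an error.
- **Site quality.** A pluggable minimum-QUAL predicate exists but is off by
  default: "low quality" is not a well-defined criterion across callers,
  so the package does not impose one.
- **Missingness.** Sites with missing fraction strictly greater than
  `max_site_missing` (default 0.20) are removed first, then samples
  strictly above `max_sample_missing` (default 0.20) measured on the
  surviving sites — removing bad sites first rescues borderline samples.
  Because removing a called sample can in turn push a boundary site over
  the limit, the two passes are iterated to a fixed point; the output
  therefore satisfies both constraints simultaneously and the filter is
  idempotent. On realistic data the fixed point is reached in one pass.
- **MAF.** With p the alternate-allele frequency over called genotypes,
  sites with min(p, 1−p) < `min_maf` (default 0.10) are removed; a site at
  exactly the threshold is kept. Sites with no called genotypes are
  removed.
- **LD pruning.** Greedy left-to-right within each sequence: a site is
  kept unless its r² with one of the last `ld_window_sites` (default 50)
  kept sites exceeds `ld_r2_cutoff` (default 0.80). r² is the squared
  Pearson correlation of dosage vectors over pairwise-complete samples —
  the standard composite (genotypic) measure for unphased data. Pairs with
  fewer than 3 shared called samples or zero variance are treated as
  unlinked (r² = 0): with no evidence of redundancy, a marker is kept. The
  bounded window keeps the scan linear in the number of sites; 50 sites is
  wide for a reduced-representation marker density, where retained SNPs
  are far apart physically.

Heterozygosity (`het_rate`) is the fraction of called genotypes equal to 1,
overall and per sample; in a selfing panel it should be well under 1%, and
elevated per-sample values point at outcrossed or contaminated material.

## Distances, neighbour joining, bootstrap

The pairwise distance is the allele-sharing distance
d(i,j) = mean over sites called in both samples of |g_i − g_j| / 2,
bounded in [0, 1]: 0 for identical dosage vectors, 1 for opposite
homozygotes at every shared site. It is computed over pairwise-complete
sites, so a sparse matrix still yields defined distances; pairs sharing
fewer than `min_shared_sites` sites are an error that names the pairs
(don't silently build a tree from distances estimated on nothing).

Trees are built with Saitou–Nei neighbour joining using the
Studier–Keppler Q-criterion, Q(i,j) = (m−2)·d(i,j) − r_i − r_j. Ties in Q
are broken deterministically by the lowest index pair in the current
working order, so the output is a pure function of the input. NJ is
consistent on additive matrices: the generating topology is recovered with
Robinson–Foulds distance 0 and branch lengths exactly (to floating point).
The result is an unrooted tree serialized with a trifurcating root.
Negative branch-length estimates (possible on non-additive input) are
clamped to 0 for output — Newick consumers reject negatives — with the raw
estimate kept on the node and logged.

Bootstrap support resamples site columns with replacement, recomputes
distance + NJ per replicate, and maps bipartition frequencies (percent)
onto the internal edges of the full-data tree. It is seeded and
reproducible: the same seed gives identical supports.

## Evanno ΔK

Given replicate log-likelihoods L(K) from an external clustering tool at
contiguous K (a (K, replicate, logL) table; any tool's output can be
shaped into this), the Evanno table is L′(K) = mean L(K) − mean L(K−1),
|L″(K)| = |L′(K+1) − L′(K)|, ΔK = |L″(K)| / sd(L(K)) with the sample
standard deviation (ddof 1, hence ≥ 2 replicates per K). ΔK is defined for
interior K only and the best K is its argmax. ΔK depends only on
differences of L, so it is invariant to constant shifts; a zero sd yields
an infinite ΔK with a warning rather than an error, since it usually means
the chain converged identically. The MCMC clustering itself is deliberately
out of scope — only the model-choice arithmetic is implemented.

## Authenticity audit

`check_replicates` operationalizes the judgment "does this sample sit where
its label says it should" from a distance matrix plus metadata (sample,
accession, taxon, replicate). Each sample's `k_neighbors` nearest
neighbours (default 1; ties broken by sample id, logged choice) vote a
taxon by majority, ties resolved in favour of the nearest voter. A sample
whose vote disagrees with its recorded taxon is flagged MISCLASSIFIED.

A one-shot vote has a blind spot: the mislabeled sample itself votes, so a
genuine sample whose nearest neighbour happens to be the mislabeled one
inherits the wrong label as evidence. The audit therefore iterates the
vote to a fixed point, excluding currently-flagged samples as voters (at
most 10 rounds; 2–3 suffice in practice). Under well-separated groups and
moderate mislabeling rates this recovers planted label errors with perfect
precision and recall, which the acceptance checks verify at a 15% planted
rate.

Samples with another replicate of their accession present are additionally
flagged REPLICATE_DISCORDANT when their nearest same-taxon neighbour is
not one of those replicates — the distance-based form of "biological
replicates should be each other's closest relatives".

Misclassification evidence from morphology or crossing records is outside
what a distance matrix can see; the audit automates only the genetic
component.

## Synthetic data

Three generators produce all test inputs, each seed-deterministic and each
returning a machine-readable truth table.

- **Genomes** (`make_genome`): a rejection-sampled background free of both
  recognition patterns, with concrete site sequences implanted at recorded
  positions (spacing guaranteed by a stars-and-bars draw), re-verified
  after implantation so the digest truth is exact.
- **Reads** (`make_reads`): pairs drawn from RARE–COMMON fragments:
  read 1 = barcode + rare remnant + fragment prefix, read 2 = common
  remnant + reverse-complemented fragment end. Per-sample read counts are
  proportional to positive depth multipliers, emulating the observation
  that template DNA quality — not run identity — drives uneven read
  yields. Sequencing errors, if enabled, touch only the genomic interior
  so that assignment truth stays valid.
- **Populations** (`make_population`): K gene pools diverged from shared
  ancestral allele frequencies p_s ~ U(0.05, 0.95) by the Balding–Nichols
  model, p_ks ~ Beta(p_s(1−F)/F, (1−p_s)(1−F)/F) — the simplest structured
  model with one interpretable divergence parameter F. Genotypes follow
  Hardy–Weinberg deflated by an inbreeding coefficient (default 0.99,
  putting heterozygosity well under 1%, the selfing-crop regime).
  Missingness combines a per-sample random dropout (default 0.05) with an
  optional per-run shared site dropout that reproduces the run-to-run
  effect of low coverage: different runs observe different loci, so
  replicates from different runs look more distant than they are.

Defaults for the end-to-end recovery setting are 4 pools × 10 samples ×
2,000 sites at F = 0.3 — a panel size at which a full
filter → distance → NJ → bootstrap cycle runs in seconds while leaving
pool separation far from trivial saturation.

What the generators do **not** emulate: base-quality profiles and
position-dependent error, PCR duplicates, GC bias, fragment-length bias,
alignment and variant-calling artifacts, and linkage (sites are drawn
independently, so LD pruning on generated matrices removes only
chance correlation). Passing tests therefore demonstrate correctness of
the implemented computations under a clean population-genetic model, not
robustness to upstream wet-lab or alignment pathologies.

## Numerical conventions

- Missing dosage sentinel is −1; all comparisons treat it explicitly.
- Threshold boundaries: missingness is strict (> limit removed), MAF is
  inclusive (≥ threshold kept), LD is strict (> cutoff removed).
- All randomness flows through `numpy.random.default_rng(seed)`; every CLI
  command that draws random numbers takes `--seed` and is byte-reproducible.
- Coordinates: FASTA/BED and fragments are 0-based half-open; VCF positions
  are 1-based, converted at the boundary.

## Known limitations

- `merge_vcfs` holds all calls in memory; it is sized for reduced-
  representation marker sets (10⁴–10⁶ sites), not whole-genome cohorts.
- The LD window is defined in sites, not base pairs.
- The audit assumes taxa form coherent distance clusters; hybrids or
  admixed accessions sit between clusters and can be flagged even when
  correctly labeled — such flags are a starting point for inspection, not
  a verdict.
- NJ is quadratic-to-cubic in sample count; fine for germplasm panels
  (≤ a few hundred samples), not for thousands.
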