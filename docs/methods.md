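# Methods

This note records the models implemented in `spacegt`, the conventions and
defaults chosen where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Seeds and spaced k-mers

A seed is a pattern over {`1`, `0`} whose first and last positions are
care positions; leading or trailing don't-cares would merely shift windows.
Applying a seed of length *l* and weight *w* to a sequence yields one
spaced *w*-mer per window (positions 0 … n−l), taking the characters at the
care offsets. Windows are rejected only when a non-ACGT symbol falls on a
care position; don't-care columns tolerate anything, which maximises usable
windows. Input is upper-cased on ingestion, so soft-masked references count
like unmasked ones. Base qualities are never used.

Canonical form is the lexicographic minimum of a k-mer and its reverse
complement (A<C<G<T). For the forward and reverse strand of the same
window to canonicalise identically, the seed must be palindromic: reversal
then maps the sampled positions onto themselves. Mirror extension takes a
base seed of length *l* and appends its reversal minus the final position,
producing a palindrome of length 2l−1 and weight 2w−1 centred on the base's
last care position. Any base length is accepted; the result length is
always odd.

Counting admissible palindromic seeds: fixing the endpoints and the
mirror symmetry leaves binom(⌊l/2⌋−1, ⌊w/2⌋−1) free choices. The formula
silently over-counts one impossible parity class — an even-length
palindrome necessarily has even weight — so the implementation returns 0
for even *l* with odd *w*. Arithmetic is exact integer throughout; the
counts of interest exceed 10^6.

The heavy counting path packs k-mers two bits per base into uint64 (weights
up to 31), vectorises window extraction, canonicalisation and uniquing in
numpy, and decodes only the distinct k-mers back to strings. A string-level
reference path (`extract_spaced_kmers`) exists for clarity and is asserted
equivalent in the tests.

## Seed sensitivity and design

Sensitivity of a seed is P(≥1 hit) in a region of length *L* whose
positions match i.i.d. with probability *p*; a hit is a placement fully
inside the region with matches at every care position (L−l+1 placements —
the full-containment convention is declared here because published seed
design tools do not always state theirs). The implementation runs a
forward pass over the deterministic automaton of alive seed prefixes
(shift-and with don't-care wildcards), with hits absorbing. The state
space grows only with the seed's internal structure (roughly 2^(l−w));
the weight-16 base seed used throughout evaluates in ~20 ms. Probabilities
stay in linear space: sensitivities of interest are near 1 and the state
probabilities are bounded below by (1−p)^l per step, far from underflow at
these sizes.

Overlap complexity is OC(s) = Σ over shifts i ∈ [−(l−1), l−1] of 2^σ(i),
where σ(i) counts positions at which the seed and its shifted copy both
carry a care position. The shift-0 term 2^w is included; it is constant
across seeds of equal weight, so it never affects ranking. Low OC
correlates with high sensitivity, and contiguous seeds are maximally
regular and score worst — both properties are pinned by exhaustive small
cases in the tests.

The designer hill-climbs OC with first-improvement scans over all
(interior care ↔ interior don't-care) swaps in randomised order; the
iteration budget caps total neighbour evaluations, there are no restarts,
and the search is deterministic given its rng seed. Candidate base lengths
are scored by exact sensitivity and the winner (smallest length on ties)
is mirror-extended. OC drives the moves rather than sensitivity because it
is orders of magnitude cheaper and its ranking agrees with sensitivity in
the regimes exercised here.

## Pangenome graph and unique k-mers

The graph is the reference plus ordered, non-overlapping bubbles. Panel VCF
records must be phased; records with any missing haplotype allele are
dropped, so every retained site assigns an allele to every haplotype.
Records whose reference spans lie closer than the seed length *l* merge
into a single bubble (windows of length *l* would straddle both variants);
the merged alleles are the distinct haplotype subsequences over the merged
span, with the reference subsequence always allele 0, and each allele
remembers the per-record allele indices it was built from so calls can be
decomposed back to the original records on output (ambiguous decompositions
— two different record-level patterns yielding the same sequence — are
emitted as the merged record instead).

A k-mer is *unique* to (bubble, allele) when its total multiplicity across
the whole problem is exactly 1. Multiplicity is accumulated over every
reference chromosome plus every non-reference allele path (allele sequence
with l−1 reference bases of flank on each side); reference-allele path
k-mers are counted through the reference itself, avoiding a double count
that would otherwise erase all reference-allele evidence. A k-mer occurring
in the paths of two different (bubble, allele) homes is dropped from both.
Consequences worth noting: alt-path k-mers whose care positions all miss
the variant coincide with reference k-mers and are excluded, which is
exactly why a SNV is covered by at most *w* informative k-mers; bubbles
inside perfect repeats retain no unique k-mers at all.

Diploid k-mer coverage *c* is estimated from the nonzero count histogram of
unique k-mers belonging to alleles carried by at least half the panel. The
histogram is a mixture with peaks near c/2 (one copy in this sample) and
c (two copies); the estimator smooths with a width-3 boxcar, takes the
modal peak, and returns the mass-weighted position near twice the mode
whenever that doubled position also carries ≥25% of the modal mass — i.e.
it recognises when the mode was the one-copy peak. A flat histogram falls
back to the mean; an empty one returns 0 (no data). Note *c* is k-mer
coverage: even error-free 30× reads of length R give only about
30·(R−l+1)/R expected counts, ~24 at R=150, l=31.

## Genotyping HMM

Hidden state: an ordered pair of panel haplotypes (the implementation works
in the H×H ordered space and aggregates to unordered genotypes at the end).
Initial distribution: uniform, so with no data the genotype posterior is
the panel (Hardy–Weinberg) prior. Transitions: per haplotype,
switch with probability θ_b = 1 − exp(−ρ·d_b), landing uniformly on the H
haplotypes (self included); d_b is the gap between consecutive bubble spans
(min 1). The pair transition factorises, so one forward or backward step is
O(H²) using row/column sums rather than an (H²)² matrix.

Emissions: for each allele *a* owning unique k-mers, with m = copies of
*a* in the state, each observed count is Poisson with mean εc (m=0), c/2
(m=1) or c (m=2). Poisson rather than negative binomial keeps one
parameter; defaults ε = 0.01 and ρ = 10⁻⁵ per bp are exposed everywhere.
Emission log-likelihoods are computed in log space and exponentiated
per-bubble after subtracting the maximum; forward–backward itself runs in
scaled linear space with per-step normalisation. Posteriors per genotype
are forward–backward marginals summed over states inducing the same
unordered allele pair; ties in the argmax break toward more reference
alleles, then lower allele indices, making output deterministic.

Bubbles where no allele owns a unique k-mer get uniform emissions and are
genotyped from LD alone. If such a bubble is the only one on its
chromosome there is no LD context and the call is *undefined* (VCF `./.`);
the same applies when the count table is entirely empty — zero reads carry
no evidence, so emissions are made uniform rather than letting a fixed
c > 0 spuriously favour absent genotypes. The per-chromosome reading of
"no LD context" is deliberate: LD never flows across chromosomes.

## Evaluation

Comparison is unphased (0|1 ≡ 1|0) over a universe of known sites. Truth
sites that are undefined are removed from both sets. A correct non-absent
genotype is a TP; a truth variant that is missed, called absent, called
undefined, or mis-genotyped is an FN; a non-absent claim at a truth-absent
site, or a mis-genotyped truth variant, is an FP (so one mismatch costs
FN+FP). Undefined predictions are never FPs: no claim is made. Per-class
tallies are kept by truth class — 0|0, one reference allele, no reference
allele — and wGC averages the per-class concordances, excluding empty
classes. Variant classes for stratified reports are SNV (1 bp, equal
length), indel (length difference < 50) and SV (≥ 50).

The exact Wilcoxon signed-rank test drops zero differences, assigns average
ranks to tied absolute differences, and enumerates the full sign-assignment
distribution with an integer subset-sum convolution over doubled ranks
(n ≤ 25). The two-sided p is min(1, 2·min(P(W≤w), P(W≥w))); at n = 9 the
floor is 2⁻⁸ ≈ 0.004, and the Bonferroni bound over the study's 24 tests,
min(1, 24p), is therefore never significant — individual p-values are
reported uncorrected, with the bound available.

## Simulator

Reference: i.i.d. uniform ACGT. Variant sites are placed by rejection
sampling (no overlaps, a margin of max(read_length, 200) from the sequence
ends, bounded retries with explicit failure): SNVs (random different
base), indels with geometric lengths (mean 5, capped at 49) and SVs with
geometric lengths above 50 (mean 80), insertions and deletions equally
likely, all VCF-anchored. Derived-allele counts among founders follow a
neutral site-frequency spectrum (P(i copies) ∝ 1/i), so most variants are
rare, as in real cohorts. Panel haplotypes are founder mosaics with
Poisson crossovers (default 10⁻⁵ per bp), which induces LD decaying with
distance; haplotypes 2i and 2i+1 form diploid sample i.

Defaults describe the emulated regime at desk scale: 100 kb reference, 22
panel haplotypes (eleven diploid samples), 150 bp single-end reads at 30×
diploid coverage, substitution error rate 0.087% (the HiSeq-class median);
low-coverage runs use 5× and, where a harsher error regime is wanted, 1%.
Variant densities default to 1.5×10⁻³ SNV, 2.5×10⁻⁴ indel and 2×10⁻⁵ SV
per base — roughly the relative proportions of a human pangenome callset,
scaled to give informative counts on short references. Reads are
substitution-only and single-end: the genotyper consumes reads as a bag of
k-mers, so pairing adds nothing, and substitution errors are the mechanism
the seed comparison is about. Everything is reproducible bit for bit from
the config and its rng seed.

The leave-one-out harness removes a sample's two haplotypes from the
panel, drops variants carried (as alternative) by neither the held-out
truth nor the remaining panel, rebuilds the graph per seed (the merge
radius depends on *l*), counts, genotypes with estimated coverage and
scores against the held-out truth, then runs exact paired Wilcoxon tests
across samples for every seed pair, metric and variant class.

### What the synthetic experiments show — and what they cannot

The cohorts here have uniform random references (few repeats), biallelic
variants only, ideal phasing, no indel sequencing errors and no coverage
bias. Passing tests therefore demonstrate the internal correctness of the
machinery (the HMM matches brute-force enumeration; counting is strand
symmetric and linear; the metrics match their definitions) and the
*direction* of the spaced-seed effect — at 5× coverage with 1% errors,
recall with the weight-31 palindromic spaced seed is at least that of the
contiguous weight-31 seed, because errors on don't-care positions leave
spaced k-mers intact and the covering k-mers fail more independently.
They do not certify effect sizes on real human data, where repeat
structure, multi-allelic sites and platform error profiles dominate; the
problem sizes used in the tests (20 kb, 5–10 haplotypes, 2–3 held-out
samples, five simulation replicates) were chosen as the smallest cohorts
that exercise every code path with stable statistics.

## Known limitations

- Seed weights above 31 are rejected by the packed counter (uint64, 2
  bits/base).
- The Poisson emission underestimates count overdispersion on real data;
  a negative-binomial emission would be the natural extension.
- Coverage estimation assumes a diploid sample and a mostly-rare-variant
  panel; exotic allele-frequency spectra could fool the doubled-peak rule.
- The exact Wilcoxon enumerator is limited to n ≤ 25 pairs by design; the
  study sizes it serves are single-digit.
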