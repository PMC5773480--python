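# Methods

## Background and scope

Strand-seq sequences only the parental DNA template strands of a single
cell, so the orientation of each mapped read (Crick `C` = reference plus
strand, Watson `W` = minus strand) reports which template strand the
cell inherited.  A diploid chromosome is in one of three template-strand
states — WW, WC or CC — and a sister chromatid exchange (SCE) appears as
a switch of exactly one homolog's template, i.e. a one-step move in the
state chain WW ↔ WC ↔ CC at some genomic position.  Cells deficient for
the BLM helicase (Bloom syndrome) show ~10-fold elevated SCE rates, and
mapped SCEs concentrate at guanine-quadruplex (G4) motifs inside
transcribed genes.  This package implements the full analysis chain
needed to make and test that kind of claim — SCE calling from
strand-labelled reads, G4 motif annotation, a gap-aware circular-shift
permutation test of SCE/feature association, recurrent-hotspot
statistics, allele-specific (homolog-resolved) concordance testing and
copy-neutral LOH detection — plus a synthetic data generator that plants
all of these signals with known ground truth.

## Template-strand segmentation and SCE calling

Per cell and chromosome, reads are reduced to a binary Watson/Crick
sequence ordered by position.  The expected Watson fraction is 1, ½ or 0
for WW, WC and CC, up to a symmetric label-error rate ε (default 0.02).

Segmentation is an exact penalized changepoint search (PELT) that
minimizes the negative binomial log-likelihood with a *free* Watson
fraction per segment plus a penalty β per changepoint (default
β = 2·ln n, the BIC charge for a changepoint's two parameters).  The
free-rate cost is essential: a cost constrained to the three states is
blind to many genuine switches, because the WC log-likelihood
(n·log ½) does not depend on the Watson count at all, so a split whose
two halves both classify as WC has exactly zero likelihood gain.  For
speed the search runs on 5-read bins — the binomial cost depends only on
cumulative counts, so restricting boundaries to bin edges is exact for
that boundary lattice — and every boundary is then refined to the
maximum-likelihood read index between its neighbouring boundaries.
Found segments are snapped to the best-likelihood state of the three
(ties prefer WC, which keeps the caller symmetric under a global W↔C
swap), same-state neighbours are merged, and each remaining boundary is
re-localized with the state-constrained likelihood (rates fixed at 1−ε,
½, ε), which is sharper than the free-rate optimum.

An SCE region is the interval between the end of the last read of the
left segment and the start of the first read of the right segment; its
width is the local inter-read distance and therefore the mapping
resolution of the event.  Adjacent segments two steps apart (WW↔CC) are
reported as a stacked pair of SCEs covering the same region rather than
silently dropped.  Chromosomes with fewer than `min_reads` (default 10)
reads are uncallable.  Putative stable rearrangements are removed by
clustering regions across cells at ≥50% reciprocal overlap and deleting
clusters present in more than 5% of cells (both configurable); the
removal threshold is floored at one cell, so for small cell counts a
cluster must still recur in at least two cells before it is treated as
an artifact.

### What "recovering" a planted SCE means

A breakpoint can only ever be localized between the two flanking reads
*of the homolog that switched*.  Reads of the other homolog routinely
fall inside that bracket, and for switches involving the WC state such
reads are label-compatible with both sides, so the called inter-read
region excludes the true breakpoint position roughly half the time for
any caller — this is geometry, not an implementation defect.  The
generator therefore records, for every planted SCE, its observable
localization window (the interval between the flipping homolog's
flanking reads, clamped to contain the breakpoint), and the truth oracle
counts an SCE as recovered when a called region falls within 50 kb of
that window.  50 kb is half the 100 kb bound within which essentially
all SCEs are mapped at this coverage and roughly three orders of
magnitude below the mean distance between planted exchanges, so the
criterion is stringent against false matches while tolerating the
irreducible few-read ambiguity of boundary placement (a short run of
Watson reads just before a WC→WW switch is genuinely more WW-like than
WC-like, and the maximum-likelihood boundary legitimately sits a few
reads early).  At default settings the caller reaches ≈98% recall and
≈99.8% precision under this oracle; the residual misses are provably
undetectable events (breakpoints within about one read of a chromosome
end, or same-homolog double exchanges closer than one inter-read gap).

## G4 motif scanning

Canonical quadruplex-forming motifs are matches of
G<sub>3+</sub>N<sub>1..x</sub>G<sub>3+</sub>N<sub>1..x</sub>G<sub>3+</sub>N<sub>1..x</sub>G<sub>3+</sub>
with loop classes x ∈ {3, 7, 12} (7 is canonical).  The match convention
is the Perl/Python regex convention: greedy runs, lazy loops, leftmost
and non-overlapping per strand (scanning resumes at a match end).  Loop
bases are unrestricted apart from ambiguity codes — in particular loops
may contain G, so a single run of ≥15 Gs satisfies the canonical
pattern; candidates containing N are rejected; any character outside
ACGTN is an error naming the offending position.  Minus-strand motifs
come from scanning the reverse complement and mapping coordinates back.
Because the convention (not just the pattern) determines genome-wide
counts, the test suite pins the scanner to an independently written
backtracking matcher over random sequence.

Controls: A-rich motifs reuse the same scanner with A as the anchor base
(T-runs on the minus strand); "high-GC" control regions are the top
decile of non-overlapping 1 kb tiling windows ranked by GC fraction
(ties broken by position) — the window construction is a package choice,
parameterized so it can be changed.

Gene context: gene bodies are `[min(tss, tes), max(tss, tes))`; genes
are active iff FPKM strictly exceeds 1 (FPKM exactly 1 is silent — the
definition of "active" is a strict inequality and the boundary case is
otherwise undefined); promoters are the 1 kb upstream of the TSS,
clipped at chromosome ends.  A motif inside a gene body lies on the
transcribed (template) strand when its strand is opposite the gene's
annotated sense strand.  A motif overlapping two gene bodies is assigned
to the gene with the larger overlap, ties to the 5'-most gene.

## Circular-shift permutation test

The observed statistic is the number of SCE regions intersecting at
least one feature interval — binary per region, so a region containing
three motifs counts once.  Analyses of motif-scale features use a 10 kb
region-size cutoff (inclusive: resolution ≤ 10 kb is kept); gene- and
promoter-scale analyses use 100 kb.  The null is built by 1,000
permutations; in each, one offset n is drawn uniformly from
[2 Mb, 50 Mb] and every region is moved +n on its own chromosome,
wrapping circularly.  All arithmetic happens in gap-excluded
coordinates: assembly gaps are removed, regions and features are
projected into the compacted coordinate system, and shifted intervals
can therefore never land inside a gap.  Regions wrapping the origin are
split into two arcs for overlap counting; per-chromosome region counts
and gapless lengths are conserved exactly.  A single shared offset per
permutation is the default (preserving the spatial configuration of the
region set); an independent offset per chromosome is available as an
option.  Enrichment is reported relative to the median permuted overlap;
the empirical p-value is the fraction of permutations with overlap at
least (enrichment) or at most (depletion) the observed count, floored at
1/1,000 and reported as "< 0.001" when no permutation reaches the
observed value.  Observed regions overlapping gaps are dropped (counted
in the result) before testing.  No multiple-testing correction is
applied across feature sets; p-values are reported raw.

Under uniform placement of regions the test is calibrated: across 500
null replicates the type-I error at α = 0.05 stays within [0.03, 0.07]
and the p-values pass a Kolmogorov–Smirnov uniformity check, which the
test suite verifies.

## Hotspot statistics

A hotspot candidate is a maximal interval where per-cell-merged SCE
regions from at least 3 distinct cells overlap simultaneously (for
exactly three regions this is their intersection).  Its score is the
probability of seeing the observed number of events in one genome bin of
the hotspot's size if the line's total SCE count were scattered
uniformly over the gap-excluded genome: the exact upper-tail binomial
probability P(X ≥ k), X ~ Binomial(total, length/effective genome),
with a Poisson tail and a Bonferroni-over-bins correction available as
options.  Events can be counted as SCEs (default) or as distinct
libraries.

## Allele-specific motifs, concordance, LOH

In an F1-hybrid genome a SNP can destroy (or create) a quadruplex motif
on one haplotype.  Allele-specific motifs are found by scanning both
haplotype sequences (aligned base-for-base under the SNP-only model) and
keeping motifs with no same-strand overlapping counterpart on the other
haplotype.  An SCE is assigned to a homolog by re-examining
haplotype-tagged reads within ±2 Mb of the region: a haplotype switches
when its Watson fraction changes by ≥0.35 across the region with ≥3
tagged reads on each side; exactly one switching haplotype is an
assignment, otherwise the SCE is uninformative.  The concordance test
takes SCEs whose region overlaps exactly one allele-specific motif and
asks whether the SCE homolog is the motif-bearing homolog; under the
null each informative SCE is a fair coin, and the default p-value is the
one-sided exact binomial tail P(X ≥ concordant) (two-sided available;
results name the mode).

LOH segments are runs of ≥3 consecutive 1 Mb bins (both configurable) in
which one haplotype holds ≥95% of haplotype-informative reads *and* the
total read count stays within 25% of the cell's median bin count — the
copy-number guard that distinguishes copy-neutral LOH from deletions.
Chromosome-scale copy states come from a deliberately naive estimator:
read density per chromosome relative to the per-cell median density,
with thresholds at 1.25× (trisomy) and 0.75× (monosomy).  It assumes
most chromosomes are disomic and needs at least three chromosomes to
form a stable baseline.

## Synthetic data generator

The generator is first-class, tested code; it defines the study
conditions under which every downstream claim is validated.

**Genome.**  Chromosomes are uniform random sequence (default 3 × 30 Mb,
a 1/30-scale genome) with ~2% of each chromosome in assembly gaps
(up to three gap blocks), G4 motifs written at exponentially distributed
spacings with target mean 8.6 kb (run lengths 3–4, loops 1–7 from
{A,T}, both strands; 8-base flanks are cleared of G/C so background
sequence cannot chain into a planted motif), and non-overlapping genes
(20–150 kb, default 200) with a strict 60% active fraction (active FPKM
= 1 + lognormal, silent FPKM uniform on [0, 1)).  The motif track used
downstream is a full rescan of the generated sequence, so planted motifs
plus the rare spontaneous ones (~1 per 45 kb in random sequence vs 1 per
8.6 kb planted) are exactly self-consistent with the scanner.

**Reads.**  Read starts are a homogeneous Poisson process over non-gap
bases at coverage 1.5% of the genome per cell (the 1–2% regime of
single-cell template-strand libraries) with 50 bp reads.  Each
chromosome starts in WW, WC or CC with equal probability; each read
draws its source homolog (fair coin) and carries that homolog's current
template label, flipped with probability 0.02 (`background_noise`) — a
deliberately simple symmetric error model, since no read-level error
rate is established for this assay.

**SCE placement and the enrichment factor.**  Each cell receives
Poisson(`sce_rate_per_cell`, default 2 — a Bloom-like rate scaled to the
90 Mb genome) exchanges.  Placement is a mixture of a uniform component
over non-gap bases and an excess component uniform over G4-motif bases
inside active genes.  `g4_enrichment_factor` is defined on the
*measurement scale*: it is the relative enrichment (observed over median
permuted overlap) that the standard analysis — calling, 10 kb cutoff,
circular-shift permutations against the G4 track — is expected to read
out.  A per-base interpretation (multiplying the point mass of the ~0.3%
of bases inside motifs by 1.2) would shift the region-overlap statistic
by ~0.05%, which no overlap-based analysis could measure; the
measurement-scale definition is what makes "a planted 1.2× excess is
recovered as ~20% enrichment" a well-posed round trip.  The mixture
weight w for a factor f is obtained by pilot calibration:
a pilot dataset with every exchange placed inside an active-gene motif
is simulated and processed with the production caller and cutoff,
yielding (i) p₁, the probability that the called region of a
motif-placed exchange actually covers a motif (well below 1 because of
boundary ambiguity), and (ii) p₀, the null overlap probability of the
same regions under random circular shifts.  Then w = (f−1)·p₀/(p₁−p₀),
which makes the expected relative enrichment equal f by construction.
With f = 1 the weight is exactly 0 and placement is uniform, so null
calibration is exact.  Factors below 1 fall back to per-base thinning of
motif bases (a weak, documented asymmetry).  The realized weight is
recorded in the truth set.

**F1-hybrid mode.**  Heterozygous SNPs are placed at 0.008 per base (the
~20 million heterozygous positions of a 129Sv × Cast/EiJ genome scaled
to base rate), excluding scanned motifs so the engineered
allele-specific set is the exact truth.  A fraction (default 20%) of
planted motifs gets a run-breaking substitution on one haplotype; reads
covering at least one SNP carry their source homolog as a haplotype tag
(~30% of 50 bp reads at this SNP density).  Clonal LOH intervals force
the source homolog of all reads inside them (copy-neutral by
construction); trisomies raise a chromosome's read rate 1.5× with the
duplicated haplotype sampled at ⅔.  A concordance parameter sets the
probability that an exchange arising within 15 kb of an allele-specific
motif is placed on the motif-bearing homolog (0.5 = no causal link);
15 kb matches the scale of called-region extent plus boundary
displacement, so the bias is visible to the region-level concordance
test with limited dilution.

**What the generator does not model** — and therefore what passing tests
do not demonstrate about real data: GC- or mappability-driven coverage
bias, library-preparation artifacts (chimeric reads, duplicates, the
uneven coverage that widens real mapping resolutions to the ~10 kb
median), indels and structural variation between haplotypes (SNP-only
model), sequence-context-dependent error rates, and any biology of *why*
quadruplex structures form (the generator plants positional enrichment,
not thermodynamics).  Genome-scale motif counts on a real reference also
depend on the reference's composition; the synthetic genome only
reproduces the density, not the composition, of the real motif
landscape.

## Numerical and degenerate-input choices

- Segmentation penalty 2·ln n per changepoint; 5-read bins; ε = 0.02.
  State ties prefer WC; all tie-breaks are first-index and symmetric
  under label swap.
- Regions whose boundary reads overlap (possible after refinement) are
  clamped to width 1 so resolution stays positive.
- p-value floor 1/n_permutations, reported as a "< " string alongside
  the numeric value; depletion p computed symmetrically with ≤.
- Median permuted overlap of 0 makes relative enrichment undefined
  (None); p-values remain valid.
- Size cutoffs are inclusive; flanking clips at chromosome bounds;
  subsampling is uniform without replacement.
- The gapless coordinate map is a bijection between non-gap bases and
  [0, effective length); round-trip identity is property-tested.
- Chromosome-size correlation returns R² = 0 when either variable is
  constant (the OLS r is undefined there).
- Zero informative reads in an LOH bin skip the bin without breaking a
  run; a cell with median bin count 0 is skipped entirely.
- Pipeline stage seeds are spawned from the global seed; every report
  row carries the global seed and a config hash, and rerunning a config
  is byte-identical.

## Known limitations

- Two exchanges on the same homolog closer than about one inter-read gap
  cancel and are undetectable in principle; breakpoints within
  ~`min_reads` reads of a chromosome end are likewise uncallable.
- Close opposite-homolog pairs can merge into a WW↔CC double switch
  whose reported location sits between the two true breakpoints.
- The pilot calibration targets the expectation of the enrichment
  read-out; per-replicate values scatter by a few percentage points at
  300 cells, so factor recovery is asserted on medians across seeds.
- The homolog assigner uses a window majority rather than a full
  re-segmentation per haplotype; at the default SNP density its accuracy
  against truth is ≈99%, but it returns "none" for ~25% of SCEs that
  lack enough tagged reads on both sides.
- The hotspot bin probability treats events as independent uniform
  throws; it ignores the mapping-resolution structure of regions and is
  intended for ranking recurrent loci, not as a calibrated genome-wide
  error rate.
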