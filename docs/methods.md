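# Methods

`tedyn` analyses the accumulation of transposable elements (TEs) in
non-recombining regions (NRRs) of fungal mating-type chromosomes, and ships
a ground-truthed simulator so that every stage of the analysis can be
validated without external data. This note documents the models, the
defaults that matter, and the choices made where the design was open.

## Genomic conventions

All internal coordinates are 0-based half-open; GFF3 (1-based closed) and
tabular hit files (1-based inclusive subject coordinates) are converted at
the I/O boundary. Motif counting runs on the forward strand only:
reverse-strand sites are represented by the reverse-complement motif, which
is already part of each site-class definition. `N` never matches a motif;
matching is case-insensitive.

## TE-candidate filtering and annotation

A candidate query passes the repeat criterion when at least 3 of its hits
reach identity ≥ 0.8, alignment length > 100 bp and gapless query coverage
≥ 0.8 (coverage = (qend − qstart + 1)/qlen; the 12-column tabular dialect
carries no query length, so a 13th `qlen` column — the common
`-outfmt "6 std qlen"` idiom — is accepted; without it coverage is unknown
and the hit cannot qualify). For qualifying queries, the 3 passing hits
with the smallest e-values are retained unconditionally; further passing
hits must also meet the secondary e-value threshold — a fixed value, or the
25th percentile (linear-interpolation quantile) of the e-values of
qualifying queries' hits (`"q25"` mode). With a fixed threshold the filter
is idempotent; in `q25` mode the resolved threshold is recorded in the
result so a re-run can reproduce it.

Annotation uses a majority rule over up to four independent evidence labels
(DNA similarity, protein similarity, protein domain, detector); ties keep
all tied labels in lexicographic order, no evidence yields `unclassified`.
Unclassified copies overlapping a gene by ≥ 1 bp are discarded, as is any
copy overlapping an rRNA/ribosomal/mitochondrial hit at e-value ≤ 1e−10.
Putatively intact copies are defined by genomic footprint: 5–7.5 kb for
Copia and Ty3, 5–11 kb for Helitron.

## Compartments

Telomeres are contig ends whose terminal 100 bp contain ≥ 5 overlapping
occurrences of TTAGGG or CCCTAA; subtelomeres are the adjacent 20 kb.
Centromeres seed from the largest stretch of centromeric-repeat hits (hits
merged across gaps ≤ 1 kb — "stretch" is otherwise undefined; arrays are
near-contiguous) on contigs > 20 kb, then extend outward in 1-kb steps
while each candidate extension window's gene-covered fraction stays below
0.25 (the per-step window makes the recursion well defined). Compartment
painting precedence is telomere > subtelomere > centromere > NRR stratum >
PAR > autosome, so every base carries exactly one effective label; TE
content per compartment splits TE intervals at compartment boundaries.

The margin test compares the TE fraction of the 100-kb PAR window flanking
the NRR boundary (each side separately, when both PARs exist) to 100-kb
non-overlapping windows laid left-to-right in autosomal segments at least
100 kb from centromeres, with trailing partial windows discarded; the
reported probability is the fraction of autosomal windows at least as
TE-dense as the margin. Sides with PAR < 100 kb, or genomes with < 30
autosomal windows, are flagged ineligible rather than computed.

## RIP-like index

RIP-type genome defense converts C→T at TCG trinucleotides (CGA on the
reverse complement). Per window (1 kb, final partial window on its own
length): t = (#TTG + #CAA)/(#TCG + #CGA − #overlap) over product and
remaining target sites, n the analogous ratio on non-target contexts
([A,C,G]TG + CA[C,G,T] over [A,C,G]CG + CG[C,G,T] − [A,C,G]CG[C,G,T]), and
the normalized index is t/n − 1. The subtracted overlap motif is TCGA (the
4-mer carrying both a forward TCG and a reverse-strand CGA site); the
config switch `rip.overlap_motif` substitutes any literal variant. Windows
with a vanishing denominator are reported missing, not zero. Per-copy
indices are computed on the copy's own sequence (the windowed track would
mix in flanking sequence), and group means exclude missing values.

For an i.i.d. background with GC fraction g, the asymptotic neutral index
is not exactly zero but −g/(2 − (1−g)/2) — a consequence of the overlap
subtraction terms (without them it is identically 0 for any g). At g = 0.5
this is −0.29; at the simulator's default g = 0.25 it is −0.15, and finite
1-kb windows average closer to zero still. AT-rich backgrounds are also
what RIP-exposed fungal repeat regions actually look like, which is why the
simulator defaults to GC = 0.25.

## LTR divergence and burst-versus-conversion classification

The two LTRs of a retroelement are identical at insertion and then diverge;
likewise the 5'-LTR of a progeny copy and its progenitor's. Within-copy
5'–3' divergence (N2) therefore dates the insertion, and 5'–5' divergence
to the most similar copy (N1) dates the transposition. Divergences are
gamma-corrected Kimura two-parameter distances,

d = (α/2)[(1 − 2P − Q)^(−1/α) − 1] + (α/4)[(1 − 2Q)^(−1/α) − 1],

computed from a global pairwise alignment (match +1, mismatch −1, gap open
−4, gap extend −1; gap and N columns excluded from P, Q and the aligned
length L), multiplied by L. The gamma shape α defaults to 1.0
(configurable; the appropriate value is data-dependent and rarely
reported). As α→∞ the expression converges to plain K2P; `expm1` keeps the
large-α limit numerically exact. Saturated alignments (1 − 2P − Q ≤ 0 or
1 − 2Q ≤ 0) are excluded with a reason rather than clamped. N2 is
re-expressed on the between-copy aligned length so N1 and N2 share a scale.

The closest copy minimizes the 5'-LTR γ-K2P distance, with ties broken by
copy id. The search is pre-screened by edlib edit distance (5 nearest
candidates; exact γ-K2P decides among them) — at burst-level divergences
the two orderings coincide, and the screen turns an O(n²) alignment pass
into an O(n²) byte-level one.

Transposition bursts put (N1, N2) on the first bisector; gene conversion
overwrites an old copy's 5'-LTR, producing small N1 with large N2. The null
spread is simulated as 10,000 points with both coordinates i.i.d.
Poisson(λ), λ = mean observed N2 (unaffected by conversion). "Outside the
cloud" is formalized as a two-sided tail test on D = N2 − N1 against the
simulated D distribution at `alpha_level` (default 0.001): upper-tail
points are conversion candidates, lower-tail points are copies whose true
parent is missing from the assembly, everything else is burst-compatible.
Because a copy's 5'-LTR lineage is shared between N1 and N2, the observed D
has smaller variance than the Skellam null, making the test conservative.
One caveat: when a burst contains many contemporaneous copies, "closest of
k siblings" biases N1 low (a minimum of many draws), shifting D upward; the
false-positive guarantee is therefore calibrated on simulations whose
pairing structure matches the model (two-copy bursts across a range of
ages), and the bias is visible but sub-threshold for large bursts at the
default alpha level.

Burst clusters are single-linkage components at per-site 5'-LTR distance
≤ 0.01 (p-distance via edit distance; at ≤ 1% divergence this equals the
substitution proportion) with ≥ 5 members. Genealogy-stage analyses refuse
datasets under 100 copies (configurable) rather than emit under-powered
output. The NRR pair deficit compares the observed number of closest-copy
pairs with both members in the NRR against the mean over random
permutations of the compartment labels (label multiset preserved).

## Strata and accumulation dynamics

NRR gene runs of a single stratum become blocks; the boundary between
adjacent runs is the midpoint between their inner flanking genes, and
terminal blocks extend to the region bounds. Blocks < 80 kb or with < 2
genes are discarded, and the retained fraction of NRR bases is reported.
TE content is averaged over the a1/a2 haplotypes per species, then over the
species sharing a recombination-suppression event, giving one point per
independent event; a time-zero record (recombining-outgroup autosomal TE
content, age 3e−8 MY — effectively one day, keeping logarithms finite) can
be appended.

Four accumulation models are fitted by least squares and compared by AIC
under a Gaussian likelihood with k = (mean parameters) + 1 for σ²: linear
in t, linear in ln t, a penalized cubic regression spline in t (natural
spline on 5 quantile-placed knots, integrated-squared-second-derivative
penalty, GCV-chosen penalty weight, k = edf + 1), and the asymptotic model
y(t) = y0 + (A − y0)(1 − e^(−rt)) via multi-start nonlinear least squares
(r ∈ {0.1, 0.5, 1, 2, 5}/MY, A ∈ {max y, 1.2·max y}; y0 free by default or
fixed to the time-zero TE content). An additive, standardized
ancestral-size covariable can enter any model. The RSS is floored at 1e−12
in the AIC so noiseless fits stay finite and are then ordered by parsimony.
The fitted curve is summarized by A and t95 = ln(20)/r; r ≤ 0 is flagged
"no plateau". A known property of this comparison: with n ≈ 21 noisy
points, the df-5 spline genuinely wins the AIC in a nontrivial minority of
replicates even when the data are generated from the asymptotic model —
the same behavior is reproduced by the standard GAM stack — so model
selection on a single dataset should be read together with the fitted
parameters.

Phylogenetic signal uses Pagel's λ: GLS regression of TE content on
stratum age with covariance λ·V off-diagonal (V = shared root-path lengths
on the supplied ultrametric tree) and the Brownian diagonal kept; λ̂ by
maximum likelihood on [0, 1], with likelihood-ratio p-values against λ = 0
and λ = 1. Star trees are flagged unidentifiable. Intact-copy fractions
over age are smoothed by local linear regression with tricube weights, the
span chosen on a grid by corrected AIC (AICc with the smoother's effective
degrees of freedom); ≥ 5 points are required.

Standard group tests: paired two-sided Wilcoxon (zero differences dropped,
exact null for n < 50, all-zero input returns p = 1 flagged), ANOVA with
optional blocking/interaction factors plus Tukey-adjusted pairwise
comparisons, and the two-sided Pearson test.

## The synthetic-data generator

The simulator emulates the statistical structure the analysis assumes, not
fungal genome biology in full. It plants: autosomes and a mating-type
contig (PAR–strata–PAR) with telomeric TTAGGG/CCCTAA runs and a tandem
centromeric repeat array flanked by genes dense enough to stop the
extension rule (so detected features equal planted truth exactly); TE
copies of five families (Copia and Ty3 with paired LTRs, Helitron, TIR,
unclassified) placed to per-compartment target fractions, full-length with
probability 0.35 and otherwise truncated; genes in the inter-TE gaps, with
stratum labels inside the NRR; RIP mutation of TE bodies at per-compartment
intensities; and 13-column hit tables giving every planted copy 3–5
qualifying same-genome matches plus five decoy queries that each violate
exactly one retention criterion (identity, length, coverage, match count,
e-value), so a filter defect is pinpointed by which decoy survives.

LTR histories: each family has a root LTR sequence at `family_depth_my`;
a burst ancestor branches off after the root-to-burst stem, and every burst
copy's two LTRs start as the ancestor and accumulate Poisson(μ·a·L)
substitutions per lineage, placed uniformly without indels (so planted
divergences are exact and alignment-free oracles apply; real-data indels
are handled by the aligner). μ defaults to 0.0025 substitutions/site/MY — a
free parameter of the simulation, not an empirical estimate. Conversion
overwrites the 5'-LTR of copies at least 5× older than the youngest burst
with a young donor's 5'-LTR. RIP is applied to TE bodies only, never to
LTRs, so LTR-dating truth stays exact. The a2 haplotype is the a1 sequence
under an independent mutation stream (1e−4/site), supporting the paired
a1-vs-a2 test with a true null.

What the simulator does not emulate — indel evolution, nested insertions,
segmental duplication, selection and drift, GC heterogeneity along
chromosomes, assembly errors — bounds what passing tests show: they
validate the statistical machinery and its calibration, not robustness to
the full messiness of real assemblies.

Default study sizes: 3×400-kb autosomes, 150-kb PARs, strata of 500/400/200
kb at ages 2.5/1.2/0.3 MY with TE targets 0.45/0.35/0.12 (the old-stratum
target reflecting the ~50% plateau, the young stratum far below it);
autosomes at 0.08. The end-to-end check scales this to ~5.1 Mb. The
accumulation-table generator reproduces its stated curve
y(t) = y0 + (A − y0)(1 − e^(−rt)) plus Gaussian noise truncated to
[0, 100]. All randomness flows from one seeded NumPy generator in a fixed
order; a fixed seed reproduces every output byte-for-byte.

## Known limitations

- Closest-copy selection bias in large same-age bursts (above) makes the
  conversion test slightly anti-conservative at loose alpha levels.
- The 25th-percentile e-value threshold is computed after the repeat
  criterion (recorded in output metadata); computing it before is a
  one-line config change but changes retention.
- Stratum ages are inputs; the package does not estimate them, nor dS.
- The spline/negexp AIC comparison is noisy at n ≈ 21 (see above).
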