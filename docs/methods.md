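# Methods

`fermentype` re-implements, as a tested pipeline, the computational side of
a yeast-isolate typing and phenotyping study of a spontaneously fermented
(backslopped) goat milk: in-silico PCR-RFLP species/genotype typing of ITS
amplicons, ITS identity-based species assignment with a single-site G/A
genotype-group call, a chord-distance phylogeny from multilocus
microsatellite genotypes, and threshold-based phenotype scoring with
multivariate and permutation statistics. This note records the models, the
numerical choices, and what the synthetic world does and does not show.

## In-silico PCR-RFLP

Digestion scans one strand of the amplicon for every (possibly
overlapping) match of the enzyme's IUPAC recognition pattern and cuts at
`match_start + cut_offset`. The two enzymes used, HaeIII (GG^CC, offset 2)
and HinfI (G^ANTC, offset 1), are the REBASE-standard definitions; both
sites are palindromic (up to N), so single-strand scanning finds every
cut. Fragment lengths of an unbinned digest always sum to the input
length; this conservation plus equality with a naive sliding-window
scanner are the engine's correctness oracles.

Gel binning removes fragments *strictly below* the detection limit
(default 80 bp). Fragments exactly at the limit are kept, because the
reference table reports 80-bp bands while its footnote excludes only
smaller ones.

Band-pattern matching is rank-pairing after a descending sort: a
reference entry matches iff band counts agree for every enzyme and each
observed band lies within a relative tolerance (default 10%, the typical
sizing error of agarose gel estimates — the original comparison was done
by eye) of its paired reference band. Among multiple matches the smallest
summed absolute deviation wins; ties break by database (table-row) order.
Raising the tolerance can only turn non-matches into matches, never the
reverse.

## ITS species assignment and the G/A group call

Remote database search is replaced by deterministic global pairwise
alignment against a local reference panel, preserving the standard
acceptance rule exactly: a query is assigned to the best hit's species
only at >= 97% identity and >= 95% coverage. Scoring is fixed at match
+1, mismatch -1, gap -2 (linear); identity is computed end-gap-free
(terminal gap columns excluded) so coverage stays meaningful for partial
amplicons. Alignment uses biopython's `PairwiseAligner`; a textbook
dynamic-programming implementation in the test suite independently
reproduces its scores on small inputs.

The multiple alignment is a center-star progressive alignment (center =
sequence with the greatest summed pairwise score; "once a gap, always a
gap" merging). For the nearly identical ITS sequences of conspecific
strains this is effectively exact; de-gapping any output row recovers its
input, which is asserted.

Within *K. marxianus* a single G/A polymorphism in the ITS1-5.8S-ITS2
region splits strains into Group I (G) and Group II (A). Because only a
boxed alignment region, not a coordinate, is known for the site, it is
located by an 8-bp flanking motif (configurable per panel); the allele is
read in the column immediately after the motif, with gaps or other
residues yielding "unknown". Column indices are 0-based internally,
1-based in reports.

## Microsatellite phylogeny

Genetic distance is the Cavalli-Sforza & Edwards (1967) chord distance,

    d_l = (2/pi) * sqrt(2 * (1 - sum_a sqrt(p1(a) p2(a)))),

computed per locus from within-strain allele frequencies and averaged
over the loci both strains carry (pairwise deletion; a pair sharing no
loci is an error, not NaN). Strains are diploid by default (homozygote ->
one allele at 1.0, heterozygote -> two at 0.5); a haploid mode is
provided since yeast ploidy varies. The per-locus distance is bounded by
(2/pi)*sqrt(2) ~ 0.9003, attained when no alleles are shared.

Trees are built with a re-implemented Saitou-Nei neighbor joining:
iteratively join the pair minimizing the Q-criterion, branch lengths from
the standard closed forms, negative estimates clamped to zero with the
excess moved to the sister branch, ties broken toward the smallest
(row, col) index pair for bit-reproducible trees. On additive matrices NJ
recovers the generating tree exactly (to 1e-9), which is the core
correctness oracle; topology also agrees with scikit-bio's NJ on random
matrices.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path; the two farthest leaves end up equidistant from the root to 1e-9,
and a midpoint landing exactly on a node makes that node the root without
inserting a zero-length edge. Model-based ancestry estimation (the
original study's K = 7 Structure/CLUMPP analysis against 350 worldwide
strains) is out of scope; `cluster_separation` — a monophyly report per
label on the rooted tree — is the desk-scale stand-in for "clusters
apart".

## Phenotype statistics

Growth calls: OD630 < 0.2 negative, 0.2–0.4 inhibited, > 0.4 positive.
The source protocol hedges the upper boundary ("above circa 0.4"); the
closed interval [0.2, 0.4] is assigned to INHIBITED here, and both
thresholds are arguments. Replicate cultures are averaged per cell before
analysis, with replicate counts retained.

PCA runs on the standardized matrix (zero mean, unit sample SD per
condition; constant columns are dropped with a warning) via SVD; each
loading's largest-magnitude element is made positive for a deterministic
sign.

The permutational ANOVA uses Euclidean distances on the standardized
matrix (the permANOVA metric was not stated in the source; Euclidean
makes the pseudo-F comparable to the classical one-way F, and the two
coincide exactly on univariate data — asserted in tests; Bray-Curtis is
available). The pseudo-F comes from the partitioning of pairwise squared
distances into between- and within-group sums of squares, and
p = (#{permuted F >= observed F} + 1) / (n_permutations + 1) with a
mandatory seed (default 999 permutations; the source does not state its
count). Groups need at least 2 members: a singleton contributes no
within-group information and cannot be permuted meaningfully, so the
single *K. unispora* strain is excluded from the species-level test (the
published separation claim concerns the three multi-strain species). An
exhaustive mode enumerates all relabelings for n <= 8, making the
tiny-case p an exact fraction.

Rank-sum tests (two-sided, statistic = rank sum of the first group) are
exact by enumeration of all C(n, nA) rank assignments when the combined
sample is <= 20 and untied, otherwise a normal approximation with
midranks, tie correction, and continuity correction. Per-condition group
comparisons star raw p-values at 0.05/0.01/0.001 with no multiplicity
correction, mirroring the original presentation; Benjamini-Hochberg is
available but off by default.

MIC calling: growth at a concentration means OD above the threshold
(default 0.2); the MIC is the lowest concentration with no growth at it
nor above it. Growth at the highest tested concentration censors the call
above the range (MIC undetermined); no growth anywhere censors it below,
flagged at the lowest tested concentration. The wet-lab re-incubation of
borderline wells collapses to this single-threshold rule in silico.

Phytate results are plain arithmetic: percent IP6 degraded =
100·(initial − final)/initial, clipped at 0 with a warning if the final
concentration exceeds the initial. Qualitative trait summaries round
percentages half-up to integers; "n.d." cells are missing data and are
excluded from hyphae denominators (a strain counts toward the denominator
only if at least one hyphae cell is readable).

## Synthetic data

The generators define the conditions under which the pipeline is tested;
they are seeded and byte-identical under a fixed seed.

ITS amplicons are built constructively (pattern -> sequence), never
sampled-and-filtered: a site-free random background receives planted
HaeIII/HinfI sites at positions whose fragment gaps reproduce the target
band pattern after binning, with sub-80-bp filler fragments absorbing the
length mismatch between the two enzymes' patterns. The Group II template
carries the A allele after the flanking motif; the Group I template is
derived from it by shifting one HinfI cut 20 bp upstream (140-bp band ->
120-bp band) and setting G, so the RFLP subgroup and the SNP call are
linked by construction — mirroring the observed co-occurrence of the
120-bp pattern with G and the 140-bp pattern with A. Per-strain copies
receive random substitutions (default 0.5%/site) outside site footprints
and the motif; a substitution that would create a new site is reverted.
Amplicon length is the shortest fitting the patterns (735 bp for
*K. marxianus*); forcing a shorter length is an error.

Microsatellite genotypes are drawn from K ancestral allele-frequency
pools (Dirichlet frequencies over 4 alleles per locus, pools offset by
20 bp so ranges lean disjoint); mosaic strains pick a pool per locus
according to mixing weights. Phenotype matrices are baseline 0.5 OD plus
per-species (default 2.5 SD) and per-group (default 2 SD) mean shifts on
signature condition subsets, plus Gaussian noise (SD 0.1) truncated at
zero, in duplicate replicates — the noise model is a modelling choice,
not an inference from the source. MIC series follow a decreasing Hill
curve (slope 4, top OD 0.8) with log-uniform IC50 extending one dilution
window beyond the tested range so both censoring regimes occur.

What the synthetic world does not emulate: real ITS evolution (indels,
rate heterogeneity), microsatellite mutation processes, growth-curve
kinetics, plate effects, or inter-replicate correlation. Passing tests
therefore demonstrate correctness of the computations and recoverability
of planted structure at study scale, not robustness to every artifact of
real microplate or sequencing data.

## Problem sizes and determinism

The test suite exercises the engines at the collection's own scale
(52 strains, 29 conditions, 999 permutations for the headline test) and
uses 200 null simulations at 199 permutations for the type-I-error
calibration, 200 random 5–8-taxon additive trees for NJ recovery, and
1000 random 700-bp sequences against the digestion oracle. All
randomness is seeded; `scripts/acceptance.py` derives every seed from its
`--seed` argument.
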