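# Methods

`nascenttx` re-creates, as a tested library, the computational route from
strand-specific nascent-transcription (TT-seq-style) coverage to transcribed
enhancer annotations, cell-type-specificity scores, correlation-based
enhancer-promoter (E-P) pairs, and matched-null enrichment statistics.
Everything runs against a built-in synthetic data generator with known
ground truth, so each stage can be verified end to end without external
downloads.

## Coverage model and segmentation

Coverage is stored as fragment-midpoint counts in consecutive 200-bp bins,
one vector per strand and chromosome. Fragment tables are reduced to bins by
the midpoint rule (`floor((start+end)/2)`), and interval counting assigns a
bin to an interval iff the bin midpoint lies inside it — the two conventions
compose exactly, so counting is invertible at bin resolution.

Segmentation uses a two-state hidden Markov model whose emission is
Poisson-log-normal: the count in a bin is Poisson with rate
`exp(mu_s + sigma_s * Z)`, `Z ~ N(0,1)`, per state *s*. The log-normal
mixing absorbs the overdispersion of nascent-RNA coverage that a plain
Poisson HMM cannot. The marginal emission likelihood has no closed form and
is integrated by Gauss-Hermite quadrature (20 nodes by default; the
likelihood of a count depends only on its value, so the quadrature is
evaluated once per unique count). Fitting is Baum-Welch EM: transitions and
the initial distribution have closed-form M-steps; the emission M-step is a
guarded Nelder-Mead maximization of the weighted likelihood per state
(generalized EM — parameters are only accepted when they improve the
objective, which keeps the log-likelihood trace non-decreasing up to
numerical tolerance). Initialization is 2-means on `log1p(counts)`, states
are re-ordered by mean afterwards, and two guards keep the model
identifiable on clean data: a rate floor of 1e-6 for the quiet state (an
all-zero background otherwise drives `mu -> -inf`) and a `sigma` cap of 5
(an all-zero state is unidentifiable in `sigma`). Viterbi decoding breaks
ties toward the untranscribed state (conservative TU calls); maximal runs
of the transcribed state become transcription units (TUs).

TU boundaries can be refined by an exhaustive two-segment
piecewise-constant fit within the two bins around each boundary; with only
bin-level data the refinement snaps to the best bin edge, with per-bp
profiles it is exact to the bp. A boundary never moves further than the
400-bp window.

## Annotation rules

All constants live in one `ClassificationRules` object:

| rule | value | role |
| --- | --- | --- |
| mRNA overlap | >= 25% of a coding gene + exon hit, same strand | mRNA call |
| uaRNA / conRNA / asRNA | TSS < 1 kbp upstream / < 1 kbp downstream / > 1 kbp downstream (overlapping) of an opposite-strand coding TSS | ncRNA classes |
| nc merge gap | 200 bp (1 bin) | bridges mappability gaps |
| activity cutoff | mean FPK >= 20 and every replicate >= 15 | expressed TUs |
| eRNA state window | TSS +/- 500 bp intersects an enhancer-state interval | eRNA call |
| promoter exclusion | eRNA TSS >= 1 kbp from any coding TSS | removes promoter transcripts |
| divergent gap | <= 750 bp between divergent TSSs (overlap allowed) | intergenic eRNA pairs |
| readthrough filter | chains of ncTUs < 5 kbp behind an mRNA/uaRNA; antisense eRNA kept only at >= 2x the FPK of the head TU's last 1 kbp | removes spurious downstream TUs |
| intergenic region | TSS span +/- 500 bp | enhancer construction |
| intragenic region | 750 bp upstream to 500 bp downstream of the antisense TSS (always 1,250 bp) | enhancer construction |

Choices the rules do not force, made here and kept fixed: the nearest
coding TSS resolves ambiguous uaRNA/asRNA host assignment; a TSS exactly
1 kbp downstream classifies as asRNA; the divergent-pair geometry with
overlap allowed is implemented as an outward-body test (the minus-strand
member must extend at least as far left and the plus member at least as far
right as the partner, TSS gap <= 750 bp) so convergent configurations are
excluded without a separate rule; readthrough chains are walked strand-aware
from the 3' end of the head TU.

Quantification over the cross-cell-line union annotation: intragenic
enhancers count only the antisense strand (the eRNA strand) with effective
length `width - 750`; intergenic enhancers sum both strands over the full
width. Union records that mix kinds count as intergenic.

## Normalization

Size factors are the median-of-ratios estimator on gene counts (features
with any zero excluded), verified in the tests against the DESeq2
implementation in pydeseq2. Note an exact property of this estimator:
scaling one of *m* samples by *c* scales its factor by `c^((m-1)/m)`, not
*c*, because the per-feature geometric means absorb `c^(1/m)`; FPK values
shift by a constant common to all samples, so between-sample comparisons are
invariant. Replicate averaging and length normalization commute because
replicates share feature lengths; averaging is arithmetic, after
length normalization.

## Scores

Entropy specificity: `1 - H(p)/log2(n)` with `p_i = x_i / sum(x)`, entropy
in bits, `0*log0 = 0`; 0 = uniform across cell lines, 1 = single-line.
JS specificity w.r.t. line *c*: `1 - sqrt(JS(p, e_c))` with JS in bits and
`e_c` the one-hot indicator. Both are clipped to [0,1] against log
round-off, return missing for all-zero input, and are tested against
independent scipy evaluations (`scipy.stats.entropy`,
`scipy.spatial.distance.jensenshannon`). The entropy score feeds
matched-null covariates; the JS score is the per-line specificity used
elsewhere.

Directionality: promoters use sense (TSS..TSS+1000) and upstream-antisense
(TSS-1150..TSS-150) windows, mirrored on minus-strand genes, and require
>= 10 normalized counts on both strands before a ratio is reported; genes
with an opposite-strand coding gene within +/- 5 kbp of the TSS are excluded.
Intergenic enhancers narrower than 3 kbp get a plus/minus ratio; 'preferred'
means ratio >= 3 or <= 1/3. Cross-cell-line correlation of such ratios
requires >= 5 bidirectional lines and a coefficient of variation > 50%,
computed on the raw normalized counts of the summed (both-window) signal —
the log-vs-raw choice is not forced by the score's definition and is fixed
here.

## Pairing

Promoter anchors are 5'-most TSSs of coding genes with FPK >= 30 in at
least one cell line; enhancer anchors are region midpoints. Nearest (N)
takes the closest active promoter under 500 kbp with no correlation filter
(ties to the leftmost TSS). Correlated-neighboring (CN) tests the nearest
active promoter on each side; correlated-window (CW) tests every active
promoter within +/- 500 kbp; both keep pairs with Pearson r > 0.6 on
`log2(FPK + 1)` across cell lines (replicate-averaged). CW pairs carry a
flag marking targets beyond a closer transcribed promoter. A pair is
attributed to a cell line when both partners are active there. CN ⊆ CW and
the distance/correlation contracts are audited on every pipeline run.

## Matched-null enrichment

Null sets preserve the observed covariate distribution by decile-bin
matching: bins are deciles of the background per covariate, sampling is per
joint bin with replacement, and empty joint bins fall back to the nearest
nonempty bin (L1 on bin coordinates) with a warning. Empirical p-values use
the plus-one rule `p = (1 + #{null >= obs}) / (1 + n_sets)`, so they are
never zero. Matched resampling is only calibrated when the background
dwarfs the observed set (several background members per joint bin);
with three covariates and decile bins that means a background of at least
~50x the joint-bin count.

CHi-C support: a pair counts as supported when an interaction with score
>= 3.0 has its bait fragment covering the promoter TSS and its hit fragment
overlapping the enhancer; pairs closer than 10 kbp are excluded from the
denominator. E-P nulls redraw promoters matched on activity and entropy
specificity, each paired to a random gene-free region matching the observed
enhancer widths and E-P distances. SNP nulls draw trait-set-sized samples
of background SNPs matched on MAF, gene density, and distance to the
nearest gene (LD matching is not modelled).

Super-enhancers: peaks separated by < 12.5 kbp are stitched, stitched
regions ranked by total constituent signal, both axes min-max rescaled, and
the cutoff placed where the central-difference slope of the signal-rank
curve first exceeds 1; regions ranked strictly above it are super-enhancers.
Calls are invariant to uniform signal scaling; with fewer than three
stitched regions the inflection is undefined and everything is typical.

Gene-class enrichment uses Fisher's exact test on 2x2 tables; the odds
ratio is reported as the cross-product `(a*d)/(b*c)` with the `inf`/`0`
conventions at zero cells, the p-value from `scipy.stats.fisher_exact`.

## Synthetic data generator

The generator emulates a 14-cell-line x 2-replicate design on a toy genome.
Genes (6-14 kbp, two exons) and intergenic enhancer sites are placed
without overlap by distributing free space between inflated footprints
(3-kbp margins, so features sit > 5 kbp apart and readthrough chains cannot
bridge them); antisense-eRNA sites go inside sufficiently long gene bodies
at >= 1.4 kbp from the TSS. All feature boundaries are bin-aligned so that
noise-free decoding recovers them exactly. Every enhancer state hosts
either a divergent eRNA pair (TSS gap drawn from {0, 200, 400, 600} bp) or
a single antisense eRNA, and keeps >= 1 kbp distance from any coding TSS
(asserted at generation time).

Activities: a configurable fraction of enhancers (default 0.37) is active
in exactly one cell line; the rest vary log-normally across lines. Active
levels draw from a log-normal with floor 1.2 so planted features sit
clearly above the FPK-20/15 activity cutoff — features at the detection
boundary would not be recoverable truth. A configurable fraction of
enhancers is linked to its nearest gene (at most one enhancer per gene, so
each link carries an unambiguous signal); linked genes mix the enhancer's
activity pattern with baseline noise at weight `coupling` (default 0.8).
Default rates: 10 counts/bin per unit gene activity, 5 for eRNAs,
background 0.05/bin (the background-to-signal ratio is a free choice — the
model only needs the two emission states separable), uaRNA rate =
`ua_fraction` (uniform 0.1-0.5) times the gene rate, mirroring typical
promoter directionality ratios around 3. Per-bin counts are
`Poisson(depth * rate * exp(sigma * Z))` with `sigma = 0.3` and per-sample
log-normal depth factors (`sigma = 0.3`); `noise="none"` emits rounded
expected counts for exact-recovery checks.

Ancillary data: one >= 3.0-scoring 4-kbp bait/hit fragment pair spans every
planted E-P link plus three sub-3.0 decoys per link; trait SNPs fall inside
enhancers with probability `enrichment * background_fraction` and
explicitly outside otherwise (background SNPs are uniform, so enrichment 1
reproduces the background rate exactly); peak signal is enhancer activity
times a Pareto-tailed boost (shape 1.2) whose heavy upper tail makes the
slope-1 rule isolate a small top fraction, as co-activator signal does.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no read-level errors or mappability structure, no
sequence content, no intron/exon coverage difference within genes, no
distance-decay contact background in the interaction table, no LD structure
among SNPs, and feature boundaries are bin-aligned rather than fuzzy. The
recovery results certify the algorithmic chain, not robustness to
alignment artifacts.

## Problem sizes used in the tests

The default demo config runs a 10-Mbp genome with 100 genes, 150 enhancer
states and 14 x 2 samples. The test suite exercises exact truth recovery on
that 10-Mbp scale for one cell line, pairing recall on a 4 x 20-Mbp genome
with 700 genes and >= 500 planted links, null calibration with 50
repetitions of 99 (SNP) and 49 (CHi-C) resamples, and end-to-end
determinism on a 1-Mbp four-line configuration — sizes chosen to probe each
property at the smallest scale where it is statistically meaningful.

## Known limitations

* The HMM is fitted per cell line on pooled replicates (configurable by
  passing different coverage); no joint multi-sample segmentation.
* Boundary refinement is only bp-exact when per-bp profiles are supplied.
* The valley-based activity-cutoff finder is a diagnostic; the fixed
  FPK >= 20 rule is the default.
* Matched SNP nulls do not match on LD (no LD model in the catalog).
* With heavily discrete statistics (tiny interaction tables), empirical
  p-values are conservative at the ties, as expected for the plus-one rule.
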