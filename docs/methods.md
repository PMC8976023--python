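# Methods

`archcomp` compares the 3D genome architecture and regulatory circuitry of
two cellular conditions from Hi-C contact maps, peak calls, and replicate
expression counts. This note records the models behind each stage, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Contact-map model and preprocessing

Contacts are binned raw counts `c_ij` on a fixed genome tiling (0-based,
half-open bins; dense global ids). Balancing is ICE-style iterative
correction: per-bin weights `w_i` are iterated until the marginals of
`w_i c_ij w_j` over unmasked bins are equal (relative marginal variance
below `tol`, default 1e-5), then rescaled so unmasked marginals are 1. Bins
with zero coverage, or with log coverage more than `mad_max` (default 5)
median absolute deviations below the median, are masked. The first diagonal
is zeroed before balancing (self-ligation artifacts). For a symmetric
matrix this fixed point coincides with the Sinkhorn-Knopp equilibrium, which
the tests exploit as an independent oracle.

The distance-decay expectation pools all unmasked intra-chromosomal pairs at
each bin separation `d`; separations above 20 bins share log-spaced
smoothing bins (ratio 1.05) to control long-range variance. Observed/
expected (O/E) divides each balanced entry by the expectation at its
separation; trans entries are divided by a flat trans mean. The diagonal
(d = 0) is excluded throughout.

## Compartments

The first principal eigenvector E1 is computed per chromosome from the
Pearson correlation matrix of the intra-chromosomal O/E map (masked bins
removed), then concatenated. The sign is anchored so E1 correlates
non-negatively with an activity track — gene density by default, binned
ATAC signal as an alternative — and A is defined as E1 > 0. Chromosomes
whose leading eigenvalue explains less than 5 % of total variance are
flagged low-confidence.

Compartmentalization strength is the saddle statistic: bins are ranked by
E1 genome-wide, and with quantile fraction q = 0.2, `AA` is the mean O/E
among top-q pairs, `BB` among bottom-q pairs, `AB` across, using only
intra-chromosomal pairs separated by more than 2 bins; strength =
`AA*BB/AB^2`. A uniform O/E map scores exactly 1, and the statistic is
invariant to global rescaling.

Condition-restricted regions are maximal runs of bins labelled A in one
condition and B in the other (masked bins break runs). Expression shift of
the genes whose TSS falls inside them uses fold changes
`(TPM1 + 0.1)/(TPM2 + 0.1)` on per-condition mean TPM and a two-sided
one-sample Wilcoxon signed-rank test of the log fold changes. With one
pooled TPM value per condition and gene, a signed-rank on log ratios is the
implementable form of a paired location test; this is a deliberate reading,
documented here because two-sample alternatives exist when per-replicate
data are retained. Peak enrichment in restricted regions is
`(fraction of peak midpoints inside) / (fraction of genome covered)`,
tested by circular-shift permutations per chromosome (spacing-preserving),
with an add-one-corrected p-value.

## TADs

The insulation score of bin `i` is `log2` of the mean balanced contact in
the `w x w` diamond spanning the bin over the chromosome mean of that
quantity. The default window is 300 kb at 20-kb bins — deliberately below
the median domain size (~500 kb); a window at or above the domain scale
dilutes boundary prominence and misses shallow boundaries. Near chromosome
ends the diamond shrinks symmetrically (arm >= 3 bins) so edge-proximal
boundaries remain callable. Boundaries are local insulation minima with
prominence >= 0.1; domains are inter-boundary intervals of at least 5 bins.
Boundary sharing between two calls counts a boundary as shared when the
other set has one within +/- 1 bin, reported in both directions and as
their mean.

Intra-TAD strength compares, for a TAD of `s` bins, contacts inside the TAD
with contacts linking the TAD to its immediate same-size flanks. Only
separations present in both pair sets contribute, and they are compared as
per-distance means so distance decay cancels exactly: a decay-only map
scores 0 in expectation, and a block with 4x internal contact scores
exactly 2.0. Pooled (not distance-matched) means would inherit a ~+0.1
log2 bias from decay, which is why strict matching is used. The average-TAD
pileup rescales each TAD plus one flank on each side to a common grid by
area-weighted interpolation of the O/E-normalized window and averages.

## Entropy and 3D structure

Von Neumann entropy treats each chromosome's O/E Pearson correlation matrix
as a density operator: negative eigenvalues are clipped, the spectrum is
normalized to trace 1, and `VNE = -sum(lambda ln lambda)` (natural log).
Computing the entropy on the correlation of O/E — not on the balanced
counts — is essential: the spectrum of the balanced matrix is dominated by
distance decay and its entropy *rises* with added compartment structure,
whereas the correlation spectrum concentrates onto the compartment
eigenvectors, so organised chromatin scores low and dispersed chromatin
high, the direction the biology demands. A strongly checkerboarded map has
near-rank-2 correlation (low VNE); a structureless map approaches the flat
spectrum bound `ln(n)`.

3D reconstruction converts balanced contacts to distances `d = c^(-1/2)`,
completes missing distances by graph shortest path, and embeds with
classical (Torgerson) multidimensional scaling into 3D — fully
deterministic, no random initialization. One resolution is used genome-wide
(mixed intra/inter resolutions are under-specified for a single embedding);
a disconnected contact graph is an error naming the components. Coordinates
are centered; only internal distances are meaningful (rigid motions are
arbitrary), and tests compare distance matrices, not coordinates.

The intermingle index of a bead is the Shannon diversity `H = -sum p_c ln
p_c` of chromosome identities among its k = 20 nearest neighbours in 3D. A
bead is "extensively intermingled" when `H >= ln 2`, the point at which at
least two chromosomes are equally represented. The probability track is the
per-bead indicator smoothed by a 1-Mb running window per chromosome; the
genome mean of this track is the headline scalar. In a territorial nucleus
(low trans contact) the index is near 0; it rises with the trans-contact
level.

## Regulatory circuitry

Promoters are TSS +/- 2 kb (strand-aware TSS, clipped to the chromosome).
Enhancers are H3K27ac peaks not overlapping any promoter; stitching merges
enhancers within 12.5 kb and super-enhancers are those above the elbow of
the ascending rank-signal curve (maximum perpendicular distance to the
chord — the ROSE construction, deterministic and tuning-free).

A promoter-enhancer interaction (PEI) links gene `g` and enhancer `e` on
the same chromosome when their bin separation is in (0, max_dist = 1 Mb],
the O/E contact is >= 2.0, and the raw count support is >= 3. One record is
kept per (gene, enhancer), the best-supported bin pair. Cross-condition
overlap uses the key (gene, enhancer locus), so differing peak calls in the
two conditions still compare by locus identity; percentages are
100*shared/|set|, rounded half-up to two decimals.

The regulatory potential score is `RPS(g) = sum signal(e) * OE(p, e)` over
the gene's PEIs — enhancer activity weighted by spatial contact, with
distance entering only through the contact term. Covariation selects genes
with `log2((RPS1+1)/(RPS2+1)) > 1` and expression log2FC > 1 at BH q <
0.05 from the moderated t-test (below). The strict expression filter keeps
genes with mean TPM above 5 in condition 1 and below 0.5 in condition 2.
Promoter-promoter analysis connects promoter bins with O/E >= 2 at
separations >= 40 kb on the same chromosome and compares per-gene degree
across expression quartiles (rank-sum, top vs bottom).

## Statistics

Rank-sum and signed-rank tests are two-sided; exact by full enumeration for
tie-free samples with n <= 12, otherwise normal approximation with tie and
continuity corrections. Spearman uses average ranks with the
t-approximation. FDR is Benjamini-Hochberg step-up. TPM is
length-normalized counts scaled to 1e6 per sample. The light differential
test (`de_lite`) is a pooled-variance t on log2(TPM+1) with per-gene
variance shrunk halfway toward the mean per-gene variance — a simple
moderated t in the limma spirit, chosen because the comparison needs a
deterministic, dependency-light test; under null simulations it selects
< 2 % of genes at q < 0.05.

## Synthetic data: what it emulates, what it does not

Expected cis contact between bins i < j is

    E[c_ij]  ∝  |i-j|^(-alpha) * gamma^[same compartment]
                * tau^[same TAD] * lam^[planted loop]

scaled so cis totals match `depth`; trans pairs share a flat expectation
sized to the target trans fraction; observed counts are Poisson. Defaults:
alpha = 1.0 (the classic fractal-globule decay), depth 5e6, 3 chromosomes
x 30 Mb at 100-kb bins for compartment/entropy/3D work, and 1 x 10 Mb at
20-kb bins for TAD work (minutes-scale runtimes on one CPU; these desk
sizes are the package's chosen study conditions throughout the tests and
the acceptance script). Compartment labels alternate in geometric runs
(mean 10 bins at 100 kb, kept at ~1 Mb physical scale at 20-kb bins). TAD
sizes are shifted-geometric with a floor of 0.4x the mean (>= 200 kb at
20-kb bins): domains below the insulation-window scale would be unresolvable
by construction and would only measure the caller's floor, not its accuracy.
Planted loops connect gene promoters to same-compartment distal bins
(enhancers are active-chromatin elements; peak placement avoids TSS
neighbourhoods so a planted enhancer is never swallowed by a promoter).
Gene TSSs are placed 80 % into A-compartment bins so that gene density
anchors the E1 sign, as it does in real genomes.

Expression is negative-binomial (variance mu + phi mu^2, phi = 0.05 — the
well-replicated bulk RNA-seq regime) with 4 replicates per condition. Genes
whose TSS lies in an A-to-B switch region carry a planted fold change of
1.48 (condition 1 over condition 2), B-to-A genes 0.59, and genes with a
condition-1-specific loop a 4.0-fold gain, coupling enhancer rewiring to
expression the way the covariation analysis assumes.

Condition 2 differs from condition 1 by flipping 10 % of compartment bins
in contiguous runs, scaling the TAD boost, changing the trans level, and
replacing half of the planted loop set. Two presets bracket the biology:
`stem_like` (gamma 1.2, tau 1.5, trans 0.05, 40 loops — a dispersed,
pluripotent-like nucleus) and `differentiated_like` (gamma 1.5, tau 2.0,
trans 0.25, 60 loops).

The generator does **not** emulate: polymer physics or loop extrusion
dynamics, restriction-fragment or read-level artifacts, copy-number or
mappability biases, replicate-level Hi-C batch effects, sub-compartments,
or nested TAD hierarchies. Passing tests therefore certify that each
statistic recovers the structure it targets under clean planted conditions
with Poisson/NB noise — not that it is robust to every artifact of real
libraries.

## Numerical choices and degenerate inputs

- Balancing convergence: relative marginal variance < 1e-5 (1e-14 in
  oracle-equivalence tests); non-convergence raises, carrying the residual.
- Eigen-decompositions use dense symmetric solvers; a degenerate leading
  pair (gap < 1e-9) in compartment calling is an error, not a warning.
- PSD projection before entropy: negative eigenvalues (possible after
  correlation of noisy O/E) are clipped to 0 and the spectrum renormalized;
  0 ln 0 := 0.
- Ties in rank tests switch the implementation to the corrected normal
  approximation; identical samples give p ~= 1.
- Fold-change pseudocounts: 0.1 on TPM ratios, 1.0 on RPS ratios.
- Percentages are rounded half-up (decimal, not banker's rounding).
- TADs without a full same-size flank (chromosome ends) are skipped with a
  warning in strength computation; an all-skipped set is an error.
- Empty inputs raise (`ValueError`) wherever a statistic would be
  undefined: empty peak sets, empty PEI sets in overlap, all-zero samples
  in TPM, fewer than 2 replicates or maps per condition.

## Known limitations

- The intermingle probability depends on the embedding, which compresses a
  population-average contact map into a single conformation; its absolute
  scale is not comparable to microscopy, only its between-condition
  ordering is interpreted.
- VNE values depend on bin count and normalization convention; only
  relative comparisons at fixed resolution are meaningful.
- The PEI caller thresholds (O/E 2.0, raw 3, 1 Mb) are exposed
  configuration, not estimates; real analyses should calibrate them against
  orthogonal data (e.g. capture Hi-C).
- `de_lite` assumes roughly constant within-group variance on the log
  scale after shrinkage; strongly heteroskedastic designs warrant a full
  NB model instead.
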