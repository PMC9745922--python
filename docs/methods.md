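# Methods

## Reference-guided assembly model

The pipeline assumes the target loci are **low copy**: each read has (at
most) one true origin among the reference loci, so one best placement per
read is reported and pileups stay unambiguous. Reads are anchored by exact
k-mer seeds (forward-strand index; the read and its reverse complement are
queried) and extended by scoring. Extension is gapless on the seed diagonal
whenever that reaches the reporting threshold — optimal when no indel is
needed — with a banded affine-gap alignment (global in the read, free
reference ends, band 15 around the seed diagonal) as fallback. A placement is
reported when its score reaches `min_score_frac × read_length × A`. Ties
break deterministically by (score, locus id, reference start, strand).

Scoring defaults are the mem-style `A=1, B=4, O=6, E=1` with `k=19` and
`min_score_frac=0.5`. The mapping stage of the original tool family exposes
`-A/-B/-O` without published values; the remaining knobs are necessities of
any concrete aligner and are documented package choices. Seeds are taken at
stride `k` first; if no candidate diagonal emerges, every read offset is
scanned, so any read sharing an indexed k-mer with a reference is considered.
Paired-end structure is not used (no rescue, no insert-size model).

Pileup projection keeps everything in reference coordinates: `M` columns
increment the read base's counter at the reference position, `D` increments a
separate deletion counter, and insertions relative to the reference are
discarded. This is what lets per-locus consensus stacks align columnwise
without an external multiple aligner. The cost is that sample-specific
insertions are invisible — acceptable for conserved low-copy loci mapped
against a related taxon's references, and flagged as the main caveat for
highly divergent targets.

## Consensus calling

At each position, depth = sum of A/C/G/T counts. The call is `N` when depth
< `d` (the `-d` knob); otherwise the majority base, or the two-fold IUPAC
code when the second allele reaches `het_fraction` (default 0.25) of the site
depth — a 50/50 tie therefore yields the code, and remaining ties resolve in
A<C<G<T order. Positions where deletions outnumber base observations are
emitted as `-` and count as recovered (a deletion is an observation, not
missing data). `het_fraction` has no published value in the toolchain being
emulated; 0.25 is the package default and configurable.

Depth summary statistics (median, sd) are computed **over positions with
depth ≥ 1**. With partially covered loci, including the zero-depth positions
would drag depth medians to 0 and make the low integer medians (1–5) seen in
real shallow libraries unreachable; users comparing against whole-locus
statistics should be aware of the convention. All standard deviations in the
package use the n−1 denominator.

## Alignment layer

A consensus joins its locus alignment only when its coverage ≥ `C`. Edge
gaps are then converted to `N` (absence of data, not indels); `-T` trimming
removes leading/trailing columns whose occupancy (fraction of rows with a
non-missing character) is below 0.5 — the trimming rule is unquantified in
the emulated tool, so the threshold is a documented package choice. Site
classification ignores `N`, `-`, `?` and IUPAC ambiguity codes entirely: a
variable site has ≥ 2 distinct unambiguous bases, a parsimony-informative
site has ≥ 2 distinct unambiguous bases each in ≥ 2 rows, and gaps never
create variability. `?` is accepted on input as a missing synonym and
normalized to `N`. Missing cells are `N`, `-`, `?`.

Concatenation fills samples absent from a locus with `N` across that
partition and records 1-based inclusive partition coordinates (internal
coordinates are 0-based half-open; conversion happens only at I/O).

Parameter sweeps are run **untrimmed**: trimming interacts with row removal
(dropping a ragged-edged row can raise edge occupancy and lengthen the kept
alignment), which would break the otherwise-guaranteed monotone trends in
`d` and `C`. Sweep tables report missing data both over retained terminals
(`missing_pct`) and over the full library roster with dropped terminals
counted as all-`N` rows (`missing_pct_total`); the latter is the quantity
that is monotone by construction when stringent settings push a whole
terminal out of the matrix.

## Library statistics, correlations, regression

A library summary counts a locus as recovered when ≥ 1 non-`N` base was
called, and takes coverage/depth medians over recovered loci only. The
bundled 16-library Melastomataceae table reproduces its published headline
values under exactly these conventions (n−1 sd, untransformed correlations):
mean 617.7 recovered loci, 57.2 % of reference base pairs, median depth
median 2 (sd 1.365), and Pearson r of 0.65/0.50/0.30 between read counts and
depth median / coverage median / total bp. Library-level correlations are
computed on untransformed values — that is what reproduces the published r —
whereas the log transform applies to the regression analyses.

Collinearity pruning is a greedy scan in column order dropping any column
with |r| > 0.7 against an already-kept column. Relative importance uses the
LMG decomposition: each predictor's sequential R² increment averaged over all
p! orderings (enumerated exactly; subsets cached), normalized to percentages
of the explained variance. LMG is the package's choice of "relative
importance" method — it is the standard one that yields non-negative
percentages summing to 100. The log mask uses natural log; base is
irrelevant to R² and the importance shares.

## Treespace outliers

Quartet topologies are inferred from the four-point condition on topological
(unit-branch) path distances: for tips {i,j,k,l} the pairing with the
strictly smallest distance sum is the induced resolution; a three-way tie
means the quartet is unresolved. This is exact for trees (subdividing any
edge shifts all three sums equally or preserves the strict minimum) and
vectorizes over all C(s,4) subsets. A quartet resolved in both trees but
differently counts 1; resolved in exactly one counts 0.5 (a documented
convention — with fully resolved trees it reduces to the standard count).
Distances are normalized by the number of shared-tip quartets; trees are
restricted to shared tips pair by pair, and pairs with < 4 shared tips are
mean-imputed (loudly logged) so tree indices stay aligned with locus
descriptors.

Ordination is classical PCoA (double centering of −D²/2, eigendecomposition,
negative-eigenvalue axes dropped, no Lingoes/Cailliez correction — quartet
distances at these scales embed adequately). Outliers are flagged by squared
Mahalanobis distance on the first three axes against the chi-square upper
tail (df = 3, p < 0.05), with the sample covariance over all points.
Descriptor comparisons between flagged and unflagged loci use two-sided
rank-sum tests (exact for small tie-free groups, normal approximation with
tie and continuity corrections otherwise) under Holm step-down adjustment.

`nj_tree` (neighbor joining on p-distances that ignore positions where
either sequence is missing or ambiguous) is a diagnostics and testing
utility, deliberately simple; it is not a substitute for model-based tree
inference on real data.

## Simulator: what it emulates, and what it does not

The simulator generates the statistical regime the pipeline consumes: a Yule
topology with floored-exponential branch lengths normalized to unit mean
root-to-tip depth (so `substitutions_per_site` directly sets expected
tip-to-reference divergence; the floor, 0.15 of the mean edge, keeps every
internal edge identifiable at desk-scale sequence volumes — a deliberate
property of a recovery benchmark, since a tree with effectively zero-length
edges is unrecoverable from finite data by any method); Jukes–Cantor
substitution (P(differ) = ¾(1−e^(−4d/3))); references taken from the root
sequence, emulating mapping against a related taxon's transcriptome-derived
references; uniform read shearing with `round(depth × L / read_length)`
reads per locus, per-base error to a uniformly chosen different base, and
random strand. Per-sample target depths may differ, mirroring unequal real
library sizes. Defaults (16 taxa, 50 loci × 500 bp, 100-bp reads, depth 3,
divergence 0.05, error 10⁻³) are scaled-down analogues of a 16-library
shallow-skim study.

Not emulated: indel evolution, paralogy, GC/coverage bias, quality-score
structure, rate heterogeneity, paired-end structure. Passing tests therefore
demonstrate correctness of the assembly logic and its statistical behaviour
under the stated model — not robustness to paralogs or alignment error in
real data.

On interior positions (where every read start is admissible) simulated depth
is exactly Binomial(n_reads, rl/(L−rl+1)), whose tail converges to the
Poisson law P(Poisson(c) ≥ d) as locus length grows. The coverage-law test
asserts the convergence analytically (gap < 0.01 at L = 10,000) and the
simulation against the exact binomial tail within 3 SE over 48 loci —
comparing raw simulation to the asymptotic formula at nominal c would carry
a known ~1 SE finite-size bias and make 3 SE verdicts noise-dominated.

## Validation study sizes

Chosen as the package's own desk-scale design: parameter recovery uses 20
seeds of a 16-taxon, 50-locus × 500-bp simulation at expected depth 8, read
error 10⁻³, assembled at `-d 2 -C 0.1`, requiring the NJ tree on the
supermatrix to match the generating topology (RF 0) in ≥ 95 % of seeds; the
sweep-monotonicity study uses a fixed 12-taxon, 30-locus dataset at depth 6
across d ∈ {2..5} × C ∈ {0.1, 0.3, 0.5, 0.7}; outlier detection plants 8
scrambled topologies among 100 concordant NJ gene trees (16 taxa, 300-bp
loci) and requires ≥ 6/8 found with ≤ 5 % false flags; quartet distances are
checked against exhaustive 4-subset enumeration on 200 random pairs with ≤ 8
tips.

## Numerical and degenerate-input conventions

Empty pileups yield all-`N` consensuses with depth statistics reported as 0;
single-value sds are 0. Zero-variance inputs to Pearson are a hard error, as
are singular regression designs (collinear columns named) and singular
Mahalanobis covariances (fewer axes suggested). Empty locus alignments are
dropped before concatenation with a log line. PCoA eigenvalues below a
relative 1e-12 tolerance count as non-positive. Gzip is detected from the
`.gz` suffix for FASTQ. All seeds are explicit; nothing draws from global
random state.
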