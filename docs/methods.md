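# Methods

## Model and assumptions

Sequencing the mtDNA pool of one cell is treated as a series of Bernoulli
trials: with $N$ fragments sampled at a locus and true WT heteroplasmy
$\pi$, the WT read count is $X \sim \mathrm{Bin}(N, \pi)$. Mitochondrial
turnover makes $\pi$ itself vary between cells of the same population, so
across cells $\Pi \sim \mathrm{Beta}(\alpha, \beta)$ and $X$ follows a
beta-binomial with mean $\theta = \alpha/(\alpha+\beta)$ and dispersion
$\phi = 1/(\alpha+\beta+1)$ (the binomial is the $\phi \to 0$ limit). The
test is deliberately one-sided ($H_1: \pi_i < \theta$): only *loss* of the
WT allele is evidence for a mutation, which presumes at most one mutant
allele per locus. That assumption is quantified by the collision
simulation (below): with ~50 detectable mutations on a 16-kb genome, the
chance that a locus harbours two distinct mutant alleles is ~10⁻³.

Key structural assumptions, in decreasing order of importance:

* mutation events at different loci are independent — each locus is fitted
  and tested separately, and BH correction is applied within a locus
  across cells, never pooled across loci;
* the WT allele is the base with the highest **median raw count** across
  all cells (median of counts, not of frequencies; on even cell numbers
  the midpoint of the central order statistics; ties broken A<C<G<T and
  flagged). The WT profile is computed on *all* imported cells — the depth
  filter applies only to fitting and calling;
* strand information carries no signal for the model: forward and reverse
  counts are summed at import;
* cells with zero depth at a locus are missing, not observations of 0 or 1
  allele frequency; they are excluded from fits and receive NaN p/q.

## Wild-type preselection

Fitting the null on all cells lets a sizeable mutant clone inflate the
fitted dispersion until the clone itself becomes unremarkable. The guard is
a two-component binomial mixture (WT component $\pi_W \ge \pi_M$, weights
summing to 1) fitted by EM:

* initialization at the 10th/90th percentiles of observed wAF with equal
  weights; when both percentiles coincide (rare mutant components) the low
  component starts at the observed minimum;
* E/M iterations until the relative log-likelihood change is below 1e-8 or
  500 iterations; the log-likelihood trace is retained and is
  non-decreasing (a property test enforces this);
* cells with zero density under both components (possible when a component
  sits exactly on a boundary) fall back to prior-weight responsibilities.

Cells are classified by the inclusive lower tail of the *WT component*,
$P = \Pr(X \le m \mid N, \pi_W)$, BH-adjusted across the locus's cells;
adjusted values ≤ 0.05 mark likely mutants, which are excluded from the
null fit. The mixture posterior of the mutant component is exposed as a
diagnostic but not used for selection. Selection can be disabled, and
falls back to all usable cells when fewer than two survive.

Two robustness gates protect the classifier from its own boundary
behaviour, both chosen here as design decisions where the underlying
method is silent:

1. **Separation gate.** On a clean locus, EM happily carves the $m = N$
   atom into its own $\pi = 1$ component; every cell with a single non-WT
   read then has tail probability exactly 0 and would be excluded,
   collapsing the null to zero dispersion and flagging ordinary noise. The
   two-component fit is therefore only *acted on* when (a) it beats a
   single pooled binomial in a likelihood-ratio test (χ², 2 df, 5%) and
   (b) the component heteroplasmies differ by at least `min_separation`
   (default 0.05). Below either bar the classifier uses the pooled
   $\hat\pi$. Heteroplasmy gaps under ~5 points are not distinguishable
   from continuous overdispersion at depths typical of these assays, so
   nothing callable is lost. The gate never alters the reported EM
   estimates — parameter-recovery benchmarks see the raw fit.
2. **Error-rate floor.** If the selected reference cells happen to be all
   pure ($m = N$), the maximum-likelihood null claims literally error-free
   sequencing and any cell with one mismatching read becomes an extreme
   outlier. A fitted mean is therefore capped at $\theta \le 1 - 10^{-4}$
   (a residual per-base error floor below typical raw Illumina error); the
   floored null is the *binomial* at that rate — a free 1-D dispersion
   search at fixed $\theta$ would land on a degenerate U-shaped beta that
   splits cells into "perfect" and "zero" and misbehaves worse than the
   problem it fixes.

## Beta-binomial fitting

The log-pmf is computed with log-beta/log-gamma functions (stable to
$N \sim 10^5$, $\alpha + \beta \sim 10^6$); lower tails are inclusive
cumulative sums of the pmf. Maximum likelihood runs over
$(\log\alpha, \log\beta)$ (Nelder–Mead; parameters clipped to
$[10^{-8}, 10^8]$), initialized by method of moments with the binomial
sampling variance subtracted from the observed wAF variance. Two
post-steps: the fit never returns a point worse than its initialization,
and the binomial boundary ($s = \alpha+\beta$ at the $10^8$ cap, pooled
$\hat\theta$) is preferred whenever finite dispersion improves the
log-likelihood by less than 2 units — the simplex approaches that boundary
only asymptotically, and below ~2 units the "improvement" is sampling
noise on one extra effective parameter. Loci with fewer than two usable
cells are flagged and skipped; a failed locus never aborts the pipeline.

An inclusive tail $\Pr(X \le m)$ is used for both the classifier and the
q-value (the strict inequality sometimes written for these tails differs
by one pmf term; the inclusive version is consistent with summation from
0 and is conservative).

## Defaults

| parameter | default | meaning |
|---|---|---|
| `q_threshold` | 0.01 | per-cell q-value below which a cell is mutant |
| `min_mutant_cells` | 5 | cells with $q <$ threshold needed to report a locus |
| `min_mean_depth` | 5 | per-cell mean mtDNA depth filter (median optional) |
| `classifier_fdr` | 0.05 | BH level of the WT-cell preselection |
| `min_separation` | 0.05 | smallest heteroplasmy gap treated as two populations |
| precision cap | 1e8 | $\alpha+\beta$ ceiling (numerically binomial) |
| $\theta$ cap | 1−1e−4 | residual sequencing-error floor |

The depth filter supports both mean (default) and median statistics since
both conventions are in circulation. For multiome-style datasets a higher
`min_mutant_cells` (e.g. 10) is a plain configuration change.

## Synthetic data generator

`simulate_dataset` emulates the statistical structure the model assumes:
per cell × locus a WT heteroplasmy $\Pi \sim \mathrm{Beta}(\theta s,
(1-\theta)s)$, a depth $N \sim \mathrm{round}(\mathrm{logNormal}(\mu_{\log},
\sigma_{\log}))$, a WT count $\mathrm{Bin}(N, \Pi)$, and the remainder on a
single fixed alternative base per locus (WT bases cycle A,C,G,T across
loci). Planted clones lower $\theta$ to $1-h$ at their locus for their
member cells, where $h$ is the mutant-allele heteroplasmy. Ground truth
(clone membership, per-cell $\theta$, depths) is returned alongside.

Defaults are a clean high-coverage locus: $\theta = 0.999$ with precision
$s = 1000$, i.e. $\beta = 1$ and $\phi \approx 10^{-3}$. The precision was
set so that cell-to-cell heteroplasmy scatter stays below sequencing noise
— with $\beta < 1$ the beta density acquires a heavy lower tail and the
"clean" locus becomes bimodal, which no longer resembles a wild-type locus
at all. Depth defaults ($\mu_{\log}=2$, $\sigma_{\log}=1$, rounded, zeros
permitted and treated as missing) match the benchmark simulations used for
parameter-recovery tests; the end-to-end clone fixtures use
$\mu_{\log}=\log 50$, $\sigma_{\log}=0.3$ for scATAC-like coverage of ~50×.

What the generator does **not** emulate: strand bias, per-position error
profiles, alignment artefacts around the mitochondrial control region,
contamination, index hopping, or correlated depths across neighbouring
loci. Passing tests therefore demonstrate statistical correctness of the
machinery under its own assumptions, not robustness to every artefact of
real libraries; on real data the upstream counters (mgatk, cellSNP-lite)
and their QC remain essential.

Benchmark-style dispersion values quoted as "$\phi$ of 20…160" in common
usage of these simulations cannot be the dispersion $\phi \in (0,1)$
defined above; they are interpreted throughout as the precision
$s = \alpha + \beta$ (so $\alpha = \theta s$, $\beta = (1-\theta)s$).

## Collision simulation

All $16{,}000 \times 3 = 48{,}000$ single-nucleotide mutation events are
enumerated; per repetition $k$ events are drawn uniformly without
replacement (iid draws with whole-row rejection of duplicates — exact, and
cheaper than a per-row shuffle of 48,000 events), and a collision is a
locus receiving ≥ 2 of its 3 alternative alleles. The reported probability
is total collision loci over total sampled mutations; per-repetition and
aggregate ratios coincide because every repetition samples exactly $k$
mutations. The closed-form pair-collision expectation $(k-1)/(E-1)$ serves
as the analytic cross-check (0.001021 at $k=50$, $E=48{,}000$). The genome
length is taken as a round 16,000 ("16 kb"), not 16,569.

## Numerical and degenerate-input choices

* BH adjustment is `statsmodels`' `fdr_bh`; NaN p-values are excluded from
  the adjustment and stay NaN.
* Per-locus fits run through `joblib`; each locus is self-contained, so
  results are bit-identical for any parallel degree.
* Zero-count loci are imported and flagged rather than dropped, keeping
  locus indices aligned with upstream tables.
* Lower tails at $m = N$ are clipped to 1 against cumulative rounding.
* `memo_sort` orders mutations by decreasing clone size and cells by their
  membership vector read as a binary number (descending), ties and
  non-mutant cells keeping original order — making the sort idempotent.
* Cell-type clustering is complete-linkage on Euclidean distances between
  normalized mutation-frequency profiles ($F_{ij} = N_{ij}/T_j$).

## Known limitations

* Loci whose mutant clones sit within `min_separation` of the WT
  heteroplasmy are deliberately not preselected; at extreme depths
  (≫10³×) such clones would become resolvable and the default should be
  lowered.
* The mixing-weight estimate of the classifier is weakly identified when
  the two components are separated by less than about one read at the
  typical depth (e.g. 0.992 vs 1 at depth ~7); per-run estimates scatter
  widely even though they are unbiased in aggregate. This is a property
  of the likelihood surface, not of the optimizer.
* The mutant base of a call is not identified — only loss of WT; reporting
  the gained allele would require a per-base extension of the test.
* RNA-derived counts (with editing artefacts) and indels/multi-allelic
  encodings are out of scope; imports reject non-ACGT alleles.
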