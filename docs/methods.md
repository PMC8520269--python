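# Methods

## The genomic-cline model

In a hybrid zone between two parental populations (P0 and P1), each admixed
individual carries a **hybrid index** h ∈ [0, 1], the genome-wide fraction of
its ancestry derived from P1. A *genomic cline* describes how the ancestry of
one locus departs from that genome-wide average. clinekit works with the
polynomial cline function used by the bgc software:

    ϕ(h) = h + 2h(1 − h)[α + β(2h − 1)],  clamped to [0, 1]

where ϕ is the probability of P1 ancestry at the locus, **α** (cline center)
shifts ancestry toward P1 (α > 0) or P0 (α < 0), and **β** (cline rate) makes
the ancestry transition steeper (β > 0) or wider (β < 0) than neutral. At
α = β = 0 the cline is the diagonal ϕ = h; ϕ(0) = 0 and ϕ(1) = 1 always,
because the 2h(1 − h) factor vanishes at the endpoints. The cubic can leave
[0, 1] for large |α| or |β|; ϕ is clamped, and the pre-clamp polynomial
satisfies the ancestry symmetry ϕ(h; α, β) + ϕ(1 − h; −α, β) = 1, which the
test suite verifies on a dense grid.

clinekit does not run the bgc MCMC itself: it prepares bgc's inputs,
aggregates its posterior output, and interprets the result.

## Posterior aggregation

bgc is typically run as several independent MCMC replicates; its HDF5 output
is dumped to text per parameter by `estpost`. Files must be named
`<prefix>_stat_<param>_<replicate>` with an integer replicate suffix; the
known parameters are `LnL`, `alpha`, `beta`, `hi` (hybrid index),
`gamma_quantile` and `zeta_quantile`. Unknown parameter names are parsed and
stored with a warning rather than rejected, since bgc's parameter set is
model-dependent.

Burn-in and thinning use an explicit, burnin-anchored convention: 0-based
draw indices i ≥ burnin with (i − burnin) mod thin = 0 are retained, giving
⌈(S − burnin)/thin⌉ draws from a replicate of length S. Replicates are then
concatenated in file order with per-draw provenance. The convention is pinned
because retained counts — and therefore every downstream quantile — depend on
it; the test suite checks it against brute-force index enumeration over all
(S ≤ 50, burnin < S, thin ≤ 10).

Trace inspection is advisory: `trace_stats`/`plot_traces` report per-replicate
mean, variance and lag-1 autocorrelation (defined as 0 for a constant trace)
but never block the pipeline; convergence judgment is left to the user, which
matches standard practice for these analyses.

estpost text is parsed with a declared orientation (`entities_as_rows`, the
estpost default, or `samples_as_rows`) rather than sniffed, so parsing is
deterministic.

## Outlier detection

Two per-locus rules, applied independently to α and β:

1. **Credible-interval rule.** The equal-tailed interval at `level` (default
   0.95) is the pair of empirical quantiles at (1 − level)/2 and
   (1 + level)/2, computed with numpy's linear interpolation between order
   statistics — chosen because it is exactly testable against a
   sort-and-interpolate oracle and produces nested intervals as the level
   grows (so raising the level can only remove outliers, never add them).
   A locus is a positive (negative) outlier when the interval lies entirely
   above (below) 0. A highest-posterior-density interval is available as a
   non-default option.

2. **Quantile rule.** bgc reports, per locus, the quantile of α (the γ
   parameter) and β (ζ) within their zero-mean Gaussian conditional priors.
   A locus is an outlier when the posterior *median* of that quantile falls
   outside the central prior mass n, i.e. below (1 − n)/2 or above
   (1 + n)/2. The median (not the mean) is used for robustness. For
   uniformly distributed quantiles this flags a fraction 1 − n of loci, which
   the suite verifies at n ∈ {0.90, 0.95, 0.975}.

The final per-parameter verdict is the OR (`combine="any"`) or AND
(`combine="all"`) of the selected rules; α and β never influence one another,
and "both α- and β-outlier" is a reading of the output, not a constraint.

## Visualization

`phi_curves` evaluates ϕ on a uniform h grid (default 101 points) at the
posterior-median α and β of each locus, and summarizes each admixed
individual's hybrid index as its posterior median; the rendered figure
overlays the curves (outliers colored) above a histogram of hybrid indices.
Point-estimate curves (medians) were chosen over per-draw curve bundles for
legibility and determinism.

`alpha_beta_summary` places loci in (α, β) space: a Gaussian KDE (Scott's
bandwidth, 100×100 grid — purely presentational) plus polygon hulls around
each outlier class (α⁺, α⁻, β⁺, β⁻). Hulls default to convex
(deterministic, dependency-light); a concave mode with a concavity ratio is
available. Classes with fewer than three loci get points but no polygon,
since the hull would be degenerate.

## Genome mapping

Scaffold-level SNP coordinates are lifted to chromosomes through a
scaffold→chromosome table parsed from Minimap2 PAF (target coordinates
0-based half-open, shifted to the internal 1-based inclusive convention) or
a simplified PAFScaff-style TSV. When a scaffold has several hits, the best
one wins: highest mapping quality, ties broken by longest alignment block,
then lexicographic chromosome — arbitrary but deterministic. Lifting is
`chrom_start + pos − 1` on forward scaffolds and
`chrom_start + (scaffold_len − pos)` on reverse ones, which is injective per
scaffold and exactly invertible; unmapped scaffolds stay `UNPLACED` rather
than erroring.

GFF3 gene features (1-based inclusive) are joined by point-in-interval
overlap via an interval tree; when genes overlap, the lowest start coordinate
wins. Ideogram band tables center one band per placed SNP on its chromosome
position — default widths 2 Mb for SNPs inside genes and 0.5 Mb otherwise,
sized for turtle-scale (hundreds of Mb) chromosomes and fully
user-adjustable — clipped to the chromosome bounds, with the SNP's α or β as
the heatmap value; the rendered figure draws each chromosome twice (α left,
β right).

## Environment association

The module consumes a pre-extracted per-sample covariate table (CSV;
raster extraction and niche modelling are deliberately out of scope, keeping
the package dependency-light). `clines_x_environment` fits, by ordinary
least squares with a 95% confidence band from the fit's standard errors:
(a) hybrid index on the covariate, and (b) per requested locus, genotype
class (0/1/2) on the covariate; a binomial-GLM dosage option
(`locus_model="logistic"`) treats the genotype as 2 Bernoulli trials.
Zero-variance covariates are rejected by name.

## Synthetic data

The fixtures module fabricates every input with known truth, as pure
functions of a seed (byte-reproducible files):

- **bgc posteriors**: per-locus α/β draws are independent Normals around the
  true values with spread `posterior_sd` (default 0.2, a typical posterior
  width for well-estimated ddRAD-scale loci); an AR(1) option adds
  autocorrelation for mixing-sensitive tests. Hybrid-index draws are
  Beta-concentrated around each individual's true h; LnL is a stationary
  AR(1) series; γ/ζ quantile draws are the true value's quantile within the
  Normal(0, σ_prior = 1) conditional prior plus small clipped noise.
  `center_noise_sd` optionally offsets each locus's posterior center once
  (shared across replicates, as a common dataset would), reproducing the
  frequentist calibration in which a true-null locus's 95% credible interval
  excludes zero about 5% of the time.
- **genotype datasets**: default 12 + 12 parental and 24 admixed individuals
  at 50 loci, parental allele frequencies near fixation (0–0.1 vs 0.9–1.0,
  a strongly differentiated hybrid zone), admixed h ~ Beta(2, 2), genotypes
  Binomial(2, h·p1 + (1 − h)·p0), 5% missing data, and VCF allele depths
  Poisson(20) split binomially for heterozygotes — consistent by
  construction with the genotypes. Planted-outlier scenarios use 90 null
  loci plus 10 outliers at |effect| = 1.5 with alternating sign.
- **annotation fixtures**: scaffolds tiled on chromosomes with random gaps
  and orientation (PAF + karyotype), non-overlapping genes (GFF3), and a
  covariate table with one variable tracking h linearly and one pure noise.

These generators emulate the *formats and statistical shape* of real data,
not hybrid-zone dynamics: posterior draws are not a real MCMC chain, loci
are unlinked and exchangeable, and depths are ideal. Passing tests therefore
demonstrate the correctness of the aggregation, classification, geometry and
format logic — not the behavior of bgc itself on real data.

## Numerical and edge-case choices

- Genotypes are coded as counts of the second (ALT) allele with −9 as the
  missing sentinel (bgc's convention). VCF calls carrying a third allele,
  and PHYLIP three/four-base IUPAC ambiguities (B, D, H, V), cannot be
  represented under a biallelic coding and become missing (with a warning);
  such loci carry `allele_count > 2` and are removed by the biallelic filter.
- Filter order is fixed and documented: non-biallelic (>2 alleles) →
  monomorphic (<2 alleles) → per-locus missingness → per-individual
  missingness (over surviving loci) → MAF (over surviving individuals'
  non-missing calls) → seeded random subsample. Outputs depend on this
  order; the report records per-stage removals and the removed ids.
- PHYLIP allele order follows first observation, so round-trips are exact
  only up to per-locus allele polarity; VCF round-trips are strict because
  REF/ALT anchor the polarity.
- All randomness flows through explicitly seeded `numpy.random.default_rng`
  streams; no global RNG state is touched.

## Problem sizes

The shipped tests and the reproduction script run on deliberately compact
problems — hundreds to a thousand loci, hundreds of MCMC draws, two
replicates — chosen so the full suite completes in well under a minute while
every code path (including the end-to-end CLI pipeline, run twice to verify
byte-identical tables) is exercised. All sizes scale up trivially.

## Known limitations

- bgc, Introgress, Minimap2/PAFScaff and niche-modelling tools are not
  executed; their inputs are written and their outputs parsed.
- The bgc input dialect (locus/pop headers, two-integer lines, `-9 -9`) is
  pinned by this package's writer/reader pair; bgc itself never published a
  grammar, so verify against your bgc version before production runs.
- The quantile rule's printed threshold convention differs across sources;
  this package uses the central-mass reading ((1 − n)/2, (1 + n)/2), which
  is the only internally consistent two-sided region.
- Per-locus environment fits model genotype class, not Introgress's internal
  ML cline parameters.
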