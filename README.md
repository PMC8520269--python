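# clinekit

Genomic-cline outlier detection and visualization for hybrid-zone SNP data.

When two divergent populations hybridize, most loci introgress at the rate
set by genome-wide admixture — but loci under selection do not. clinekit is
a toolkit for researchers running **Bayesian genomic cline (bgc)** and
**Introgress** analyses on SNP datasets (e.g. ddRAD): it builds their custom
input files from VCF or PHYLIP data, aggregates bgc's MCMC posterior output
across independent replicates, flags α/β outlier loci, draws the standard
cline figures, places outliers on chromosome ideograms, and relates clines
to environmental covariates. It does not run bgc or Introgress themselves.

## The model

Each admixed individual has a hybrid index h ∈ [0, 1], the fraction of its
genome from parental population 1. The probability of population-1 ancestry
at a locus follows the polynomial genomic-cline function

    ϕ(h) = h + 2h(1 − h)[α + β(2h − 1)]      (clamped to [0, 1])

with per-locus **cline center α** (excess ancestry: α > 0 biases toward
population 1) and **cline rate β** (transition steepness: β > 0 steep,
β < 0 wide). Loci are flagged as outliers by two rules, separately for α and
β:

1. **Credible interval** — the equal-tailed posterior interval at `level`
   excludes the neutral value 0 (sign retained);
2. **Prior quantile** — the posterior median of the locus's γ (for α) or ζ
   (for β) quantile within its zero-mean Gaussian conditional prior falls
   outside the central mass n, i.e. below (1 − n)/2 or above (1 + n)/2.

Either rule or any combination (OR/AND) drives the final verdict. See
`docs/methods.md` for conventions, defaults and limitations.

## Worked example

Simulate bgc-style output with 90 neutral loci and 10 planted α-outliers
(|α| = 1.5), then run the core pipeline:

```bash
clinekit simulate posterior --seed 42 --out bgc_runs
clinekit combine --dir bgc_runs --prefix sim --burnin 100 --thin 2 --out combined
clinekit outliers --in combined --level 0.95 --qn 0.95 \
    --methods ci,quantile --combine any --out outliers.tsv
clinekit phiplot  --posterior combined --outliers outliers.tsv --png phi.png
clinekit alphabeta --posterior combined --outliers outliers.tsv --png ab.png
```

The combine step prints what survived burn-in (100 of 500 draws per
replicate) and thinning (every 2nd draw) in each of the 2 replicates:

```
alpha: 400 draws x 100 entities (2 replicates)
beta: 400 draws x 100 entities (2 replicates)
hi: 400 draws x 24 entities (2 replicates)
```

i.e. 2 × ⌈(500 − 100)/2⌉ = 400 retained draws per parameter, for 100 loci
and 24 admixed individuals. The outlier step prints

```
100 loci: 10 alpha outliers, 0 beta outliers
```

— exactly the 10 planted loci, with no false positives among the 90 neutral
ones. `outliers.tsv` holds the per-locus medians, credible intervals, flags
from each rule with signs, and the final verdict; a neutral locus looks like

```
locus_0   alpha_median=0.0097   alpha CI (-0.419, 0.366)   not_outlier
```

`phi.png` shows each locus's ϕ(h) curve (outliers colored) over a histogram
of hybrid indices; `ab.png` shows the loci in (α, β) space with a 2-D
density and convex hulls around each outlier class. Both figures come with
`.tsv` files of the plotted data.

Conversion and the accessory pipelines work the same way:

```bash
clinekit convert --vcf snps.vcf --popmap pops.txt --to bgc --outdir bgc_in
clinekit filter  --phylip snps.phy --popmap pops.txt --maf 0.05 --biallelic \
    --max-missing-locus 0.25 --outdir filtered
clinekit ideogram --outliers outliers.tsv --positions pos.tsv --gff genes.gff \
    --paf scaffolds.paf --karyotype chroms.tsv --outdir ideo
clinekit envassoc --env env.csv --hybrid hi.tsv --covariate bio_track --outdir env
```

The popmap is a two-column file (sample, population) using the reserved
labels `P0`/`P1` for the parental populations; any other label marks an
admixed population.

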