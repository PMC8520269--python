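"""Synthetic input generators with known truth.

Everything the rest of the package consumes can be fabricated here:
bgc/estpost-style posterior replicate files, toy VCF/PHYLIP genotype
datasets with popmaps, scaffold->chromosome PAF maps, GFF3 gene
annotations, and per-sample environmental tables.  Every generator is a
pure function of its seed, so fixture files are byte-reproducible.

These generators emulate the *shape* of real data — bgc's output text, a
variant caller's VCF — not hybrid-zone population dynamics: posterior
draws are independent Normals around the true parameter values (an AR(1)
option adds autocorrelation), and genotypes are binomial draws from
parental or admixture-weighted allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from clinekit.matrix import MISSING, POP_P0, POP_P1, GenotypeMatrix

_BGC_PARAMS = ("LnL", "alpha", "beta", "hi", "gamma_quantile", "zeta_quantile")


@dataclass
class SimulationTruth:
    """Ground truth for a simulated bgc posterior.

    ``true_alpha``/``true_beta`` are the per-locus cline parameters the
    posterior draws are centered on; ``outlier_set`` indexes the loci
    planted as outliers; ``posterior_sd`` is the spread of the simulated
    posterior; ``sigma_prior`` the SD of the zero-mean Gaussian
    conditional prior used for the gamma/zeta quantile parameters.

    ``center_noise_sd`` adds per-locus estimation noise: the posterior
    center of each locus is offset once (shared across replicates, as the
    underlying data would be) by Normal(0, center_noise_sd).  Setting it
    equal to ``posterior_sd`` reproduces the frequentist calibration of a
    well-behaved Bayesian analysis, where the credible interval of a true
    null locus excludes zero at rate ``1 - level``.
    """

    true_alpha: np.ndarray
    true_beta: np.ndarray
    outlier_set: set[int] = field(default_factory=set)
    posterior_sd: float = 0.2
    hybrid_indices: np.ndarray | None = None
    seed: int = 0
    replicate_count: int = 2
    draws_per_replicate: int = 500
    sigma_prior: float = 1.0
    center_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.true_alpha = np.asarray(self.true_alpha, dtype=float)
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        if self.true_alpha.shape != self.true_beta.shape:
            raise ValueError("true_alpha and true_beta must have equal length")
        if self.posterior_sd <= 0:
            raise ValueError("posterior_sd must be > 0")
        n = self.true_alpha.size
        if any(i < 0 or i >= n for i in self.outlier_set):
            raise ValueError("outlier_set indexes outside the locus range")
        if self.hybrid_indices is None:
            rng = np.random.default_rng(self.seed + 7)
            self.hybrid_indices = rng.beta(2.0, 2.0, size=24)
        self.hybrid_indices = np.asarray(self.hybrid_indices, dtype=float)

    @property
    def n_loci(self) -> int:
        return self.true_alpha.size


def planted_outlier_truth(
    n_null: int = 90,
    n_outlier: int = 10,
    effect: float = 1.5,
    posterior_sd: float = 0.2,
    seed: int = 0,
    param: str = "alpha",
) -> SimulationTruth:
    """Truth with ``n_null`` neutral loci and ``n_outlier`` planted outliers.

    Outlier loci get the planted effect (alternating sign) in the chosen
    parameter; the other parameter stays neutral everywhere.
    """
    n = n_null + n_outlier
    values = np.zeros(n)
    signs = np.where(np.arange(n_outlier) % 2 == 0, 1.0, -1.0)
    values[n_null:] = signs * effect
    zeros = np.zeros(n)
    return SimulationTruth(
        true_alpha=values if param == "alpha" else zeros,
        true_beta=values if param == "beta" else zeros,
        outlier_set=set(range(n_null, n)),
        posterior_sd=posterior_sd,
        seed=seed,
    )


def _write_estpost(path: Path, draws_by_entity: np.ndarray) -> None:
    # estpost convention: one entity (locus/individual) per row, draws as columns
    with open(path, "w") as fh:
        for row in draws_by_entity:
            fh.write(",".join(f"{v:.6f}" for v in row) + "\n")


def simulate_bgc_posterior(
    truth: SimulationTruth,
    outdir: str | Path,
    prefix: str = "sim",
    ar1_phi: float = 0.0,
) -> dict[str, list[Path]]:
    """Write estpost-dialect replicate files for every bgc parameter.

    Per replicate: alpha/beta draws are Normal(truth, posterior_sd) per
    locus (independent by default; AR(1) with coefficient ``ar1_phi`` when
    nonzero), hybrid-index draws are Beta-concentrated around each
    individual's true h, LnL is a stationary AR(1) series, and the
    gamma/zeta quantile draws are the true parameter's quantile within the
    Normal(0, sigma_prior) conditional prior plus small clipped noise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    n_loci, n_draws = truth.n_loci, truth.draws_per_replicate
    paths: dict[str, list[Path]] = {p: [] for p in _BGC_PARAMS}

    # estimation noise on the posterior center, shared across replicates
    alpha_center = truth.true_alpha + rng.normal(0.0, truth.center_noise_sd, n_loci) \
        if truth.center_noise_sd else truth.true_alpha
    beta_center = truth.true_beta + rng.normal(0.0, truth.center_noise_sd, n_loci) \
        if truth.center_noise_sd else truth.true_beta

    gamma_center = stats.norm.cdf(alpha_center / truth.sigma_prior)
    zeta_center = stats.norm.cdf(beta_center / truth.sigma_prior)

    def _param_draws(center: np.ndarray, sd: float) -> np.ndarray:
        # entities x draws
        eps = rng.normal(0.0, sd, size=(center.size, n_draws))
        if ar1_phi:
            for t in range(1, n_draws):
                eps[:, t] = ar1_phi * eps[:, t - 1] + np.sqrt(1 - ar1_phi**2) * eps[:, t]
        return center[:, None] + eps

    for rep in range(1, truth.replicate_count + 1):
        blocks = {
            "alpha": _param_draws(alpha_center, truth.posterior_sd),
            "beta": _param_draws(beta_center, truth.posterior_sd),
            "gamma_quantile": np.clip(
                gamma_center[:, None] + rng.normal(0.0, 0.01, size=(n_loci, n_draws)),
                0.0, 1.0,
            ),
            "zeta_quantile": np.clip(
                zeta_center[:, None] + rng.normal(0.0, 0.01, size=(n_loci, n_draws)),
                0.0, 1.0,
            ),
        }
        h = truth.hybrid_indices
        conc = 50.0
        blocks["hi"] = rng.beta(
            np.maximum(h * conc, 1e-3)[:, None],
            np.maximum((1.0 - h) * conc, 1e-3)[:, None],
            size=(h.size, n_draws),
        )
        lnl = np.empty(n_draws)
        lnl[0] = rng.normal(-1000.0, 1.0)
        innov = rng.normal(0.0, 1.0, size=n_draws)
        for t in range(1, n_draws):
            lnl[t] = -1000.0 + 0.5 * (lnl[t - 1] + 1000.0) + innov[t] * np.sqrt(1 - 0.25)
        blocks["LnL"] = lnl[None, :]

        for param, block in blocks.items():
            path = outdir / f"{prefix}_stat_{param}_{rep}"
            _write_estpost(path, block)
            paths[param].append(path)
    return paths


# ---------------------------------------------------------------------------
# genotype data
# ---------------------------------------------------------------------------

_HET_CODE = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


def simulate_genotype_data(
    n_p0: int = 12,
    n_p1: int = 12,
    n_admixed: int = 24,
    n_loci: int = 50,
    p0_freqs: np.ndarray | None = None,
    p1_freqs: np.ndarray | None = None,
    missing_rate: float = 0.05,
    mean_depth: float = 20.0,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """Simulate a hybrid-zone SNP dataset and its standard serializations.

    Parental genotypes are Binomial(2, population allele frequency) draws
    (frequencies near-fixed between parentals by default, as in a strongly
    differentiated hybrid zone); admixed individuals get a Beta(2, 2)
    hybrid index ``h`` and genotypes Binomial(2, h*p1 + (1-h)*p0).  When
    ``outdir`` is given, a VCF (with depth-consistent AD annotations), a
    PHYLIP alignment, and a popmap encoding the same matrix are written.

    Returns a dict with the GenotypeMatrix, true hybrid indices, allele
    frequencies, and any file paths.
    """
    rng = np.random.default_rng(seed)
    if p0_freqs is None:
        p0_freqs = rng.uniform(0.0, 0.1, size=n_loci)
    if p1_freqs is None:
        p1_freqs = rng.uniform(0.9, 1.0, size=n_loci)
    p0_freqs = np.asarray(p0_freqs, float)
    p1_freqs = np.asarray(p1_freqs, float)
    if p0_freqs.size != n_loci or p1_freqs.size != n_loci:
        raise ValueError("allele frequency arrays must have length n_loci")
    if ((p0_freqs < 0) | (p0_freqs > 1) | (p1_freqs < 0) | (p1_freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")

    h_true = rng.beta(2.0, 2.0, size=n_admixed)
    freqs = np.vstack(
        [
            np.tile(p0_freqs, (n_p0, 1)),
            np.tile(p1_freqs, (n_p1, 1)),
            h_true[:, None] * p1_freqs[None, :] + (1 - h_true[:, None]) * p0_freqs[None, :],
        ]
    )
    geno = rng.binomial(2, freqs).astype(np.int16)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING

    sample_ids = (
        [f"p0_ind{i}" for i in range(n_p0)]
        + [f"p1_ind{i}" for i in range(n_p1)]
        + [f"adm_ind{i}" for i in range(n_admixed)]
    )
    pop_labels = [POP_P0] * n_p0 + [POP_P1] * n_p1 + ["ADMIXED0"] * n_admixed

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_loci)]
    alt = np.array([bases[(list(bases).index(r) + 1 + rng.integers(0, 3)) % 4] for r in ref])
    alleles = list(zip(ref.tolist(), alt.tolist()))

    allele_count = np.empty(n_loci, dtype=np.int64)
    for j in range(n_loci):
        col = geno[:, j]
        obs = col[col != MISSING]
        seen = set()
        if (obs < 2).any():
            seen.add(0)
        if (obs > 0).any():
            seen.add(1)
        allele_count[j] = max(len(seen), 1)

    positions = [(f"scaffold_{j % 5}", 1000 + 500 * j) for j in range(n_loci)]
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        locus_ids=[f"snp_{j}" for j in range(n_loci)],
        alleles=alleles,
        genotypes=geno,
        allele_count=allele_count,
        positions=positions,
    )

    result = {
        "matrix": gm,
        "h_true": h_true,
        "p0_freqs": p0_freqs,
        "p1_freqs": p1_freqs,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result["vcf"] = _write_vcf(gm, outdir / "sim.vcf", mean_depth, rng)
        result["phylip"] = _write_phylip(gm, outdir / "sim.phy")
        result["popmap"] = _write_popmap(gm, outdir / "sim.popmap")
        truth_path = outdir / "sim_truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("sample\th_true\n")
            for sid, h in zip(sample_ids[n_p0 + n_p1 :], h_true):
                fh.write(f"{sid}\t{h:.6f}\n")
        result["truth"] = truth_path
    return result


def _write_vcf(gm: GenotypeMatrix, path: Path, mean_depth: float, rng) -> Path:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = sorted({c for c, _ in (gm.positions or [])})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_loci):
            chrom, pos = gm.positions[j]
            a1, a2 = gm.alleles[j]
            cells = []
            for i in range(gm.n_samples):
                g = int(gm.genotypes[i, j])
                if g == MISSING:
                    cells.append("./.:.")
                    continue
                depth = max(int(rng.poisson(mean_depth)), 2)
                if g == 0:
                    ad = (depth, 0)
                elif g == 2:
                    ad = (0, depth)
                else:
                    d1 = int(rng.binomial(depth, 0.5))
                    d1 = min(max(d1, 1), depth - 1)
                    ad = (d1, depth - d1)
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[g]
                cells.append(f"{gt}:{ad[0]},{ad[1]}")
            fh.write(
                f"{chrom}\t{pos}\t{gm.locus_ids[j]}\t{a1}\t{a2}\t.\tPASS\t.\tGT:AD\t"
                + "\t".join(cells)
                + "\n"
            )
    return path


def _write_phylip(gm: GenotypeMatrix, path: Path) -> Path:
    with open(path, "w") as fh:
        fh.write(f"{gm.n_samples} {gm.n_loci}\n")
        for i in range(gm.n_samples):
            seq = []
            for j in range(gm.n_loci):
                g = int(gm.genotypes[i, j])
                a1, a2 = gm.alleles[j]
                if g == MISSING:
                    seq.append("N")
                elif g == 0:
                    seq.append(a1)
                elif g == 2:
                    seq.append(a2)
                else:
                    seq.append(_HET_CODE[frozenset((a1, a2))])
            fh.write(f"{gm.sample_ids[i]}  {''.join(seq)}\n")
    return path


def _write_popmap(gm: GenotypeMatrix, path: Path) -> Path:
    with open(path, "w") as fh:
        for sid, pop in zip(gm.sample_ids, gm.pop_labels):
            fh.write(f"{sid}\t{pop}\n")
    return path


# ---------------------------------------------------------------------------
# genome annotation fixtures
# ---------------------------------------------------------------------------

def simulate_scaffold_map(
    n_scaffolds: int = 5,
    n_chromosomes: int = 2,
    scaffold_len: int = 100_000,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """Scaffold->chromosome placements plus a karyotype, optionally as PAF.

    Scaffolds tile their chromosome with random gaps and random
    orientation; the PAF file carries one high-quality primary hit per
    scaffold (target coordinates 0-based half-open, as Minimap2 writes).
    """
    rng = np.random.default_rng(seed)
    mappings = []
    karyotype: dict[str, int] = {}
    cursor: dict[str, int] = {}
    for s in range(n_scaffolds):
        chrom = f"chr{s % n_chromosomes + 1}"
        start = cursor.get(chrom, 1) + int(rng.integers(0, 10_000))
        orientation = "+" if rng.random() < 0.5 else "-"
        mappings.append(
            {
                "scaffold": f"scaffold_{s}",
                "scaffold_len": scaffold_len,
                "chromosome": chrom,
                "chrom_start": start,
                "orientation": orientation,
                "mapping_quality": 60,
                "block_len": scaffold_len,
            }
        )
        cursor[chrom] = start + scaffold_len
    for chrom, end in cursor.items():
        karyotype[chrom] = end + 50_000

    result = {"mappings": mappings, "karyotype": karyotype}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paf = outdir / "sim.paf"
        with open(paf, "w") as fh:
            for m in mappings:
                tstart0 = m["chrom_start"] - 1  # 1-based -> 0-based half-open
                fh.write(
                    "\t".join(
                        str(v)
                        for v in (
                            m["scaffold"], m["scaffold_len"], 0, m["scaffold_len"],
                            m["orientation"], m["chromosome"], karyotype[m["chromosome"]],
                            tstart0, tstart0 + m["scaffold_len"],
                            m["scaffold_len"], m["block_len"], m["mapping_quality"],
                        )
                    )
                    + "\n"
                )
        kar = outdir / "sim_karyotype.tsv"
        with open(kar, "w") as fh:
            for chrom in sorted(karyotype):
                fh.write(f"{chrom}\t{karyotype[chrom]}\n")
        result["paf"] = paf
        result["karyotype_path"] = kar
    return result


def simulate_gff(
    karyotype: dict[str, int],
    n_genes: int = 5,
    gene_len: int = 20_000,
    seed: int = 0,
    path: str | Path | None = None,
) -> list[dict]:
    """Random non-overlapping gene features on the karyotype, as GFF3."""
    rng = np.random.default_rng(seed)
    chroms = sorted(karyotype)
    genes = []
    for g in range(n_genes):
        chrom = chroms[g % len(chroms)]
        start = int(rng.integers(1, max(karyotype[chrom] - gene_len, 2)))
        genes.append(
            {
                "seqid": chrom,
                "start": start,
                "end": start + gene_len - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
                "gene_id": f"gene_{g}",
            }
        )
    if path is not None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g['seqid']}\tsim\tgene\t{g['start']}\t{g['end']}\t.\t"
                    f"{g['strand']}\t.\tID={g['gene_id']};Name={g['gene_id']}\n"
                )
    return genes


def simulate_env_table(
    sample_ids: list[str],
    h: np.ndarray,
    slope: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    path: str | Path | None = None,
) -> dict:
    """Environmental covariates: one tracking h linearly, one pure noise."""
    rng = np.random.default_rng(seed)
    h = np.asarray(h, float)
    bio_track = slope * h + rng.normal(0.0, noise_sd, size=h.size)
    bio_noise = rng.normal(0.0, 1.0, size=h.size)
    if path is not None:
        with open(path, "w") as fh:
            fh.write("sample_id,latitude,longitude,bio_track,bio_noise\n")
            for sid, ht, bt, bn in zip(sample_ids, h, bio_track, bio_noise):
                lat = 34.0 + 2.0 * ht + rng.normal(0, 0.05)
                lon = -94.0 + rng.normal(0, 0.3)
                fh.write(f"{sid},{lat:.5f},{lon:.5f},{bt:.6f},{bn:.6f}\n")
    return {"bio_track": bio_track, "bio_noise": bio_noise}
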