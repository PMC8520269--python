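import numpy as np
import pytest

from clinekit.matrix import MISSING, GenotypeMatrix
from clinekit.fixtures import (
    planted_outlier_truth,
    simulate_bgc_posterior,
    simulate_genotype_data,
)
from clinekit.posterior import combine_all


@pytest.fixture(scope="session")
def geno_dataset(tmp_path_factory):
    """Synthetic hybrid-zone SNP dataset with VCF/PHYLIP/popmap on disk."""
    outdir = tmp_path_factory.mktemp("geno")
    return simulate_genotype_data(outdir=outdir, seed=11), outdir


@pytest.fixture(scope="session")
def posterior_dir(tmp_path_factory):
    """bgc-style replicate files for a planted-outlier truth."""
    outdir = tmp_path_factory.mktemp("post")
    truth = planted_outlier_truth(n_null=90, n_outlier=10, effect=1.5,
                                  posterior_sd=0.2, seed=21)
    simulate_bgc_posterior(truth, outdir, prefix="run")
    return truth, outdir


@pytest.fixture(scope="session")
def combined_posteriors(posterior_dir):
    truth, outdir = posterior_dir
    return truth, combine_all(outdir, "run", burnin=100, thin=2)


@pytest.fixture(scope="session")
def run_pipeline():
    """Callable running simulate -> combine -> outliers -> phiplot -> alphabeta.

    Returns the bytes of every tabular artifact so determinism can be
    asserted across runs.
    """
    from pathlib import Path

    from click.testing import CliRunner

    from clinekit.cli import main

    def _run(root: Path, seed: int) -> dict[str, bytes]:
        runner = CliRunner()

        def invoke(args):
            result = runner.invoke(main, args, catch_exceptions=False)
            assert result.exit_code == 0, result.output
            return result

        post, comb = root / "post", root / "comb"
        invoke(["simulate", "posterior", "--seed", str(seed), "--out", str(post)])
        invoke(["combine", "--dir", str(post), "--prefix", "sim",
                "--burnin", "100", "--thin", "2", "--out", str(comb)])
        invoke(["outliers", "--in", str(comb), "--methods", "ci,quantile",
                "--out", str(root / "outliers.tsv")])
        invoke(["phiplot", "--posterior", str(comb),
                "--outliers", str(root / "outliers.tsv"),
                "--png", str(root / "phi.png")])
        invoke(["alphabeta", "--posterior", str(comb),
                "--outliers", str(root / "outliers.tsv"),
                "--png", str(root / "ab.png")])
        for artifact in ("outliers.tsv", "phi.png", "phi.tsv", "ab.png", "ab.tsv"):
            assert (root / artifact).exists(), artifact
        assert (comb / "posterior_provenance.json").exists()
        return {name: (root / name).read_bytes()
                for name in ("outliers.tsv", "phi.tsv", "ab.tsv")}

    return _run


@pytest.fixture
def toy_matrix():
    """The 4-individual x 5-locus hand-enumerated filtering toy.

    L1 = [0,1,2,1] (clean, common), L2 = [M,M,0,0] (50% missing),
    L3 = [0,0,0,0] (monomorphic), L4 = [0,0,0,1] (MAF 0.125),
    L5 triallelic.
    """
    geno = np.array(
        [
            [0, MISSING, 0, 0, 0],
            [1, MISSING, 0, 0, 1],
            [2, 0, 0, 0, 0],
            [1, 0, 0, 1, 2],
        ]
    )
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        pop_labels=["P0", "P0", "P1", "ADMIXED0"],
        locus_ids=["L1", "L2", "L3", "L4", "L5"],
        alleles=[("A", "C"), ("A", "G"), ("A", "T"), ("C", "T"), ("G", "A")],
        genotypes=geno,
        allele_count=np.array([2, 2, 1, 2, 3]),
    )
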