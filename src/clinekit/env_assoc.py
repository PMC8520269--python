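"""Association of genomic clines with environmental covariates.

Consumes a pre-extracted per-sample covariate table (e.g. BioClim raster
values at sample localities) and relates it to (a) genome-wide hybrid
indices and (b) per-locus genotype clines, via ordinary least-squares
regression with 95% confidence bands (a logistic option is available for
the per-locus fits).  Raster handling and niche modelling are upstream of
this module: it starts from the extracted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clinekit.matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class EnvSample:
    """Per-sample environmental record; hybrid index is joined later by id."""

    sample_id: str
    covariates: dict[str, float] = field(default_factory=dict)
    latitude: float | None = None
    longitude: float | None = None
    hybrid_index: float | None = None


@dataclass
class RegressionSummary:
    """One fitted line: slope/intercept, correlation, p-value, CI band."""

    x_name: str
    y_name: str
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    band: pd.DataFrame  # x, fit, ci_lo, ci_hi


def read_env_table(path: str | Path) -> list[EnvSample]:
    """Read a CSV of per-sample covariates.

    Requires a ``sample_id`` column; ``latitude``/``longitude`` are
    optional; every remaining column is a covariate.  Duplicate sample ids
    and non-numeric covariate cells are errors (with the offending cell
    named); empty cells are retained as missing with a warning.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    cov_cols = [c for c in df.columns if c not in ("sample_id", "latitude", "longitude")]
    if not cov_cols:
        raise ValueError(f"{path}: no covariate columns found")

    samples: list[EnvSample] = []
    for i, row in df.iterrows():
        covs: dict[str, float] = {}
        for c in cov_cols:
            cell = row[c]
            if pd.isna(cell):
                logger.warning("%s: row %d, column %r: missing covariate", path, i, c)
                covs[c] = float("nan")
                continue
            try:
                covs[c] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {i}, column {c!r}: non-numeric covariate {cell!r}"
                ) from None
        samples.append(
            EnvSample(
                sample_id=str(row["sample_id"]),
                covariates=covs,
                latitude=float(row["latitude"]) if "latitude" in df.columns and pd.notna(row["latitude"]) else None,
                longitude=float(row["longitude"]) if "longitude" in df.columns and pd.notna(row["longitude"]) else None,
            )
        )
    return samples


def join_hybrid_index(env: list[EnvSample], hybrid: dict[str, float]) -> list[EnvSample]:
    """Attach hybrid indices (by sample id) to the environmental records."""
    for s in env:
        if s.sample_id in hybrid:
            h = float(hybrid[s.sample_id])
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"hybrid index {h} for {s.sample_id!r} outside [0, 1]")
            s.hybrid_index = h
    return env


def _ols_with_band(x: np.ndarray, y: np.ndarray, x_name: str, y_name: str,
                   band_points: int = 50, level: float = 0.95) -> RegressionSummary:
    import statsmodels.api as sm
    from scipy import stats

    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.allclose(x.var(), 0.0):
        raise ValueError(f"covariate {x_name!r} has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), band_points)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=1.0 - level)
    band = pd.DataFrame(
        {
            "x": grid,
            "fit": pred["mean"].to_numpy(),
            "ci_lo": pred["mean_ci_lower"].to_numpy(),
            "ci_hi": pred["mean_ci_upper"].to_numpy(),
        }
    )
    r, _ = stats.pearsonr(x, y)
    return RegressionSummary(
        x_name=x_name,
        y_name=y_name,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r=float(r),
        p_value=float(fit.pvalues[1]),
        n=int(x.size),
        band=band,
    )


def clines_x_environment(
    env: list[EnvSample],
    covariate: str,
    gm: GenotypeMatrix | None = None,
    loci: list[str] | None = None,
    level: float = 0.95,
    locus_model: str = "ols",
) -> tuple[RegressionSummary, dict[str, RegressionSummary]]:
    """Regress hybrid index — and, optionally, per-locus genotype clines —
    on an environmental covariate.

    The genome-wide fit regresses hybrid index on the covariate.  For each
    requested locus, the genotype class (0/1/2 copies of allele 2) of the
    samples is fit against the covariate, by OLS or logistic regression on
    the allele dosage fraction (``locus_model="logistic"``).  Returns the
    hybrid-index summary and a per-locus summary map.
    """
    pairs = [
        (s.covariates.get(covariate), s.hybrid_index, s.sample_id)
        for s in env
        if s.hybrid_index is not None and covariate in s.covariates
        and np.isfinite(s.covariates[covariate])
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 samples with both covariate and hybrid index")
    x = np.array([p[0] for p in pairs], dtype=float)
    h = np.array([p[1] for p in pairs], dtype=float)
    hi_fit = _ols_with_band(x, h, covariate, "hybrid_index", level=level)

    locus_fits: dict[str, RegressionSummary] = {}
    if gm is not None and loci:
        sample_to_x = {
            s.sample_id: s.covariates[covariate]
            for s in env
            if covariate in s.covariates and np.isfinite(s.covariates[covariate])
        }
        idx_of = {sid: i for i, sid in enumerate(gm.sample_ids)}
        for lid in loci:
            if lid not in gm.locus_ids:
                raise ValueError(f"locus {lid!r} not in genotype matrix")
            j = gm.locus_ids.index(lid)
            xs, gs = [], []
            for sid, xv in sample_to_x.items():
                i = idx_of.get(sid)
                if i is None:
                    continue
                g = int(gm.genotypes[i, j])
                if g == MISSING:
                    continue
                xs.append(xv)
                gs.append(g)
            xs_arr, gs_arr = np.asarray(xs, float), np.asarray(gs, float)
            if locus_model == "logistic":
                locus_fits[lid] = _logistic_with_band(xs_arr, gs_arr, covariate, lid, level)
            else:
                locus_fits[lid] = _ols_with_band(xs_arr, gs_arr, covariate, lid, level=level)
    return hi_fit, locus_fits


def _logistic_with_band(x: np.ndarray, g: np.ndarray, x_name: str, y_name: str,
                        level: float = 0.95, band_points: int = 50) -> RegressionSummary:
    """Binomial GLM of allele dosage (g/2 of 2 trials) on the covariate."""
    import statsmodels.api as sm
    from scipy import stats

    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.allclose(x.var(), 0.0):
        raise ValueError(f"covariate {x_name!r} has zero variance")
    X = sm.add_constant(x)
    fit = sm.GLM(np.column_stack([g, 2 - g]), X, family=sm.families.Binomial()).fit()
    grid = np.linspace(x.min(), x.max(), band_points)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=1.0 - level)
    band = pd.DataFrame(
        {
            "x": grid,
            "fit": 2.0 * pred["mean"].to_numpy(),
            "ci_lo": 2.0 * pred["mean_ci_lower"].to_numpy(),
            "ci_hi": 2.0 * pred["mean_ci_upper"].to_numpy(),
        }
    )
    r, _ = stats.pearsonr(x, g)
    return RegressionSummary(
        x_name=x_name,
        y_name=y_name,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r=float(r),
        p_value=float(fit.pvalues[1]),
        n=int(x.size),
        band=band,
    )


def association_table(
    hi_fit: RegressionSummary, locus_fits: dict[str, RegressionSummary]
) -> pd.DataFrame:
    rows = [
        {
            "target": fit.y_name,
            "covariate": fit.x_name,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r": fit.r,
            "p_value": fit.p_value,
            "n": fit.n,
        }
        for fit in [hi_fit, *locus_fits.values()]
    ]
    return pd.DataFrame(rows)


def plot_clines_x_environment(
    hi_fit: RegressionSummary,
    locus_fits: dict[str, RegressionSummary],
    env: list[EnvSample],
    covariate: str,
    path: str | Path,
) -> Path:
    """Two-panel figure: per-locus clines vs covariate, and h vs covariate."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_a, ax_b) = plt.subplots(1, 2, figsize=(10, 4))
    for lid, fit in locus_fits.items():
        ax_a.plot(fit.band["x"], fit.band["fit"], label=lid, lw=1.2)
        ax_a.fill_between(fit.band["x"], fit.band["ci_lo"], fit.band["ci_hi"],
                          alpha=0.2, color="0.5")
    ax_a.set_xlabel(covariate)
    ax_a.set_ylabel("genotype class")
    if locus_fits:
        ax_a.legend(frameon=False, fontsize=7)

    xs = [s.covariates.get(covariate) for s in env if s.hybrid_index is not None]
    hs = [s.hybrid_index for s in env if s.hybrid_index is not None]
    ax_b.scatter(xs, hs, s=12, c="0.3")
    ax_b.plot(hi_fit.band["x"], hi_fit.band["fit"], color="crimson", lw=1.5)
    ax_b.fill_between(hi_fit.band["x"], hi_fit.band["ci_lo"], hi_fit.band["ci_hi"],
                      alpha=0.3, color="0.5")
    ax_b.set_xlabel(covariate)
    ax_b.set_ylabel("hybrid index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
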