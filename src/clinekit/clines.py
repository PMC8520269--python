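"""Genomic-cline curves and alpha-beta outlier-space summaries.

The per-locus ancestry probability is the polynomial genomic-cline function

    phi(h) = h + 2 h (1 - h) [alpha + beta (2 h - 1)],   clamped to [0, 1],

where ``h`` is the individual's hybrid index (fraction of the genome from
parental population 1), ``alpha`` shifts the cline center (excess
population-1 ancestry when positive) and ``beta`` changes the cline rate
(steep when positive, wide when negative).  At alpha = beta = 0 the cline
is the neutral diagonal phi = h, and phi(0) = 0, phi(1) = 1 always.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clinekit.outliers import OutlierClassification
from clinekit.posterior import PosteriorSamples


def phi_raw(h, alpha: float, beta: float):
    """The cline polynomial before clamping (used for symmetry checks)."""
    h = np.asarray(h, dtype=float)
    return h + 2.0 * h * (1.0 - h) * (alpha + beta * (2.0 * h - 1.0))


def phi(h, alpha: float, beta: float):
    """Probability of population-1 ancestry at hybrid index ``h``.

    ``h`` may be a scalar or array in [0, 1]; values outside raise.  The
    polynomial can leave [0, 1] for large |alpha| or |beta| and is clamped.
    """
    h = np.asarray(h, dtype=float)
    if np.any((h < 0.0) | (h > 1.0)):
        raise ValueError("hybrid index h must lie in [0, 1]")
    out = np.clip(phi_raw(h, alpha, beta), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ClineCurveSet:
    """Per-locus phi curves on a common hybrid-index grid."""

    locus_ids: list[str]
    h_grid: np.ndarray
    phi: np.ndarray  # loci x grid
    hybrid_index_by_individual: np.ndarray
    alpha_outlier: np.ndarray = field(default=None)
    beta_outlier: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.phi, index=self.locus_ids, columns=np.round(self.h_grid, 10))
        df.index.name = "locus"
        return df


def phi_curves(
    posteriors: dict[str, PosteriorSamples],
    classifications: list[OutlierClassification] | None = None,
    grid_size: int = 101,
) -> ClineCurveSet:
    """Evaluate phi for every locus at posterior-median alpha/beta.

    The hybrid-index axis is a uniform grid of ``grid_size`` points on
    [0, 1]; per-individual hybrid indices are summarized as posterior
    medians of the ``hi`` parameter for the marginal histogram.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    for p in ("alpha", "beta"):
        if p not in posteriors:
            raise ValueError(f"posterior for {p!r} is required")
    a_med = posteriors["alpha"].medians()
    b_med = posteriors["beta"].medians()
    if a_med.size != b_med.size:
        raise ValueError("alpha and beta posteriors have different locus counts")
    h_grid = np.linspace(0.0, 1.0, grid_size)
    curves = np.vstack([phi(h_grid, a, b) for a, b in zip(a_med, b_med)])
    hi = posteriors["hi"].medians() if "hi" in posteriors else np.empty(0)

    if classifications is not None:
        locus_ids = [c.locus_id for c in classifications]
        if len(locus_ids) != a_med.size:
            raise ValueError("classification list does not match locus count")
        a_out = np.array([c.alpha_final for c in classifications])
        b_out = np.array([c.beta_final for c in classifications])
    else:
        locus_ids = [f"locus_{j}" for j in range(a_med.size)]
        a_out = np.zeros(a_med.size, dtype=bool)
        b_out = np.zeros(a_med.size, dtype=bool)

    return ClineCurveSet(
        locus_ids=locus_ids,
        h_grid=h_grid,
        phi=curves,
        hybrid_index_by_individual=np.asarray(hi, dtype=float),
        alpha_outlier=a_out,
        beta_outlier=b_out,
    )


def plot_phi(ccs: ClineCurveSet, path: str | Path) -> Path:
    """Render the phi-vs-hybrid-index plot with a marginal h histogram.

    Outlier loci (alpha or beta) are drawn in color over the gray
    non-outlier background curves, mirroring the conventional cline figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax, axh) = plt.subplots(
        2, 1, figsize=(6, 6), sharex=True,
        gridspec_kw={"height_ratios": [4, 1], "hspace": 0.08},
    )
    out = ccs.alpha_outlier | ccs.beta_outlier
    for j in np.flatnonzero(~out):
        ax.plot(ccs.h_grid, ccs.phi[j], color="0.7", lw=0.6, zorder=1)
    for j in np.flatnonzero(out):
        ax.plot(ccs.h_grid, ccs.phi[j], color="crimson", lw=1.2, zorder=2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, zorder=3)
    ax.set_ylabel(r"$\phi$ (prob. population-1 ancestry)")
    ax.set_ylim(0, 1)
    if ccs.hybrid_index_by_individual.size:
        axh.hist(ccs.hybrid_index_by_individual, bins=20, range=(0, 1), color="0.4")
    axh.set_xlabel("hybrid index $h$")
    axh.set_ylabel("count")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


@dataclass
class AlphaBetaSummary:
    """2-D density over (alpha, beta) medians plus outlier hull polygons."""

    points: pd.DataFrame  # locus, alpha, beta, class labels
    density_x: np.ndarray
    density_y: np.ndarray
    density_z: np.ndarray
    hulls: dict[str, object]  # class -> shapely Polygon or None


_HULL_CLASSES = ("alpha_pos", "alpha_neg", "beta_pos", "beta_neg")


def alpha_beta_summary(
    posteriors: dict[str, PosteriorSamples],
    classifications: list[OutlierClassification],
    hull_mode: str = "convex",
    concavity: float = 0.3,
    grid: int = 100,
) -> AlphaBetaSummary:
    """Summarize loci in (alpha, beta) space with outlier hulls.

    A Gaussian KDE (Scott bandwidth) over the per-locus posterior medians
    gives the density surface; each outlier class (alpha+/-, beta+/-, by
    the sign of the final flag) gets a polygon hull enclosing its loci.
    Classes with fewer than 3 loci yield no polygon, but their points are
    still reported.
    """
    from scipy.stats import gaussian_kde
    from shapely import concave_hull
    from shapely.geometry import MultiPoint

    if hull_mode not in ("convex", "concave"):
        raise ValueError(f"unknown hull_mode {hull_mode!r}")
    if not classifications:
        raise ValueError("need at least one locus")

    df = pd.DataFrame(
        {
            "locus": [c.locus_id for c in classifications],
            "alpha": [c.alpha_median for c in classifications],
            "beta": [c.beta_median for c in classifications],
            "alpha_pos": [c.alpha_final and (c.alpha_ci.sign or c.alpha_q.sign) > 0
                          for c in classifications],
            "alpha_neg": [c.alpha_final and (c.alpha_ci.sign or c.alpha_q.sign) < 0
                          for c in classifications],
            "beta_pos": [c.beta_final and (c.beta_ci.sign or c.beta_q.sign) > 0
                         for c in classifications],
            "beta_neg": [c.beta_final and (c.beta_ci.sign or c.beta_q.sign) < 0
                         for c in classifications],
        }
    )

    pts = df[["alpha", "beta"]].to_numpy().T
    xg = np.linspace(df["alpha"].min() - 0.5, df["alpha"].max() + 0.5, grid)
    yg = np.linspace(df["beta"].min() - 0.5, df["beta"].max() + 0.5, grid)
    if df.shape[0] >= 3 and np.linalg.matrix_rank(np.cov(pts)) == 2:
        kde = gaussian_kde(pts)  # Scott's rule by default
        xx, yy = np.meshgrid(xg, yg)
        zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    else:
        zz = np.zeros((grid, grid))

    hulls: dict[str, object] = {}
    for cls in _HULL_CLASSES:
        members = df.loc[df[cls], ["alpha", "beta"]].to_numpy()
        if members.shape[0] < 3:
            hulls[cls] = None
            continue
        mp = MultiPoint([tuple(p) for p in members])
        geom = mp.convex_hull if hull_mode == "convex" else concave_hull(mp, ratio=concavity)
        hulls[cls] = geom if geom.geom_type == "Polygon" else mp.convex_hull

    return AlphaBetaSummary(points=df, density_x=xg, density_y=yg, density_z=zz, hulls=hulls)


def plot_alpha_beta(summary: AlphaBetaSummary, path: str | Path) -> Path:
    """Render the alpha-beta density contour plot with outlier hulls."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if summary.density_z.any():
        ax.contourf(
            summary.density_x, summary.density_y, summary.density_z,
            levels=12, cmap="Greys", alpha=0.8,
        )
    ax.scatter(summary.points["alpha"], summary.points["beta"], s=10, c="0.2", zorder=2)
    colors = {"alpha_pos": "crimson", "alpha_neg": "navy",
              "beta_pos": "darkorange", "beta_neg": "teal"}
    for cls, geom in summary.hulls.items():
        if geom is None:
            continue
        x, y = geom.exterior.xy
        ax.plot(x, y, color=colors[cls], lw=1.5, label=cls)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel(r"cline center $\alpha$")
    ax.set_ylabel(r"cline rate $\beta$")
    if any(g is not None for g in summary.hulls.values()):
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
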