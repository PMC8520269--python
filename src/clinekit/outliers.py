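"""Locus outlier classification from bgc cline-parameter posteriors.

Two detection rules are implemented, applied independently to the cline
center (alpha) and rate (beta) of every locus:

1. **Credible-interval rule** — a locus is an outlier when the equal-tailed
   posterior credible interval of its parameter excludes the neutral value
   0; the sign of the excess ancestry (alpha) or cline steepness (beta) is
   retained.

2. **Quantile rule** — bgc reports, per locus, the quantile of the
   parameter within its zero-mean Gaussian conditional prior (the gamma
   quantile for alpha, the zeta quantile for beta).  A locus is an outlier
   when the posterior median of that quantile falls outside the central
   interval holding mass ``n``, i.e. below ``(1 - n)/2`` or above
   ``(1 + n)/2``.

Either rule, or any combination (OR / AND), can drive the final verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from clinekit.posterior import PosteriorSamples


class OutlierFlag(str, Enum):
    OUTLIER_POS = "outlier_pos"
    OUTLIER_NEG = "outlier_neg"
    NOT_OUTLIER = "not_outlier"

    @property
    def is_outlier(self) -> bool:
        return self is not OutlierFlag.NOT_OUTLIER

    @property
    def sign(self) -> int:
        return {"outlier_pos": 1, "outlier_neg": -1, "not_outlier": 0}[self.value]


def equal_tailed_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior draws.

    Uses empirical quantiles at ``(1 - level)/2`` and ``(1 + level)/2`` with
    linear interpolation between order statistics (numpy's ``linear``
    quantile rule), so intervals nest as ``level`` grows.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 posterior samples")
    if not np.isfinite(samples).all():
        raise ValueError("posterior samples contain non-finite values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo, hi = np.quantile(samples, [(1.0 - level) / 2.0, (1.0 + level) / 2.0], method="linear")
    return float(lo), float(hi)


def hpd_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Highest-posterior-density interval (shortest interval of mass ``level``).

    Offered as a non-default alternative to the equal-tailed rule.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size < 2:
        raise ValueError("need at least 2 posterior samples")
    n_keep = max(int(np.ceil(level * x.size)), 2)
    widths = x[n_keep - 1 :] - x[: x.size - n_keep + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + n_keep - 1])


def ci_outlier_flag(
    samples: np.ndarray, level: float, interval: str = "equal_tailed"
) -> OutlierFlag:
    """Flag a locus by whether its credible interval excludes zero."""
    fn = {"equal_tailed": equal_tailed_interval, "hpd": hpd_interval}[interval]
    lo, hi = fn(samples, level)
    if lo > 0.0:
        return OutlierFlag.OUTLIER_POS
    if hi < 0.0:
        return OutlierFlag.OUTLIER_NEG
    return OutlierFlag.NOT_OUTLIER


def quantile_outlier_flag(q_median: float, n: float) -> OutlierFlag:
    """Flag a locus by its prior-quantile position.

    ``q_median`` is the posterior median of the locus's quantile within the
    zero-mean Gaussian conditional prior; ``n`` is the central prior mass
    regarded as non-outlying (e.g. 0.95).  Outlying below ``(1 - n)/2`` or
    above ``(1 + n)/2``.
    """
    if not 0.0 <= q_median <= 1.0:
        raise ValueError(f"quantile median {q_median} outside [0, 1]")
    if not 0.0 < n < 1.0:
        raise ValueError("n must be in (0, 1)")
    if q_median < (1.0 - n) / 2.0:
        return OutlierFlag.OUTLIER_NEG
    if q_median > (1.0 + n) / 2.0:
        return OutlierFlag.OUTLIER_POS
    return OutlierFlag.NOT_OUTLIER


@dataclass
class OutlierClassification:
    """Per-locus verdicts from both rules, with signs and posterior summaries."""

    locus_id: str
    alpha_ci: OutlierFlag
    beta_ci: OutlierFlag
    alpha_q: OutlierFlag
    beta_q: OutlierFlag
    alpha_interval: tuple[float, float]
    beta_interval: tuple[float, float]
    alpha_median: float
    beta_median: float
    gamma_q_median: float | None
    zeta_q_median: float | None
    alpha_final: bool
    beta_final: bool


def _combine(flags: list[OutlierFlag], combine: str) -> bool:
    states = [f.is_outlier for f in flags]
    return any(states) if combine == "any" else all(states)


def classify_outliers(
    posteriors: dict[str, PosteriorSamples],
    level: float = 0.95,
    n: float = 0.95,
    methods: tuple[str, ...] = ("ci",),
    combine: str = "any",
    locus_ids: list[str] | None = None,
    interval: str = "equal_tailed",
) -> list[OutlierClassification]:
    """Classify every locus as alpha/beta outlier or not.

    ``methods`` selects any subset of ``{"ci", "quantile"}``; the final
    per-parameter flag is the OR (``combine="any"``) or AND
    (``combine="all"``) of the selected rules.  Alpha and beta are judged
    independently; "both" is a reading of the output, never imposed.  The
    quantile rule requires the gamma/zeta quantile posteriors from bgc.
    """
    methods = tuple(methods)
    unknown = set(methods) - {"ci", "quantile"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if not methods:
        raise ValueError("at least one method required")
    if combine not in ("any", "all"):
        raise ValueError("combine must be 'any' or 'all'")
    for p in ("alpha", "beta"):
        if p not in posteriors:
            raise ValueError(f"posterior for {p!r} is required")
    alpha, beta = posteriors["alpha"], posteriors["beta"]
    if alpha.n_entities != beta.n_entities:
        raise ValueError("alpha and beta posteriors have different locus counts")

    use_quantile = "quantile" in methods
    gamma_med = zeta_med = None
    if use_quantile:
        for p in ("gamma_quantile", "zeta_quantile"):
            if p not in posteriors:
                raise ValueError(
                    "quantile method requires gamma_quantile and zeta_quantile posteriors"
                )
        gamma_med = posteriors["gamma_quantile"].medians()
        zeta_med = posteriors["zeta_quantile"].medians()
        if gamma_med.size != alpha.n_entities or zeta_med.size != alpha.n_entities:
            raise ValueError("quantile posteriors have mismatched locus counts")
    elif "gamma_quantile" in posteriors and "zeta_quantile" in posteriors:
        # keep the medians in the report even when the rule is not selected
        if posteriors["gamma_quantile"].n_entities == alpha.n_entities:
            gamma_med = posteriors["gamma_quantile"].medians()
        if posteriors["zeta_quantile"].n_entities == alpha.n_entities:
            zeta_med = posteriors["zeta_quantile"].medians()

    if locus_ids is None:
        locus_ids = [f"locus_{j}" for j in range(alpha.n_entities)]
    if len(locus_ids) != alpha.n_entities:
        raise ValueError("locus_ids length does not match posterior locus count")

    a_med = alpha.medians()
    b_med = beta.medians()

    out: list[OutlierClassification] = []
    for j, lid in enumerate(locus_ids):
        a_int = equal_tailed_interval(alpha.samples[:, j], level) \
            if interval == "equal_tailed" else hpd_interval(alpha.samples[:, j], level)
        b_int = equal_tailed_interval(beta.samples[:, j], level) \
            if interval == "equal_tailed" else hpd_interval(beta.samples[:, j], level)
        a_ci = ci_outlier_flag(alpha.samples[:, j], level, interval)
        b_ci = ci_outlier_flag(beta.samples[:, j], level, interval)
        if use_quantile:
            a_q = quantile_outlier_flag(float(gamma_med[j]), n)
            b_q = quantile_outlier_flag(float(zeta_med[j]), n)
        else:
            a_q = b_q = OutlierFlag.NOT_OUTLIER

        a_flags = [{"ci": a_ci, "quantile": a_q}[m] for m in methods]
        b_flags = [{"ci": b_ci, "quantile": b_q}[m] for m in methods]
        out.append(
            OutlierClassification(
                locus_id=lid,
                alpha_ci=a_ci,
                beta_ci=b_ci,
                alpha_q=a_q,
                beta_q=b_q,
                alpha_interval=a_int,
                beta_interval=b_int,
                alpha_median=float(a_med[j]),
                beta_median=float(b_med[j]),
                gamma_q_median=None if gamma_med is None else float(gamma_med[j]),
                zeta_q_median=None if zeta_med is None else float(zeta_med[j]),
                alpha_final=_combine(a_flags, combine),
                beta_final=_combine(b_flags, combine),
            )
        )
    return out


def outliers_to_frame(classifications: list[OutlierClassification]) -> pd.DataFrame:
    """Flatten classifications into the TSV-ready table consumed downstream."""
    rows = []
    for c in classifications:
        rows.append(
            {
                "locus": c.locus_id,
                "alpha_median": c.alpha_median,
                "beta_median": c.beta_median,
                "alpha_lo": c.alpha_interval[0],
                "alpha_hi": c.alpha_interval[1],
                "beta_lo": c.beta_interval[0],
                "beta_hi": c.beta_interval[1],
                "alpha_ci": c.alpha_ci.value,
                "beta_ci": c.beta_ci.value,
                "alpha_q": c.alpha_q.value,
                "beta_q": c.beta_q.value,
                "gamma_q_median": c.gamma_q_median,
                "zeta_q_median": c.zeta_q_median,
                "alpha_outlier": c.alpha_final,
                "beta_outlier": c.beta_final,
                "alpha_sign": (c.alpha_ci.sign or c.alpha_q.sign) if c.alpha_final else 0,
                "beta_sign": (c.beta_ci.sign or c.beta_q.sign) if c.beta_final else 0,
            }
        )
    return pd.DataFrame(rows)


def write_outliers(classifications: list[OutlierClassification], path: str | Path) -> Path:
    outliers_to_frame(classifications).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_outliers(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
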