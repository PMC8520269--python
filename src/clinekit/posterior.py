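"""Aggregation of bgc MCMC posterior output across independent replicates.

bgc writes its posterior to HDF5; the ``estpost`` extractor dumps each
parameter to comma-separated text.  Files must be named
``<prefix>_stat_<param>_<replicate>`` with an integer replicate suffix.
This module discovers those files, parses them, removes burn-in, thins, and
concatenates replicates while tracking provenance, and computes simple
per-replicate trace summaries for convergence inspection.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Parameters bgc emits under the standard model; unknown names pass through.
KNOWN_PARAMS = ("LnL", "alpha", "beta", "hi", "gamma_quantile", "zeta_quantile")

#: Parameters that must share a replicate structure for outlier detection.
_REQUIRED_MATCHED = ("alpha", "beta")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws for one bgc parameter, combined over replicates.

    ``samples`` is draws x entities, where entities are loci for
    alpha/beta/quantile parameters, admixed individuals for the hybrid
    index, and a single column for LnL.  ``replicate_of_sample`` maps each
    retained draw back to its source replicate (0-based, in file order).
    """

    param: str
    samples: np.ndarray
    replicate_of_sample: np.ndarray
    burnin_used: int
    thin_used: int
    replicate_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.replicate_of_sample = np.asarray(self.replicate_of_sample, dtype=np.int64)
        if self.samples.shape[0] != self.replicate_of_sample.shape[0]:
            raise ValueError("replicate provenance does not match draw count")

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    @property
    def n_entities(self) -> int:
        return self.samples.shape[1]

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_lengths)

    def replicate_slices(self) -> list[np.ndarray]:
        """Row indices of each replicate's retained draws, in replicate order."""
        return [
            np.flatnonzero(self.replicate_of_sample == r)
            for r in range(self.n_replicates)
        ]

    def medians(self) -> np.ndarray:
        """Posterior median per entity."""
        return np.median(self.samples, axis=0)


def retained_indices(n_draws: int, burnin: int, thin: int) -> np.ndarray:
    """0-based draw indices kept by the burn-in/thin rule.

    Keeps indices ``i >= burnin`` with ``(i - burnin) % thin == 0``; the
    retained count is ``ceil((n_draws - burnin) / thin)``.
    """
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if burnin < 0:
        raise ValueError("burnin must be >= 0")
    return np.arange(burnin, n_draws, thin)


def discover_replicates(
    directory: str | Path, prefix: str
) -> dict[str, list[Path]]:
    """Group ``<prefix>_stat_<param>_<replicate>`` files by parameter.

    Files are sorted by their integer replicate suffix.  Parameters outside
    the known bgc set are kept with a logged warning.  An unequal replicate
    count between alpha and beta is an error, since outlier detection needs
    them draw-matched.
    """
    directory = Path(directory)
    pattern = re.compile(rf"^{re.escape(prefix)}_stat_(.+)_(\d+)$")
    groups: dict[str, list[tuple[int, Path]]] = {}
    for path in sorted(directory.iterdir()):
        m = pattern.match(path.name)
        if not m:
            continue
        param, rep = m.group(1), int(m.group(2))
        if param not in KNOWN_PARAMS:
            logger.warning("unknown bgc parameter %r in %s; keeping it", param, path.name)
        groups.setdefault(param, []).append((rep, path))

    out = {
        param: [p for _, p in sorted(entries)] for param, entries in groups.items()
    }
    present = [p for p in _REQUIRED_MATCHED if p in out]
    if len(present) == 2:
        reps_a = {int(pattern.match(p.name).group(2)) for p in out["alpha"]}
        reps_b = {int(pattern.match(p.name).group(2)) for p in out["beta"]}
        if reps_a != reps_b:
            missing = sorted(reps_a ^ reps_b)
            raise ValueError(
                f"alpha and beta replicate sets differ; unmatched replicates: {missing}"
            )
    return out


def parse_estpost_file(
    path: str | Path,
    orientation: str = "entities_as_rows",
    has_header: bool = False,
) -> np.ndarray:
    """Parse one estpost CSV dump into a draws x entities float matrix.

    estpost's text output typically lists one entity (locus/individual) per
    row with draws as columns; ``orientation`` declares the layout
    explicitly rather than sniffing it, and the matrix is normalized to
    draws x entities.
    """
    if orientation not in ("entities_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if has_header and ln == 1:
                continue
            cells = line.split(",")
            try:
                values = [float(c) for c in cells]
            except ValueError as exc:
                raise ValueError(f"{path}: row {ln}: non-numeric cell: {exc}") from None
            if rows and len(values) != len(rows[0]):
                raise ValueError(
                    f"{path}: row {ln}: ragged row ({len(values)} vs {len(rows[0])} cells)"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: empty file")
    mat = np.asarray(rows, dtype=float)
    if orientation == "entities_as_rows":
        mat = mat.T
    return mat


def combine_bgc_output(
    files: list[str | Path],
    burnin: int = 0,
    thin: int = 1,
    param: str = "alpha",
    orientation: str = "entities_as_rows",
    has_header: bool = False,
) -> PosteriorSamples:
    """Parse, burn-in, thin, and concatenate one parameter's replicate files.

    Per replicate, 0-based draw indices ``i >= burnin`` with
    ``(i - burnin) % thin == 0`` are retained, then replicates are
    concatenated in file order with provenance recorded.
    """
    if not files:
        raise ValueError("no replicate files given")
    blocks: list[np.ndarray] = []
    provenance: list[np.ndarray] = []
    lengths: list[int] = []
    n_entities = None
    for r, path in enumerate(files):
        mat = parse_estpost_file(path, orientation=orientation, has_header=has_header)
        if n_entities is None:
            n_entities = mat.shape[1]
        elif mat.shape[1] != n_entities:
            raise ValueError(
                f"{path}: entity count {mat.shape[1]} != {n_entities} of first replicate"
            )
        lengths.append(mat.shape[0])
        if burnin >= mat.shape[0]:
            raise ValueError(
                f"burnin {burnin} >= draw count {mat.shape[0]} in replicate file {path}"
            )
        keep = retained_indices(mat.shape[0], burnin, thin)
        blocks.append(mat[keep])
        provenance.append(np.full(keep.shape[0], r, dtype=np.int64))
    return PosteriorSamples(
        param=param,
        samples=np.vstack(blocks),
        replicate_of_sample=np.concatenate(provenance),
        burnin_used=burnin,
        thin_used=thin,
        replicate_lengths=lengths,
    )


def combine_all(
    directory: str | Path,
    prefix: str,
    burnin: int = 0,
    thin: int = 1,
    orientation: str = "entities_as_rows",
    has_header: bool = False,
) -> dict[str, PosteriorSamples]:
    """Discover and combine every parameter found under ``directory``."""
    groups = discover_replicates(directory, prefix)
    if not groups:
        raise ValueError(f"no '{prefix}_stat_<param>_<replicate>' files in {directory}")
    return {
        param: combine_bgc_output(
            files, burnin=burnin, thin=thin, param=param,
            orientation=orientation, has_header=has_header,
        )
        for param, files in groups.items()
    }


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    v = x.var()
    if v == 0.0:
        return 0.0  # constant trace: pinned to 0 rather than NaN
    d = x - x.mean()
    return float((d[:-1] * d[1:]).mean() / v)


def trace_stats(ps: PosteriorSamples) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Per-replicate trace arrays plus a mean/variance/lag-1 summary table.

    Returns the plot-ready per-replicate draw series (draws x entities) and
    a DataFrame with one row per (replicate, entity): mean, variance and
    lag-1 autocorrelation of the retained draws.
    """
    traces = [ps.samples[idx] for idx in ps.replicate_slices()]
    rows = []
    for r, block in enumerate(traces):
        if block.shape[0] == 0:
            raise ValueError(f"replicate {r} has no retained draws")
        for e in range(ps.n_entities):
            x = block[:, e]
            rows.append(
                {
                    "replicate": r,
                    "entity": e,
                    "mean": float(x.mean()),
                    "variance": float(x.var()),
                    "lag1_autocorr": _lag1_autocorr(x),
                }
            )
    return traces, pd.DataFrame(rows)


def plot_traces(ps: PosteriorSamples, path: str | Path, entity: int = 0) -> Path:
    """Render one entity's trace per replicate to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traces, _ = trace_stats(ps)
    fig, ax = plt.subplots(figsize=(8, 3.5))
    for r, block in enumerate(traces):
        ax.plot(np.arange(block.shape[0]), block[:, entity], lw=0.7, label=f"replicate {r}")
    ax.set_xlabel("retained draw index")
    ax.set_ylabel(ps.param)
    ax.set_title(f"{ps.param} trace (entity {entity})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def write_posterior(
    posteriors: dict[str, PosteriorSamples], outdir: str | Path
) -> dict[str, Path]:
    """Write combined posteriors as one TSV per parameter + a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    meta: dict[str, dict] = {}
    for param, ps in posteriors.items():
        path = outdir / f"posterior_{param}.tsv"
        df = pd.DataFrame(
            ps.samples, columns=[f"entity_{e}" for e in range(ps.n_entities)]
        )
        df.insert(0, "replicate", ps.replicate_of_sample)
        df.to_csv(path, sep="\t", index=False)
        paths[param] = path
        meta[param] = {
            "burnin": ps.burnin_used,
            "thin": ps.thin_used,
            "replicate_lengths": ps.replicate_lengths,
            "retained_draws": ps.n_draws,
        }
    sidecar = outdir / "posterior_provenance.json"
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    paths["provenance"] = sidecar
    return paths


def read_posterior(outdir: str | Path) -> dict[str, PosteriorSamples]:
    """Read back the TSV-per-parameter archive written by :func:`write_posterior`."""
    outdir = Path(outdir)
    sidecar = outdir / "posterior_provenance.json"
    meta = json.loads(sidecar.read_text())
    out: dict[str, PosteriorSamples] = {}
    for param, info in meta.items():
        df = pd.read_csv(outdir / f"posterior_{param}.tsv", sep="\t")
        rep = df.pop("replicate").to_numpy()
        out[param] = PosteriorSamples(
            param=param,
            samples=df.to_numpy(dtype=float),
            replicate_of_sample=rep,
            burnin_used=info["burnin"],
            thin_used=info["thin"],
            replicate_lengths=info["replicate_lengths"],
        )
    return out
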