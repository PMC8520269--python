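"""Chromosome placement of outlier SNPs and ideogram band tables.

SNPs from a scaffold-level assembly are lifted to chromosome coordinates
through a scaffold->chromosome mapping table (a Minimap2 PAF, or a
simplified PAFScaff-style TSV), joined against GFF3 gene annotations, and
turned into per-SNP heatmap bands for a karyotype ideogram — larger bands
for SNPs inside known genes, smaller for SNPs on surrounding scaffolds.

Coordinate conventions: GFF3 intervals are 1-based inclusive; PAF target
coordinates are 0-based half-open; everything internal is 1-based
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

UNPLACED = "UNPLACED"


@dataclass(frozen=True)
class GeneInterval:
    """One gene feature: 1-based inclusive interval on a sequence."""

    seqid: str
    start: int
    end: int
    strand: str
    gene_id: str


@dataclass(frozen=True)
class ScaffoldMapping:
    """Best placement of one scaffold on a chromosome (1-based start)."""

    scaffold: str
    scaffold_len: int
    chromosome: str
    chrom_start: int
    orientation: str
    mapping_quality: int
    block_len: int = 0

    def __post_init__(self) -> None:
        if self.chrom_start < 1 or self.scaffold_len < 1:
            raise ValueError("chrom_start and scaffold_len must be >= 1")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")


@dataclass
class AnnotatedSNP:
    """A locus with scaffold coordinate, lifted position and gene overlap."""

    locus_id: str
    scaffold: str
    scaffold_pos: int
    chromosome: str = UNPLACED
    chrom_pos: int | None = None
    in_gene: bool = False
    gene_id: str | None = None
    alpha_value: float = 0.0
    beta_value: float = 0.0


def parse_gff(path: str | Path, feature_type: str = "gene") -> list[GeneInterval]:
    """Extract gene intervals from a GFF3 file.

    Keeps rows whose type column equals ``feature_type`` and reads the
    ``ID`` (or ``Name``) attribute as the gene id; rows with an
    unparseable attribute column are skipped with a warning.
    """
    genes: list[GeneInterval] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            logger.warning("%s: line %d: expected 9 columns, skipping", path, ln)
            continue
        if cols[2] != feature_type:
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            logger.warning("%s: line %d: bad coordinates, skipping", path, ln)
            continue
        attrs = {}
        try:
            for item in cols[8].strip(";").split(";"):
                if not item:
                    continue
                key, value = item.split("=", 1)
                attrs[key.strip()] = value.strip()
        except ValueError:
            logger.warning("%s: line %d: unparseable attributes, skipping", path, ln)
            continue
        gene_id = attrs.get("ID") or attrs.get("Name")
        if gene_id is None:
            logger.warning("%s: line %d: feature lacks ID/Name, skipping", path, ln)
            continue
        genes.append(GeneInterval(cols[0], start, end, cols[6], gene_id))
    if not genes:
        logger.warning("%s: no %r features found", path, feature_type)
    return genes


def parse_scaffold_map(path: str | Path, dialect: str = "paf") -> list[ScaffoldMapping]:
    """Read a scaffold->chromosome mapping, keeping the best hit per scaffold.

    ``paf``: standard Minimap2 PAF (query = scaffold, target = chromosome;
    target start is 0-based half-open and shifted to 1-based here).
    ``pafscaff_tsv``: header-bearing TSV with columns scaffold,
    scaffold_len, chromosome, chrom_start (1-based), orientation,
    mapping_quality.  Best hit = highest mapping quality, ties broken by
    the longest alignment block.
    """
    candidates: dict[str, list[ScaffoldMapping]] = {}
    if dialect == "paf":
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}: line {ln}: PAF needs >= 12 columns")
            m = ScaffoldMapping(
                scaffold=cols[0],
                scaffold_len=int(cols[1]),
                chromosome=cols[5],
                chrom_start=int(cols[7]) + 1,  # 0-based half-open -> 1-based
                orientation=cols[4],
                mapping_quality=int(cols[11]),
                block_len=int(cols[10]),
            )
            candidates.setdefault(m.scaffold, []).append(m)
    elif dialect == "pafscaff_tsv":
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            m = ScaffoldMapping(
                scaffold=str(row["scaffold"]),
                scaffold_len=int(row["scaffold_len"]),
                chromosome=str(row["chromosome"]),
                chrom_start=int(row["chrom_start"]),
                orientation=str(row["orientation"]),
                mapping_quality=int(row["mapping_quality"]),
                block_len=int(row.get("block_len", 0)),
            )
            candidates.setdefault(m.scaffold, []).append(m)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    best: list[ScaffoldMapping] = []
    for scaffold in sorted(candidates):
        hits = candidates[scaffold]
        hits.sort(key=lambda m: (-m.mapping_quality, -m.block_len, m.chromosome))
        best.append(hits[0])
    return best


def lift_coordinates(
    scaffold: str, scaffold_pos: int, mapping: ScaffoldMapping
) -> tuple[str, int]:
    """Lift a 1-based scaffold position to its chromosome coordinate.

    Forward scaffolds: ``chrom_start + pos - 1``.  Reverse scaffolds:
    ``chrom_start + (scaffold_len - pos)``, so the scaffold's last base
    lands on ``chrom_start``.
    """
    if mapping.scaffold != scaffold:
        raise ValueError(f"mapping is for {mapping.scaffold!r}, not {scaffold!r}")
    if not 1 <= scaffold_pos <= mapping.scaffold_len:
        raise ValueError(
            f"scaffold_pos {scaffold_pos} outside [1, {mapping.scaffold_len}] "
            f"for scaffold {scaffold!r}"
        )
    if mapping.orientation == "+":
        return mapping.chromosome, mapping.chrom_start + scaffold_pos - 1
    return mapping.chromosome, mapping.chrom_start + (mapping.scaffold_len - scaffold_pos)


def invert_lift(chrom_pos: int, mapping: ScaffoldMapping) -> int:
    """Recover the scaffold position from a lifted chromosome position."""
    if mapping.orientation == "+":
        pos = chrom_pos - mapping.chrom_start + 1
    else:
        pos = mapping.scaffold_len - (chrom_pos - mapping.chrom_start)
    if not 1 <= pos <= mapping.scaffold_len:
        raise ValueError(f"chrom_pos {chrom_pos} does not fall on scaffold {mapping.scaffold!r}")
    return pos


def lift_snps(
    snps: list[AnnotatedSNP], mappings: list[ScaffoldMapping]
) -> list[AnnotatedSNP]:
    """Lift every SNP with a mapped scaffold; others stay UNPLACED."""
    by_scaffold = {m.scaffold: m for m in mappings}
    for snp in snps:
        m = by_scaffold.get(snp.scaffold)
        if m is None:
            snp.chromosome, snp.chrom_pos = UNPLACED, None
            continue
        snp.chromosome, snp.chrom_pos = lift_coordinates(snp.scaffold, snp.scaffold_pos, m)
    return snps


def join_outliers_to_genes(
    snps: list[AnnotatedSNP], genes: list[GeneInterval]
) -> list[AnnotatedSNP]:
    """Mark each placed SNP that falls inside a gene (inclusive bounds).

    When several genes overlap a SNP, the gene with the lowest start
    coordinate wins — an arbitrary but deterministic tie-break.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.seqid, IntervalTree()).addi(g.start, g.end + 1, g)
    for snp in snps:
        snp.in_gene, snp.gene_id = False, None
        if snp.chromosome == UNPLACED or snp.chrom_pos is None:
            continue
        tree = trees.get(snp.chromosome)
        if tree is None:
            continue
        hits = sorted(tree[snp.chrom_pos], key=lambda iv: (iv.begin, iv.data.gene_id))
        if hits:
            snp.in_gene = True
            snp.gene_id = hits[0].data.gene_id
    return snps


def ideogram_bands(
    annotated: list[AnnotatedSNP],
    karyotype: dict[str, int],
    param: str = "alpha",
    gene_band_bp: int = 2_000_000,
    nongene_band_bp: int = 500_000,
) -> pd.DataFrame:
    """Build the per-SNP heatmap band table for one cline parameter.

    Each placed SNP becomes a band centered on its chromosome position:
    width ``gene_band_bp`` for SNPs inside genes, ``nongene_band_bp``
    otherwise, clipped to [1, chromosome length]; the band value is the
    SNP's alpha or beta.  Unplaced SNPs are excluded; a placed SNP on a
    chromosome missing from the karyotype is an error.
    """
    if param not in ("alpha", "beta"):
        raise ValueError("param must be 'alpha' or 'beta'")
    if not gene_band_bp > nongene_band_bp > 0:
        raise ValueError("need gene_band_bp > nongene_band_bp > 0")
    rows = []
    for snp in annotated:
        if snp.chromosome == UNPLACED or snp.chrom_pos is None:
            continue
        if snp.chromosome not in karyotype:
            raise ValueError(
                f"SNP {snp.locus_id!r}: chromosome {snp.chromosome!r} absent from karyotype"
            )
        chrom_len = karyotype[snp.chromosome]
        width = gene_band_bp if snp.in_gene else nongene_band_bp
        start = max(1, snp.chrom_pos - width // 2)
        end = min(chrom_len, snp.chrom_pos + width // 2)
        rows.append(
            {
                "chromosome": snp.chromosome,
                "band_start": start,
                "band_end": end,
                "value": snp.alpha_value if param == "alpha" else snp.beta_value,
                "locus": snp.locus_id,
                "in_gene": snp.in_gene,
            }
        )
    return pd.DataFrame(
        rows, columns=["chromosome", "band_start", "band_end", "value", "locus", "in_gene"]
    )


def read_karyotype(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (chromosome, length) karyotype table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "length"], comment="#")
    return dict(zip(df["chromosome"].astype(str), df["length"].astype(int)))


def plot_ideogram(
    alpha_bands: pd.DataFrame,
    beta_bands: pd.DataFrame,
    karyotype: dict[str, int],
    path: str | Path,
) -> Path:
    """Render the dual-heatmap karyotype: alpha bands left, beta right."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colormaps
    from matplotlib.colors import Normalize
    from matplotlib.patches import Rectangle

    chroms = sorted(karyotype)
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(chroms)), 6))
    max_len = max(karyotype.values())
    values = pd.concat([alpha_bands["value"], beta_bands["value"]]) if len(alpha_bands) + len(beta_bands) else pd.Series([0.0])
    vmax = max(abs(values.min()), abs(values.max())) or 1.0
    norm = Normalize(vmin=-vmax, vmax=vmax)
    cmap = colormaps["coolwarm"]

    for ci, chrom in enumerate(chroms):
        length = karyotype[chrom]
        for dx, bands in ((0.0, alpha_bands), (0.45, beta_bands)):
            x = ci + dx
            ax.add_patch(
                Rectangle((x, 0), 0.35, length / max_len, fill=False, lw=0.8)
            )
            sub = bands[bands["chromosome"] == chrom]
            for _, b in sub.iterrows():
                y0 = b["band_start"] / max_len
                y1 = max(b["band_end"] / max_len, y0 + 0.003)
                ax.add_patch(
                    Rectangle((x, y0), 0.35, y1 - y0, color=cmap(norm(b["value"])), lw=0)
                )
    ax.set_xticks([c + 0.4 for c in range(len(chroms))])
    ax.set_xticklabels(chroms, rotation=90, fontsize=7)
    ax.set_xlim(-0.5, len(chroms))
    ax.set_ylim(0, 1.05)
    ax.set_yticks([])
    ax.set_title(r"$\alpha$ (left) / $\beta$ (right) outlier bands")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
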