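"""Readers and writers for SNP datasets and the bgc / Introgress dialects.

VCF input goes through cyvcf2; PHYLIP concatenated-SNP alignments are decoded
from IUPAC ambiguity codes.  The bgc three-file dialect (parental0,
parental1, admixed) and Introgress four-file dialect are pinned here by a
writer/reader pair, since neither program documents a formal grammar.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from clinekit.matrix import (
    MISSING,
    POP_P0,
    POP_P1,
    GenotypeMatrix,
    ReadCountMatrix,
)

logger = logging.getLogger(__name__)

# Two-base IUPAC ambiguity codes -> unordered allele pair (heterozygote).
_IUPAC_HET = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
_IUPAC_MISSING = set("N-?")
# Three/four-base ambiguities cannot be represented under a biallelic model.
_IUPAC_MULTI = set("BDHV")


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column whitespace popmap (sample, population label)."""
    popmap: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: line {ln}: expected 'sample population'")
        sample, pop = parts
        if sample in popmap:
            raise ValueError(f"{path}: duplicate sample {sample!r} at line {ln}")
        popmap[sample] = pop
    if not popmap:
        raise ValueError(f"{path}: empty popmap")
    return popmap


def read_vcf(
    path: str | Path, popmap: str | Path | dict[str, str]
) -> tuple[GenotypeMatrix, ReadCountMatrix | None]:
    """Read a VCF into a :class:`GenotypeMatrix` (+ read counts when AD present).

    Genotypes are coded as the count of the first ALT allele; calls carrying
    a second or later ALT allele cannot be represented under a biallelic
    coding and become ``MISSING`` (such loci are flagged non-biallelic via
    ``allele_count`` and are normally removed by filtering).  Physical
    coordinates (CHROM, POS) are kept as locus metadata.
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in popmap]
    if missing_samples:
        raise ValueError(
            f"samples missing from popmap: {', '.join(missing_samples)}"
        )
    pop_labels = [popmap[s] for s in samples]

    locus_ids: list[str] = []
    alleles: list[tuple[str, str]] = []
    allele_count: list[int] = []
    positions: list[tuple[str, int]] = []
    geno_rows: list[np.ndarray] = []
    count_rows: list[np.ndarray] = []
    any_ad = False
    seen_ids: set[str] = set()

    for var in vcf:
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if lid in seen_ids:  # ddRAD catalogs can repeat IDs; disambiguate
            lid = f"{lid}:{len(locus_ids)}"
        seen_ids.add(lid)
        alt = var.ALT[0] if var.ALT else "."
        gts = np.full(len(samples), MISSING, dtype=np.int16)
        observed: set[int] = set()
        for i, call in enumerate(var.genotypes):
            pair = [a for a in call[:2] if a is not None and a >= 0]
            if len(pair) != 2:
                continue
            observed.update(pair)
            if any(a >= 2 for a in pair):
                continue  # third allele: unrepresentable, leave MISSING
            gts[i] = sum(1 for a in pair if a == 1)
        # distinct alleles observed in calls; fall back to declared REF/ALT
        nall = len(observed) if observed else 1 + len([a for a in var.ALT if a != "."])
        locus_ids.append(lid)
        alleles.append((var.REF, alt))
        allele_count.append(nall)
        positions.append((var.CHROM, var.POS))
        geno_rows.append(gts)

        ad = var.format("AD")
        if ad is not None:
            any_ad = True
            ad = np.asarray(ad)
            pair_counts = np.full((len(samples), 2), MISSING, dtype=np.int64)
            if ad.ndim == 2 and ad.shape[1] >= 2:
                ok = (ad[:, 0] >= 0) & (ad[:, 1] >= 0)
                pair_counts[ok, 0] = ad[ok, 0]
                pair_counts[ok, 1] = ad[ok, 1]
            count_rows.append(pair_counts)
        else:
            count_rows.append(np.full((len(samples), 2), MISSING, dtype=np.int64))

    if not locus_ids:
        raise ValueError(f"{path}: VCF contains no variant records")

    gm = GenotypeMatrix(
        sample_ids=samples,
        pop_labels=pop_labels,
        locus_ids=locus_ids,
        alleles=alleles,
        genotypes=np.column_stack(geno_rows),
        allele_count=np.asarray(allele_count),
        positions=positions,
    )
    rc = None
    if any_ad:
        rc = ReadCountMatrix(
            sample_ids=samples,
            locus_ids=locus_ids,
            counts=np.stack(count_rows, axis=1),
        )
    return gm, rc


def read_phylip(path: str | Path, popmap: str | Path | dict[str, str]) -> GenotypeMatrix:
    """Read a PHYLIP concatenated-SNP alignment (relaxed names).

    Heterozygotes are decoded from two-base IUPAC ambiguity codes; ``N``,
    ``-`` and ``?`` become MISSING; three/four-base ambiguity codes (B, D,
    H, V) are treated as MISSING with a logged warning.  Per-locus allele
    order follows first observation in file order, so exports from PHYLIP
    are reproducible but allele polarity is not anchored to a reference.
    """
    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError(f"{path}: malformed dimension line {lines[0]!r}")
    n_samples, n_loci = int(header[0]), int(header[1])
    body = lines[1:]
    if len(body) != n_samples:
        raise ValueError(
            f"{path}: dimension line declares {n_samples} sequences, found {len(body)}"
        )

    names: list[str] = []
    seqs: list[str] = []
    for ln, line in enumerate(body, start=2):
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}: line {ln}: expected 'name sequence'")
        name, seq = parts[0], parts[1].replace(" ", "").upper()
        if len(seq) != n_loci:
            raise ValueError(
                f"{path}: line {ln}: sequence length {len(seq)} != declared {n_loci}"
            )
        names.append(name)
        seqs.append(seq)

    missing_samples = [s for s in names if s not in popmap]
    if missing_samples:
        raise ValueError(f"samples missing from popmap: {', '.join(missing_samples)}")

    geno = np.full((n_samples, n_loci), MISSING, dtype=np.int16)
    alleles: list[tuple[str, str]] = []
    allele_count = np.zeros(n_loci, dtype=np.int64)
    warned_multi = False

    for j in range(n_loci):
        order: list[str] = []  # alleles by first observation
        calls: list[frozenset[str] | None] = []
        for i in range(n_samples):
            base = seqs[i][j]
            if base in _IUPAC_MISSING:
                calls.append(None)
            elif base in _IUPAC_MULTI:
                if not warned_multi:
                    logger.warning(
                        "%s: 3/4-base IUPAC ambiguity codes treated as missing", path
                    )
                    warned_multi = True
                calls.append(None)
            elif base in _IUPAC_HET:
                pair = _IUPAC_HET[base]
                calls.append(pair)
                for a in sorted(pair):
                    if a not in order:
                        order.append(a)
            elif base in "ACGT":
                calls.append(frozenset((base,)))
                if base not in order:
                    order.append(base)
            else:
                raise ValueError(f"{path}: unknown base {base!r} at locus {j}")
        allele_count[j] = max(len(order), 1)
        a1 = order[0] if order else "N"
        a2 = order[1] if len(order) > 1 else a1
        alleles.append((a1, a2))
        for i, call in enumerate(calls):
            if call is None:
                continue
            if not call <= {a1, a2}:
                continue  # involves a 3rd allele; unrepresentable -> MISSING
            if len(call) == 2:
                geno[i, j] = 1
            else:
                (b,) = call
                geno[i, j] = 0 if b == a1 else 2

    return GenotypeMatrix(
        sample_ids=names,
        pop_labels=[popmap[s] for s in names],
        locus_ids=[f"locus_{j}" for j in range(n_loci)],
        alleles=alleles,
        genotypes=geno,
        allele_count=allele_count,
    )


# ---------------------------------------------------------------------------
# bgc dialect
# ---------------------------------------------------------------------------

def _bgc_genotype_line(g: int) -> str:
    if g == MISSING:
        return "-9 -9"
    return f"{2 - g} {g}"


def write_bgc_input(
    gm: GenotypeMatrix,
    rc: ReadCountMatrix | None,
    outdir: str | Path,
    mode: str = "genotype",
) -> tuple[Path, Path, Path]:
    """Write the bgc three-file input dialect (parental0, parental1, admixed).

    Parental files carry a ``locus_<i>`` header per locus followed by one
    two-integer line per parental individual (genotype mode: copies of
    allele 1 and allele 2; readcount mode: read depths).  The admixed file
    nests a ``pop_<j>`` header per admixed population under each locus
    header.  Missing data is ``-9 -9``; locus order is identical across the
    three files.
    """
    if mode not in ("genotype", "readcount"):
        raise ValueError(f"unknown mode {mode!r}")
    gm.require_export_populations()
    if mode == "readcount":
        if rc is None:
            raise ValueError("readcount mode requires a ReadCountMatrix")
        if rc.locus_ids != gm.locus_ids or rc.sample_ids != gm.sample_ids:
            raise ValueError("ReadCountMatrix does not match GenotypeMatrix")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p0_idx = gm.sample_indices(POP_P0)
    p1_idx = gm.sample_indices(POP_P1)
    admix_pops = gm.admixed_labels

    def _line(i: int, j: int) -> str:
        if mode == "genotype":
            return _bgc_genotype_line(int(gm.genotypes[i, j]))
        c1, c2 = rc.counts[i, j]
        if c1 == MISSING or c2 == MISSING:
            return "-9 -9"
        return f"{c1} {c2}"

    paths = (outdir / "bgc_p0.txt", outdir / "bgc_p1.txt", outdir / "bgc_admixed.txt")
    for path, idx in zip(paths[:2], (p0_idx, p1_idx)):
        with open(path, "w") as fh:
            for j in range(gm.n_loci):
                fh.write(f"locus_{j}\n")
                for i in idx:
                    fh.write(_line(i, j) + "\n")
    with open(paths[2], "w") as fh:
        for j in range(gm.n_loci):
            fh.write(f"locus_{j}\n")
            for k, pop in enumerate(admix_pops):
                fh.write(f"pop_{k}\n")
                for i in gm.sample_indices(pop):
                    fh.write(_line(i, j) + "\n")
    return paths


def read_bgc_input(
    parental0: str | Path, parental1: str | Path, admixed: str | Path
) -> GenotypeMatrix:
    """Read the bgc genotype-mode dialect back into a :class:`GenotypeMatrix`.

    The inverse of :func:`write_bgc_input` up to sample names, which are
    synthesized positionally; allele symbols are not carried by the format
    and default to the pair ``("1", "2")``.
    """

    def _parse_parental(path: Path) -> list[list[int]]:
        loci: list[list[int]] = []
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("locus_"):
                loci.append([])
                continue
            if not loci:
                raise ValueError(f"{path}: line {ln}: data before first locus header")
            loci[-1].append(_parse_two_int(line, path, ln))
        return loci

    def _parse_two_int(line: str, path, ln: int) -> int:
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: line {ln}: expected two integers")
        c1, c2 = int(parts[0]), int(parts[1])
        if c1 == -9 and c2 == -9:
            return MISSING
        if c1 + c2 != 2 or c1 < 0 or c2 < 0:
            raise ValueError(f"{path}: line {ln}: not a diploid genotype line: {line!r}")
        return c2

    p0 = _parse_parental(Path(parental0))
    p1 = _parse_parental(Path(parental1))

    # admixed file: locus_<i> / pop_<j> / genotype lines
    admix: list[dict[int, list[int]]] = []
    cur_pop: int | None = None
    for ln, raw in enumerate(Path(admixed).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("locus_"):
            admix.append({})
            cur_pop = None
            continue
        if line.startswith("pop_"):
            if not admix:
                raise ValueError(f"{admixed}: line {ln}: pop header before locus header")
            cur_pop = int(line[4:])
            admix[-1][cur_pop] = []
            continue
        if not admix or cur_pop is None:
            raise ValueError(f"{admixed}: line {ln}: data before headers")
        admix[-1][cur_pop].append(_parse_two_int(line, admixed, ln))

    n_loci = len(p0)
    if len(p1) != n_loci or len(admix) != n_loci:
        raise ValueError(
            f"locus counts disagree: p0={len(p0)} p1={len(p1)} admixed={len(admix)}"
        )
    if n_loci == 0:
        raise ValueError("no loci found")
    if any(not d for d in admix):
        raise ValueError("empty admixed section for at least one locus")

    pops = sorted(admix[0].keys())
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    columns: list[list[int]] = []
    n_p0, n_p1 = len(p0[0]), len(p1[0])
    sample_ids += [f"p0_{i}" for i in range(n_p0)]
    pop_labels += [POP_P0] * n_p0
    sample_ids += [f"p1_{i}" for i in range(n_p1)]
    pop_labels += [POP_P1] * n_p1
    for k in pops:
        n_k = len(admix[0][k])
        sample_ids += [f"admixed{k}_{i}" for i in range(n_k)]
        pop_labels += [f"ADMIXED{k}"] * n_k

    for j in range(n_loci):
        col = list(p0[j]) + list(p1[j])
        for k in pops:
            col += list(admix[j][k])
        if len(col) != len(sample_ids):
            raise ValueError(f"locus {j}: inconsistent individual count")
        columns.append(col)

    geno = np.asarray(columns, dtype=np.int16).T
    return GenotypeMatrix(
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        locus_ids=[f"locus_{j}" for j in range(n_loci)],
        alleles=[("1", "2")] * n_loci,
        genotypes=geno,
        allele_count=np.full(n_loci, 2, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Introgress dialect
# ---------------------------------------------------------------------------

def write_introgress_input(gm: GenotypeMatrix, outdir: str | Path) -> tuple[Path, Path, Path, Path]:
    """Write the Introgress four-file dialect (admix, parental1, parental2, loci).

    Genotype tables are loci-as-rows, individuals-as-columns, with
    slash-separated allele pairs (``A/C``) and ``NA/NA`` for missing.  The
    loci table lists the locus id with type code ``C`` (codominant).
    """
    gm.require_export_populations()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _cell(i: int, j: int) -> str:
        g = int(gm.genotypes[i, j])
        a1, a2 = gm.alleles[j]
        if g == MISSING:
            return "NA/NA"
        return {0: f"{a1}/{a1}", 1: f"{a1}/{a2}", 2: f"{a2}/{a2}"}[g]

    groups = {
        "introgress_admix.txt": [
            i for lab in gm.admixed_labels for i in gm.sample_indices(lab)
        ],
        "introgress_parental1.txt": list(gm.sample_indices(POP_P0)),
        "introgress_parental2.txt": list(gm.sample_indices(POP_P1)),
    }
    paths = []
    for fname, idx in groups.items():
        path = outdir / fname
        with open(path, "w") as fh:
            fh.write("\t".join(gm.sample_ids[i] for i in idx) + "\n")
            for j in range(gm.n_loci):
                fh.write("\t".join(_cell(i, j) for i in idx) + "\n")
        paths.append(path)

    loci_path = outdir / "introgress_loci.txt"
    with open(loci_path, "w") as fh:
        fh.write("locus\ttype\n")
        for lid in gm.locus_ids:
            fh.write(f"{lid}\tC\n")
    paths.append(loci_path)
    return tuple(paths)
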