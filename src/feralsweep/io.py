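"""Readers and writers for the formats the pipeline touches.

VCF v4.x (plain or bgzipped) is read through cyvcf2; the simulator emits plain
VCF through :func:`write_vcf` so round trips are lossless.  Population maps are
``sample<TAB>breed[<TAB>group]`` TSV; gene annotation is BED (0-based
half-open) or GFF3 (1-based closed, gene features only).  All result tables
leave the package as TSV with deterministic column order.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    MISSING,
    GeneAnnotation,
    GeneRecord,
    PopulationMap,
    VariantTable,
)

logger = logging.getLogger(__name__)

_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path, min_maf: float | None = None, biallelic_only: bool = True) -> VariantTable:
    """Load a VCF into a :class:`VariantTable` of alt-allele dosages.

    Multi-allelic and non-SNP records are dropped when ``biallelic_only``;
    half-called and uncalled genotypes become missing; ``min_maf`` filters on
    the minor-allele frequency over all non-missing alleles in the cohort.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples (empty cohort)")

    chroms, poss, refs, alts, rows = [], [], [], [], []
    for rec in vcf:
        if biallelic_only:
            if len(rec.ALT) != 1:
                continue
            if rec.REF not in _SNP_ALLELES or rec.ALT[0] not in _SNP_ALLELES:
                continue
        elif not rec.ALT:
            continue
        # build dosages from the raw allele calls so half calls ("./1")
        # become missing rather than cyvcf2's het interpretation
        dosage = np.full(len(samples), MISSING, dtype=np.int8)
        for k, call in enumerate(rec.genotypes):
            alleles = call[:-1]  # last element is the phase flag
            if any(a < 0 for a in alleles):
                continue
            dosage[k] = sum(1 for a in alleles if a > 0)
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)  # to 0-based
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        rows.append(dosage)

    dosages = (
        np.array(rows, dtype=np.int8)
        if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    vt = VariantTable(
        np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object), np.array(alts, dtype=object),
        dosages, samples,
    )
    if min_maf is not None and vt.n_sites:
        vt = filter_maf(vt, min_maf)
    return vt


def filter_maf(vt: VariantTable, min_maf: float) -> VariantTable:
    """Drop sites whose cohort-wide minor-allele frequency is below ``min_maf``."""
    d = vt.dosages
    called = d != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt_count = np.where(called, d, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        f = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(f, 1.0 - f)
    keep = np.where(np.isnan(maf), False, maf >= min_maf)
    return vt.take_sites(np.flatnonzero(keep))


def write_vcf(vt: VariantTable, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in vt.chrom_lengths().items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(vt.samples) + "\n")
        for i in range(vt.n_sites):
            gts = "\t".join(code[int(g)] for g in vt.dosages[i])
            fh.write(
                f"{vt.chrom[i]}\t{vt.pos[i] + 1}\t.\t{vt.ref[i]}\t{vt.alt[i]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_population_map(path) -> PopulationMap:
    """Read a ``sample<TAB>breed[<TAB>group]`` TSV ('#' lines are comments)."""
    sample_to_breed: dict[str, str] = {}
    breed_to_group: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            sample, breed = parts[0], parts[1]
            if sample in sample_to_breed:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sample!r}")
            sample_to_breed[sample] = breed
            if len(parts) >= 3 and parts[2]:
                prev = breed_to_group.get(breed)
                if prev is not None and prev != parts[2]:
                    raise ValueError(
                        f"{path}:{lineno}: breed {breed!r} assigned to two groups"
                    )
                breed_to_group[breed] = parts[2]
    return PopulationMap(sample_to_breed, breed_to_group)


def read_gene_annotation(path, fmt: str | None = None) -> GeneAnnotation:
    """Read gene records from BED or GFF3 into 0-based half-open coordinates.

    ``fmt`` is ``"bed"`` or ``"gff3"``; when omitted it is sniffed from the
    file extension.  GFF3 parsing keeps gene-type features only.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "gff3" if ext in {".gff", ".gff3"} else "bed"
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if fmt == "bed":
                chrom, start, end = f[0], int(f[1]), int(f[2])
                gene_id = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
                strand = f[5] if len(f) > 5 else "."
            else:
                if len(f) < 8:
                    raise ValueError(f"{path}:{lineno}: malformed GFF3 record")
                if f[2].lower() != "gene":
                    continue
                chrom, strand = f[0], f[6]
                start, end = int(f[3]) - 1, int(f[4])  # 1-based closed -> half-open
                gene_id = _gff3_id(f[8] if len(f) > 8 else "", f"{chrom}:{start}")
            try:
                genes.append(GeneRecord(gene_id, chrom, start, end, strand))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from e
    return GeneAnnotation(genes)


def _gff3_id(attributes: str, fallback: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attributes.split(";") if "=" in kv
    )
    return fields.get("ID", fields.get("Name", fallback))


def write_table(records, path) -> None:
    """Write any result table as TSV: header row, deterministic column order,
    byte-identical for identical input."""
    if records is None:
        raise ValueError("records must not be None")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], comment="#")


def write_gene_bed(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for g in ann:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
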