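"""Minimal VCF import/export for microhaplotype call sets.

Only the GT and AD fields are used; one VCF record per microhaplotype
locus, with the locus's haplotype strings as REF/ALT alleles.  Written
files are plain uncompressed text; reading goes through cyvcf2 and
accepts multiallelic, unphased records.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .genotypes import MISSING, DepthTable, GenotypeTable


def write_vcf(table: GenotypeTable, path, depths: DepthTable | None = None) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={locus}>" for locus in table.loci],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.individuals),
    ]
    fmt = "GT:AD" if depths is not None else "GT"
    for j, locus in enumerate(table.loci):
        alleles = table.alleles[locus]
        ref, alts = alleles[0], alleles[1:]
        fields = [locus, str(j + 1), locus, ref, ",".join(alts) or ".", ".", "PASS", ".", fmt]
        for i in range(table.n_individuals):
            a, b = table.codes[i, j]
            gt = "./." if a == MISSING else f"{a}/{b}"
            if depths is not None:
                ad = ",".join(
                    str(int(depths.counts[i, j, k])) for k in range(len(alleles))
                )
                fields.append(f"{gt}:{ad}")
            else:
                fields.append(gt)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> tuple[GenotypeTable, DepthTable | None]:
    """Read a minimal VCF (GT required, AD optional) into tables."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    loci, alleles, codes_cols, ad_cols = [], {}, [], []
    has_ad = True
    for rec in vcf:
        locus = rec.ID or f"{rec.CHROM}:{rec.POS}"
        loci.append(locus)
        labs = [rec.REF] + list(rec.ALT)
        alleles[locus] = labs
        gts = rec.genotypes  # [a, b, phased]
        col = np.full((len(individuals), 2), MISSING, dtype=np.int16)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                col[i] = sorted((a, b))
        codes_cols.append(col)
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            has_ad = False
        else:
            ad_cols.append(np.maximum(ad.astype(np.int64), 0))
    codes = np.stack(codes_cols, axis=1)
    table = GenotypeTable(codes, individuals, loci, alleles)
    depths = None
    if has_ad and ad_cols:
        max_k = max(len(alleles[l]) for l in loci)
        counts = np.zeros((len(individuals), len(loci), max_k), dtype=np.int64)
        for j, ad in enumerate(ad_cols):
            counts[:, j, : ad.shape[1]] = ad
        depths = DepthTable(counts, individuals, loci, alleles)
    return table, depths


def read_genotypes(path, dialect: str = "tsv"):
    """Uniform entry point for genotype input.

    ``dialect`` is ``tsv`` (returns a GenotypeTable) or ``minimal-vcf``
    (returns (GenotypeTable, DepthTable | None)).
    """
    if dialect == "tsv":
        return GenotypeTable.read_tsv(path)
    if dialect == "minimal-vcf":
        return read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")
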