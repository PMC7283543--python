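"""File formats: VCF genotypes, TSV expression/annotation, control lists.

Genotypes are exchanged as VCF 4.2 with GT calls on biallelic SNPs, the
risk allele stored as ALT so dosage = ALT-allele count; reading goes through
cyvcf2. Expression is a genes x samples TSV with a header row of sample
ids. Gene annotation is a BED-like TSV (chrom, 1-based TSS, strand,
gene_id); the sample sheet a TSV of sample_id, phenotype, cell_type; the
negative-control list one gene id per line.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionSet, GenotypeTable

__all__ = [
    "write_vcf", "read_vcf", "write_expression", "read_expression",
    "write_genes", "read_genes", "write_samples", "read_samples",
    "write_controls", "read_controls", "write_cohort", "read_expression_set",
]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _chrom_sort_key(c: str):
    tail = c[3:] if c.startswith("chr") else c
    return (0, int(tail)) if tail.isdigit() else (1, tail)


def write_vcf(table: GenotypeTable, path) -> None:
    """Write dosages as a VCF 4.2 file with GT calls (ALT = risk allele)."""
    path = Path(path)
    samples = table.sample_ids
    order = sorted(
        table.snp_ids,
        key=lambda s: (_chrom_sort_key(table.snps.loc[s, "chrom"]), int(table.snps.loc[s, "pos"])),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=RA,Number=1,Type=String,Description="Risk allele">\n')
        for chrom in sorted({table.snps.loc[s, "chrom"] for s in order}, key=_chrom_sort_key):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for snp in order:
            meta = table.snps.loc[snp]
            calls = [
                _GT.get(v, "./.") if np.isfinite(v) else "./."
                for v in table.dosage[snp].to_numpy(dtype=float)
            ]
            fh.write(
                f"{meta.chrom}\t{int(meta.pos)}\t{snp}\t{meta.other_allele}\t"
                f"{meta.risk_allele}\t.\tPASS\tRA={meta.risk_allele}\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypeTable:
    """Read a biallelic-SNP VCF into a risk-allele dosage table (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, meta = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        g = var.gt_types.astype(float)
        dos = np.where(g == 0, 0.0, np.where(g == 1, 1.0, np.where(g == 3, 2.0, np.nan)))
        cols.append(dos)
        ids.append(var.ID)
        meta.append((var.CHROM, var.POS, var.ALT[0], var.REF))
    dosage = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=ids,
    )
    snps = pd.DataFrame(
        meta, columns=["chrom", "pos", "risk_allele", "other_allele"],
        index=pd.Index(ids, name="snp_id"),
    )
    return GenotypeTable(dosage, snps)


def write_expression(es: ExpressionSet, path) -> None:
    es.values.round(6).to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_genes(genes: pd.DataFrame, path) -> None:
    out = genes.reset_index()[["chrom", "tss", "strand", "gene_id"]]
    out.to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("gene_id")[["chrom", "tss", "strand"]]


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.reset_index().to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("sample_id")


def write_controls(gene_ids, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def read_controls(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_expression_set(expr_path, genes_path, samples_path, controls_path,
                        cell_type: str = "cells") -> ExpressionSet:
    """Assemble an ExpressionSet from the four on-disk pieces."""
    values = read_expression(expr_path)
    genes = read_genes(genes_path)
    samples = read_samples(samples_path)
    if "cell_type" in samples.columns and (samples["cell_type"] == cell_type).any():
        samples = samples[samples["cell_type"] == cell_type]
    samples = samples[~samples.index.duplicated()]
    ctl_ids = set(read_controls(controls_path))
    controls = pd.Series(values.index.isin(ctl_ids), index=values.index)
    return ExpressionSet(values=values, genes=genes.reindex(values.index),
                         controls=controls, samples=samples, cell_type=cell_type)


def write_cohort(cohort, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    write_vcf(cohort.genotypes, out / "genotypes.vcf")
    manifest["vcf"] = str(out / "genotypes.vcf")
    any_es = next(iter(cohort.expression.values()))
    write_genes(any_es.genes, out / "genes.tsv")
    manifest["genes"] = str(out / "genes.tsv")
    sheets = []
    for cell, es in cohort.expression.items():
        p = out / f"expression_{cell}.tsv"
        write_expression(es, p)
        manifest[f"expression_{cell}"] = str(p)
        sheets.append(es.samples)
    sheet = pd.concat(sheets)
    sheet = sheet.reset_index().drop_duplicates()
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    manifest["samples"] = str(out / "samples.tsv")
    ctl_ids = list(any_es.controls.index[any_es.controls])
    write_controls(ctl_ids, out / "controls.txt")
    manifest["controls"] = str(out / "controls.txt")
    cohort.truth.pair_effects.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    cohort.truth.gene_info.to_csv(out / "truth_genes.tsv", sep="\t")
    cohort.truth.ld_realized.to_csv(out / "truth_ld.tsv", sep="\t", index=False)
    manifest["truth_pairs"] = str(out / "truth_pairs.tsv")
    manifest["truth_genes"] = str(out / "truth_genes.tsv")
    manifest["truth_ld"] = str(out / "truth_ld.tsv")
    return manifest
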