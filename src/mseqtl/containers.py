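"""In-memory containers shared across the package.

Genotypes are held as risk-allele dosages (0/1/2, NaN = missing call) in a
samples x SNPs table; expression as a genes x samples log2 matrix per cell
type, together with TSS annotation and the negative-control gene mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "ExpressionSet"]


@dataclass
class GenotypeTable:
    """Samples x SNPs risk-allele dosage matrix plus per-SNP metadata.

    Parameters
    ----------
    dosage
        DataFrame indexed by sample id with one column per SNP id; values in
        {0, 1, 2} with NaN for missing genotype calls.
    snps
        DataFrame indexed by snp_id with columns ``chrom``, ``pos`` (1-based),
        ``risk_allele``, ``other_allele``.
    """

    dosage: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosage.columns) != list(self.snps.index):
            # keep metadata aligned with the dosage columns
            self.snps = self.snps.loc[list(self.dosage.columns)]
        vals = self.dosage.to_numpy(dtype=float)
        bad = vals[np.isfinite(vals)]
        if bad.size and (np.nanmin(bad) < 0 or np.nanmax(bad) > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        """Dosage of one SNP across samples (float, NaN = missing)."""
        return self.dosage[snp_id].to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "GenotypeTable":
        return GenotypeTable(self.dosage.loc[list(sample_ids)], self.snps.copy())

    def subset_snps(self, snp_ids) -> "GenotypeTable":
        ids = list(snp_ids)
        return GenotypeTable(self.dosage[ids], self.snps.loc[ids])


@dataclass
class ExpressionSet:
    """Genes x samples log2 expression for one cell type.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns = sample ids, log2 scale.
    genes
        DataFrame indexed by gene_id with columns ``chrom``, ``tss``
        (1-based), ``strand``.
    controls
        Boolean Series indexed by gene id marking negative-control
        (housekeeping) genes.
    samples
        Sample sheet: DataFrame indexed by sample id with columns
        ``phenotype`` ("case"/"control") and ``cell_type``.
    cell_type
        Label of the cell population this matrix was measured in.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    controls: pd.Series
    samples: pd.DataFrame
    cell_type: str = "cells"

    def __post_init__(self) -> None:
        self.controls = self.controls.reindex(self.values.index).fillna(False).astype(bool)
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing[:5]}")
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def phenotype(self) -> np.ndarray:
        """Binary disease indicator per sample (case=1, control=0)."""
        return (self.samples["phenotype"].to_numpy() == "case").astype(float)

    @property
    def control_mask(self) -> np.ndarray:
        return self.controls.to_numpy(dtype=bool)

    def matrix(self) -> np.ndarray:
        """Samples x genes array (the model orientation Y)."""
        return self.values.to_numpy(dtype=float).T
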