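"""SNP-level quality control and linkage-disequilibrium utilities.

Implements the marker QC applied to a candidate risk-SNP panel before eQTL
mapping: genotype call rate, a 1-df chi-square test of Hardy-Weinberg
equilibrium, allelic case/control association with the genomic inflation
factor lambda, squared-dosage-correlation LD, single-linkage LD grouping and
best-proxy substitution within the genotyped panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .containers import GenotypeTable

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1DF_MEDIAN = 0.454936423119572

__all__ = [
    "SnpQcRecord",
    "InflationResult",
    "hwe_test",
    "dosage_r2",
    "ld_groups",
    "best_proxy",
    "genomic_inflation",
    "allelic_chi2",
    "snp_qc",
]


@dataclass
class SnpQcRecord:
    snp_id: str
    call_rate: float
    hwe_p: float
    maf: float
    allelic_chi2: float
    pass_flag: bool


@dataclass
class InflationResult:
    """Genomic inflation factor lambda = median(chi2) / median of chi2_1."""

    lambda_gc: float
    n_snps: int


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg equilibrium goodness-of-fit p-value.

    1-df chi-square test of the observed genotype counts against the HWE
    expectation at the sample allele frequency. Monomorphic input carries no
    evidence against equilibrium and returns 1.0.
    """
    counts = np.asarray([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    # p lies in (0, 1]: clamp survival-function underflow away from zero
    return float(max(stats.chi2.sf(chi2, df=1), np.finfo(float).tiny))


def dosage_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed pairwise-complete over samples with both genotypes called.
    Raises if fewer than 3 complete pairs remain or either vector is
    constant (LD undefined, as opposed to zero).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = np.isfinite(g1) & np.isfinite(g2)
    x, y = g1[keep], g2[keep]
    if x.size < 3:
        raise ValueError("fewer than 3 pairwise-complete samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant dosage vector: LD undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(table: GenotypeTable) -> np.ndarray:
    """Pairwise r2 between all SNPs; NaN where undefined (constant SNP)."""
    m = table.n_snps
    out = np.full((m, m), np.nan)
    vecs = [table.dosage_vector(s) for s in table.snp_ids]
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            try:
                out[i, j] = out[j, i] = dosage_r2(vecs[i], vecs[j])
            except ValueError:
                pass
    return out


def ld_groups(table: GenotypeTable, threshold: float = 0.5) -> pd.DataFrame:
    """Partition SNPs into LD groups by single-linkage clustering.

    Two SNPs share a group whenever they are connected by a chain of
    pairwise r2 > ``threshold``; singletons form their own group. Group ids
    are assigned in panel order of each group's first member, so the result
    is invariant to SNP ordering up to relabeling.

    Returns a DataFrame indexed by snp_id with a ``group_id`` column.
    """
    if table.n_snps < 1:
        raise ValueError("need at least one SNP")
    r2 = _r2_matrix(table)
    adj = sparse.csr_matrix(np.nan_to_num(r2, nan=0.0) > threshold)
    _, labels = connected_components(adj, directed=False)
    # relabel by first occurrence for deterministic ids
    seen: dict[int, int] = {}
    group_ids = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
        group_ids.append(seen[lab])
    return pd.DataFrame({"group_id": group_ids}, index=pd.Index(table.snp_ids, name="snp_id"))


def best_proxy(target_snp: str, panel: GenotypeTable, min_r2: float = 0.5):
    """Best available proxy for ``target_snp`` within the genotyped panel.

    Returns the panel SNP (other than the target) with the largest r2 to the
    target, provided that r2 exceeds ``min_r2``; otherwise ``None``. Ties are
    broken by smaller base-pair distance, then lexicographic snp id.
    """
    if target_snp not in panel.snp_ids:
        raise KeyError(f"target SNP {target_snp!r} not genotyped in panel")
    g_t = panel.dosage_vector(target_snp)
    t_pos = int(panel.snps.loc[target_snp, "pos"])
    best = None  # (neg r2, distance, snp_id)
    for snp in panel.snp_ids:
        if snp == target_snp:
            continue
        try:
            r2 = dosage_r2(g_t, panel.dosage_vector(snp))
        except ValueError:
            continue
        if r2 <= min_r2:
            continue
        dist = abs(int(panel.snps.loc[snp, "pos"]) - t_pos)
        key = (-r2, dist, snp)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


def allelic_chi2(case_A: int, case_a: int, ctrl_A: int, ctrl_a: int) -> float:
    """1-df chi-square for the 2x2 allele-count case/control table."""
    table = np.array([[case_A, case_a], [ctrl_A, ctrl_a]], dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in allele-count table")
    expected = np.outer(rows, cols) / n
    return float(np.sum((table - expected) ** 2 / expected))


def genomic_inflation(table: GenotypeTable, phenotype) -> InflationResult:
    """Genomic inflation lambda from allelic case/control tests.

    For every polymorphic SNP the 2x2 allele-count chi-square comparing
    cases and controls is computed; lambda is the median statistic divided
    by the null median of chi2 with 1 df (0.4549...). SNPs whose table has a
    zero margin are skipped with a log notice.
    """
    phen = np.asarray(phenotype, dtype=float)
    chis = []
    for snp in table.snp_ids:
        g = table.dosage_vector(snp)
        keep = np.isfinite(g)
        g_k, p_k = g[keep], phen[keep]
        case_A = g_k[p_k == 1].sum()
        case_a = 2 * (p_k == 1).sum() - case_A
        ctrl_A = g_k[p_k == 0].sum()
        ctrl_a = 2 * (p_k == 0).sum() - ctrl_A
        try:
            chis.append(allelic_chi2(case_A, case_a, ctrl_A, ctrl_a))
        except ValueError:
            logger.info("SNP %s skipped in lambda estimation (zero-margin table)", snp)
    if not chis:
        raise ValueError("no polymorphic SNPs for inflation estimate")
    lam = float(np.median(chis) / CHI2_1DF_MEDIAN)
    return InflationResult(lambda_gc=lam, n_snps=len(chis))


def snp_qc(
    table: GenotypeTable,
    phenotype=None,
    call_rate_min: float = 0.98,
    hwe_p_min: float = 0.002,
) -> pd.DataFrame:
    """Per-SNP QC table: call rate, HWE p, MAF, allelic chi2, pass flag.

    ``pass_flag`` is true when call rate exceeds ``call_rate_min`` and the
    HWE p-value exceeds ``hwe_p_min`` (defaults: 0.98 and 0.002). The allelic
    chi-square column is NaN when no phenotype is supplied.
    """
    phen = None if phenotype is None else np.asarray(phenotype, dtype=float)
    records = []
    for snp in table.snp_ids:
        g = table.dosage_vector(snp)
        called = np.isfinite(g)
        call_rate = called.mean() if g.size else 0.0
        gc = g[called]
        counts = [(gc == 0).sum(), (gc == 1).sum(), (gc == 2).sum()]
        hwe_p = hwe_test(*counts) if gc.size else 1.0
        af = gc.mean() / 2 if gc.size else np.nan
        maf = min(af, 1 - af) if np.isfinite(af) else np.nan
        chi = np.nan
        if phen is not None:
            p_k = phen[called]
            case_A = gc[p_k == 1].sum()
            ctrl_A = gc[p_k == 0].sum()
            try:
                chi = allelic_chi2(
                    case_A, 2 * (p_k == 1).sum() - case_A, ctrl_A, 2 * (p_k == 0).sum() - ctrl_A
                )
            except ValueError:
                chi = np.nan
        records.append(
            SnpQcRecord(
                snp_id=snp,
                call_rate=float(call_rate),
                hwe_p=float(hwe_p),
                maf=float(maf),
                allelic_chi2=float(chi),
                pass_flag=bool(call_rate > call_rate_min and hwe_p > hwe_p_min),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("snp_id")
    return df
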