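"""Cis-eQTL mapping, interaction and disease-status scans, conditional
adjustment for the strongest local eQTL, and cross-cell-type sharing.

The inference procedure per cell type: enumerate SNP-gene pairs with the
gene TSS within +-500 kb of the SNP, fit per SNP a two-factor RUV model
(X = [G, P]: risk-allele dosage and phenotype) and a three-factor model
(X = [G, P, GxP]) over all genes, and control the FDR by Benjamini-Hochberg
within explicit multiple-testing families: the full enumerated pair family,
the detected-eQTL subset, the near-SNP gene family (X = P fits) or the
whole transcriptome. For each significant pair the strongest local eQTL
SNP is sought in the genotyped panel; if it is not the risk SNP itself nor
a strong proxy (r^2 > 0.8) the risk-SNP coefficient is re-estimated with
the lead SNP in the model and classified by how much it attenuates (a
reduction above 70% or a sign change marks the association as likely
driven by the stronger nearby eQTL).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionSet, GenotypeTable
from .genotype_qc import dosage_r2
from .ruv_core import RuvConfig, RuvDesign, bh_fdr, fit

logger = logging.getLogger(__name__)

CIS_WINDOW = 500_000

__all__ = [
    "ConditionalRecord",
    "enumerate_cis_pairs",
    "run_eqtl_scan",
    "run_interaction_scan",
    "run_phenotype_scan",
    "find_best_local_snp",
    "conditional_adjust",
    "summarize_sharing",
    "benchmark_methods",
]


@dataclass
class ConditionalRecord:
    """Outcome of conditioning one significant pair on the lead local SNP."""

    snp_id: str
    gene_id: str
    best_snp_id: str | None
    r2_with_risk_snp: float
    beta_unadj: float
    beta_adj: float | None
    reduction_fraction: float | None
    attenuation_class: str  # lead_or_proxy | attenuated_major | attenuated_minor


def enumerate_cis_pairs(
    snps: pd.DataFrame, genes: pd.DataFrame, window: int = CIS_WINDOW
) -> pd.DataFrame:
    """All SNP-gene pairs with |TSS - SNP| <= window on the same chromosome.

    ``snps``: indexed by snp_id with chrom/pos; ``genes``: indexed by
    gene_id with chrom/tss. The boundary is inclusive; coordinates are
    1-based; strand is ignored. Genes without a TSS are skipped with a log
    notice. Output is sorted by (chrom, snp_pos, tss_pos) and is exactly
    the brute-force double loop.
    """
    rows = []
    genes_ok = genes
    n_bad = genes["tss"].isna().sum() if "tss" in genes else 0
    if n_bad:
        logger.info("skipping %d genes without TSS annotation", n_bad)
        genes_ok = genes[genes["tss"].notna()]
    by_chrom = {c: sub.sort_values("tss") for c, sub in genes_ok.groupby("chrom")}
    for snp_id, meta in snps.iterrows():
        sub = by_chrom.get(meta["chrom"])
        if sub is None:
            continue
        pos = int(meta["pos"])
        tss = sub["tss"].to_numpy()
        lo = np.searchsorted(tss, pos - window, side="left")
        hi = np.searchsorted(tss, pos + window, side="right")
        for gene_id, gtss in zip(sub.index[lo:hi], tss[lo:hi]):
            rows.append((snp_id, gene_id, meta["chrom"], pos, int(gtss), abs(int(gtss) - pos)))
    out = pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "chrom", "snp_pos", "tss_pos", "distance"]
    )
    return out.sort_values(["chrom", "snp_pos", "tss_pos"], kind="mergesort").reset_index(drop=True)


def _aligned_dosage(es: ExpressionSet, genotypes: GenotypeTable) -> pd.DataFrame:
    missing = [s for s in es.sample_ids if s not in genotypes.dosage.index]
    if missing:
        raise ValueError(f"samples without genotypes: {missing[:5]}")
    return genotypes.dosage.loc[es.sample_ids]

def _fit_one_snp(
    Y: np.ndarray,
    ctl: np.ndarray,
    g: np.ndarray,
    P: np.ndarray,
    config: RuvConfig,
    three_factor: bool,
    extra_g: np.ndarray | None = None,
):
    """Fit one SNP's design on complete-genotype samples.

    Returns (FitResult, kept sample count) or (None, n_kept) when the SNP is
    monomorphic among the analysis samples. Samples missing this SNP's call
    are dropped listwise for this fit only.
    """
    keep = np.isfinite(g)
    if extra_g is not None:
        keep &= np.isfinite(extra_g)
    g_k, P_k = g[keep], P[keep]
    if keep.sum() < 3 or np.ptp(g_k) == 0:
        return None, int(keep.sum())
    cols = [g_k]
    names = ["G"]
    if extra_g is not None:
        cols.append(extra_g[keep])
        names.append("G_sig")
    cols.append(P_k)
    names.append("P")
    if three_factor:
        cols.append(g_k * P_k)
        names.append("GxP")
    X = np.column_stack(cols)
    design = RuvDesign(Y=Y[keep], X=X, ctl=ctl, factor_names=names)
    return fit(design, config), int(keep.sum())


def _scan(
    es: ExpressionSet,
    genotypes: GenotypeTable,
    config: RuvConfig,
    three_factor: bool,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Per-SNP fits over all genes; rows for every cis pair x coefficient."""
    pairs = enumerate_cis_pairs(genotypes.snps, es.genes, window)
    dosage = _aligned_dosage(es, genotypes)
    Y = es.matrix()
    ctl = es.control_mask
    P = es.phenotype
    gene_pos = {g: i for i, g in enumerate(es.gene_ids)}
    rows = []
    for snp_id, sub in pairs.groupby("snp_id", sort=False):
        g = dosage[snp_id].to_numpy(dtype=float)
        res, n_kept = _fit_one_snp(Y, ctl, g, P, config, three_factor)
        if res is None:
            logger.warning("SNP %s monomorphic in analysis sample; pairs reported as NA", snp_id)
        fallback = ["G", "P", "GxP"] if three_factor else ["G", "P"]
        for _, pr in sub.iterrows():
            j = gene_pos[pr.gene_id]
            for f_idx, coef in enumerate(res.factor_names if res else fallback):
                if res is None:
                    rows.append((snp_id, pr.gene_id, coef, np.nan, np.nan, np.nan, np.nan, n_kept))
                else:
                    rows.append(
                        (
                            snp_id,
                            pr.gene_id,
                            coef,
                            res.beta[f_idx, j],
                            res.se[f_idx, j],
                            res.t[f_idx, j],
                            res.p[f_idx, j],
                            n_kept,
                        )
                    )
    out = pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "coefficient", "beta", "se", "t", "p", "n_samples"]
    )
    out.insert(0, "cell_type", es.cell_type)
    return out


def _attach_q(df: pd.DataFrame, family_id: str) -> pd.DataFrame:
    df = df.copy()
    df["q"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        df.loc[ok, "q"] = bh_fdr(df.loc[ok, "p"].to_numpy())
    df["family_id"] = family_id
    return df


def run_eqtl_scan(
    es: ExpressionSet,
    genotypes: GenotypeTable,
    config: RuvConfig | None = None,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Two-factor cis-eQTL scan: genotype coefficient, BH over all cis pairs.

    Log expression is modeled per SNP as a linear function of risk-allele
    count, adjusting for case/control status, on pooled cases+controls;
    q-values are computed within the full enumerated pair family for the
    cell type.
    """
    config = config or RuvConfig()
    full = _scan(es, genotypes, config, three_factor=False, window=window)
    out = full[full.coefficient == "G"].reset_index(drop=True)
    return _attach_q(out, f"{es.cell_type}:cis_pairs:G")


def run_interaction_scan(
    es: ExpressionSet,
    genotypes: GenotypeTable,
    config: RuvConfig | None = None,
    family: str = "all_pairs",
    eqtl_results: pd.DataFrame | None = None,
    fdr_q: float = 0.05,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Three-factor scan for genotype-by-phenotype interaction.

    ``family="all_pairs"`` adjusts the interaction p-values over the full
    enumerated pair family (discovery of interactions invisible to the
    additive model); ``family="eqtl_subset"`` restricts to pairs significant
    in ``eqtl_results`` (q < ``fdr_q``) and adjusts only over those — the
    less stringent family controlling for the number of detected eQTLs.
    """
    config = config or RuvConfig()
    full = _scan(es, genotypes, config, three_factor=True, window=window)
    out = full[full.coefficient == "GxP"].reset_index(drop=True)
    if family == "all_pairs":
        return _attach_q(out, f"{es.cell_type}:all_pairs:GxP")
    if family != "eqtl_subset":
        raise ValueError(f"unknown interaction family {family!r}")
    if eqtl_results is None:
        raise ValueError("eqtl_subset family requires eqtl_results")
    sig = eqtl_results[eqtl_results.q < fdr_q][["snp_id", "gene_id"]]
    out = out.merge(sig, on=["snp_id", "gene_id"], how="inner")
    return _attach_q(out, f"{es.cell_type}:eqtl_subset:GxP")


def run_phenotype_scan(
    es: ExpressionSet,
    genotypes: GenotypeTable | None = None,
    config: RuvConfig | None = None,
    family: str = "near_snp_genes",
    eqtl_results: pd.DataFrame | None = None,
    fdr_q: float = 0.05,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Case/control differential expression, in the stated test family.

    Pair families test the phenotype coefficient of the two-factor model:
    ``near_snp_pairs`` (BH over all cis pairs) or ``eqtl_subset`` (over the
    detected eQTL pairs). Gene families fit phenotype as the only factor of
    interest (X = P) once for all genes: ``near_snp_genes`` adjusts over the
    genes lying within the cis window of any panel SNP, ``transcriptome``
    over every gene on the array.
    """
    config = config or RuvConfig()
    if family in ("near_snp_pairs", "eqtl_subset"):
        if genotypes is None:
            raise ValueError("pair families require genotypes")
        full = _scan(es, genotypes, config, three_factor=False, window=window)
        out = full[full.coefficient == "P"].reset_index(drop=True)
        if family == "near_snp_pairs":
            return _attach_q(out, f"{es.cell_type}:cis_pairs:P")
        if eqtl_results is None:
            raise ValueError("eqtl_subset family requires eqtl_results")
        sig = eqtl_results[eqtl_results.q < fdr_q][["snp_id", "gene_id"]]
        out = out.merge(sig, on=["snp_id", "gene_id"], how="inner")
        return _attach_q(out, f"{es.cell_type}:eqtl_subset:P")
    if family not in ("near_snp_genes", "transcriptome"):
        raise ValueError(f"unknown phenotype family {family!r}")
    design = RuvDesign(Y=es.matrix(), X=es.phenotype, ctl=es.control_mask, factor_names=["P"])
    res = fit(design, config)
    out = pd.DataFrame(
        {
            "cell_type": es.cell_type,
            "gene_id": es.gene_ids,
            "coefficient": "P",
            "beta": res.beta[0],
            "se": res.se[0],
            "t": res.t[0],
            "p": res.p[0],
            "n_samples": es.n_samples,
        }
    )
    if family == "near_snp_genes":
        if genotypes is None:
            raise ValueError("near_snp_genes family requires genotypes")
        pairs = enumerate_cis_pairs(genotypes.snps, es.genes, window)
        near = set(pairs.gene_id)
        out = out[out.gene_id.isin(near)].reset_index(drop=True)
        return _attach_q(out, f"{es.cell_type}:near_genes:P")
    return _attach_q(out, f"{es.cell_type}:transcriptome:P")


def find_best_local_snp(
    gene_id: str,
    es: ExpressionSet,
    panel: GenotypeTable,
    config: RuvConfig | None = None,
    window: int = CIS_WINDOW,
):
    """The panel SNP most significantly associated with one gene.

    Every panel SNP within ``window`` of the gene's TSS is fit with the
    two-factor model and the smallest genotype p-value wins; ties break by
    distance to the TSS, then lexicographic id. Returns (snp_id, p) or
    (None, nan) when no local SNP exists. The fit restricts Y to the
    negative controls plus the target gene, which leaves the estimate
    unchanged (the control second-moment matrix and the gene's own
    statistics are all that enter).
    """
    config = config or RuvConfig()
    gene = es.genes.loc[gene_id]
    local = panel.snps[
        (panel.snps.chrom == gene.chrom) & ((panel.snps.pos - int(gene.tss)).abs() <= window)
    ]
    if local.empty:
        return None, float("nan")
    ctl = es.control_mask.copy()
    keep_genes = ctl.copy()
    gi = es.gene_ids.index(gene_id)
    keep_genes[gi] = True
    Y = es.matrix()[:, keep_genes]
    sub_ctl = ctl[keep_genes]
    j = int(np.where(np.flatnonzero(keep_genes) == gi)[0][0])
    dosage = _aligned_dosage(es, panel)
    P = es.phenotype
    best = None
    for snp_id, meta in local.iterrows():
        g = dosage[snp_id].to_numpy(dtype=float)
        res, _ = _fit_one_snp(Y, sub_ctl, g, P, config, three_factor=False)
        if res is None:
            continue
        p_val = float(res.p[0, j])
        dist = abs(int(meta.pos) - int(gene.tss))
        key = (p_val, dist, snp_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, float("nan")
    return best[2], best[0]


def conditional_adjust(
    snp_id: str,
    gene_id: str,
    es: ExpressionSet,
    panel: GenotypeTable,
    config: RuvConfig | None = None,
    window: int = CIS_WINDOW,
    lead_r2: float = 0.8,
    reduction_cut: float = 0.70,
) -> ConditionalRecord:
    """Condition a significant risk-SNP pair on the strongest local eQTL.

    If the lead SNP is the risk SNP itself or in strong LD with it
    (r^2 > ``lead_r2``) the pair is classified ``lead_or_proxy`` without a
    refit (near-collinear lead SNPs, r^2 >= 0.999, are forced into this
    class with a warning). Otherwise the model gains the lead SNP's dosage:
    Y = G_MS b_MS-adj + G_sig b_sig + P b_P (+ unwanted variation), and the
    risk-SNP coefficient before vs after conditioning yields
    reduction = 1 - b_adj/b_unadj. A reduction above ``reduction_cut`` or a
    sign change marks ``attenuated_major``; anything else
    ``attenuated_minor``.
    """
    config = config or RuvConfig()
    ctl = es.control_mask.copy()
    keep_genes = ctl.copy()
    gi = es.gene_ids.index(gene_id)
    keep_genes[gi] = True
    Y = es.matrix()[:, keep_genes]
    sub_ctl = ctl[keep_genes]
    j = int(np.where(np.flatnonzero(keep_genes) == gi)[0][0])
    dosage = _aligned_dosage(es, panel)
    P = es.phenotype
    g_ms = dosage[snp_id].to_numpy(dtype=float)

    res_unadj, _ = _fit_one_snp(Y, sub_ctl, g_ms, P, config, three_factor=False)
    if res_unadj is None:
        raise ValueError(f"risk SNP {snp_id} monomorphic; cannot condition")
    beta_unadj = float(res_unadj.beta[0, j])

    best_snp, _ = find_best_local_snp(gene_id, es, panel, config=config, window=window)
    if best_snp is None or best_snp == snp_id:
        return ConditionalRecord(snp_id, gene_id, best_snp, 1.0, beta_unadj, None, None,
                                 "lead_or_proxy")
    g_sig = dosage[best_snp].to_numpy(dtype=float)
    r2 = dosage_r2(g_ms, g_sig)
    if r2 > lead_r2:
        if r2 >= 0.999:
            logger.warning(
                "lead SNP %s near-collinear with %s (r2=%.4f); forcing lead_or_proxy",
                best_snp, snp_id, r2,
            )
        return ConditionalRecord(snp_id, gene_id, best_snp, r2, beta_unadj, None, None,
                                 "lead_or_proxy")
    res_adj, _ = _fit_one_snp(Y, sub_ctl, g_ms, P, config, three_factor=False, extra_g=g_sig)
    beta_adj = float(res_adj.beta[0, j])
    cls, reduction = classify_attenuation(beta_unadj, beta_adj, reduction_cut)
    return ConditionalRecord(snp_id, gene_id, best_snp, r2, beta_unadj, beta_adj, reduction, cls)


def classify_attenuation(
    beta_unadj: float, beta_adj: float, reduction_cut: float = 0.70
) -> tuple[str, float | None]:
    """Apply the attenuation rule to an (unadjusted, adjusted) coefficient pair.

    A sign change, or a reduction 1 - beta_adj/beta_unadj above
    ``reduction_cut``, yields ``attenuated_major``; otherwise
    ``attenuated_minor``. The reduction fraction is undefined (None) on a
    sign change. Scale-invariant by construction.
    """
    if np.sign(beta_adj) != np.sign(beta_unadj):
        return "attenuated_major", None
    reduction = 1.0 - beta_adj / beta_unadj
    return ("attenuated_major" if reduction > reduction_cut else "attenuated_minor"), reduction


def summarize_sharing(results_by_cell: dict, fdr_q: float = 0.05) -> pd.DataFrame:
    """Cross-cell-type sharing of eQTL genes.

    For each gene significant (q < ``fdr_q``) in at least one cell type:
    the set of cell types, the per-cell direction (sign of the most
    significant pair's genotype coefficient) and a concordance flag that is
    false as soon as two cell types disagree in direction.
    """
    per_gene: dict[str, dict[str, float]] = {}
    for cell, df in results_by_cell.items():
        sig = df[(df.q < fdr_q) & df.beta.notna()]
        for gene_id, sub in sig.groupby("gene_id"):
            top = sub.loc[sub.p.idxmin()]
            per_gene.setdefault(gene_id, {})[cell] = float(np.sign(top.beta))
    rows = []
    for gene_id, dirs in sorted(per_gene.items()):
        cells = sorted(dirs)
        signs = [dirs[c] for c in cells]
        rows.append(
            {
                "gene_id": gene_id,
                "cell_types": ",".join(cells),
                "n_cell_types": len(cells),
                "directions": ",".join("+" if s > 0 else "-" for s in signs),
                "concordant": len(set(signs)) <= 1,
            }
        )
    return pd.DataFrame(rows)


def sharing_region_counts(summary: pd.DataFrame) -> pd.Series:
    """Venn-style counts of genes per cell-type combination."""
    if summary.empty:
        return pd.Series(dtype=int)
    return summary.groupby("cell_types").size().sort_index()


def _truth_pair_status(scan: pd.DataFrame, truth, genotypes: GenotypeTable,
                       tag_r2: float = 0.5) -> pd.Series:
    """Label each scanned pair causal / tagged / null against the truth table.

    A pair is causal when the truth table plants a genotype effect on it,
    tagged when the SNP has r^2 > ``tag_r2`` with a causal SNP of the same
    gene (an LD shadow, counted as neither true nor false in detection
    rates), and null otherwise.
    """
    causal = {(r.snp_id, r.gene_id) for r in truth.pair_effects.itertuples() if r.beta_g != 0}
    by_gene: dict[str, list[str]] = {}
    for s, g in causal:
        by_gene.setdefault(g, []).append(s)
    dosage = genotypes.dosage
    labels = []
    for r in scan.itertuples():
        if (r.snp_id, r.gene_id) in causal:
            labels.append("causal")
            continue
        lab = "null"
        for s_causal in by_gene.get(r.gene_id, []):
            try:
                if dosage_r2(dosage[r.snp_id], dosage[s_causal]) > tag_r2:
                    lab = "tagged"
                    break
            except ValueError:
                pass
        labels.append(lab)
    return pd.Series(labels, index=scan.index)


def benchmark_methods(
    cohort,
    methods: list[RuvConfig] | None = None,
    cell_type: str | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Compare RUV flavours by detection of high-confidence planted eQTLs.

    For each method configuration the cis scan is run on one cell type and
    scored against the truth table: detection rate among high-confidence
    planted pairs (q < ``fdr_q``), detection over all planted pairs, and
    raw false-positive rates at p < 0.05 among truly null pairs for the
    genotype and phenotype coefficients.
    """
    if methods is None:
        methods = [
            RuvConfig(method="ols", calibrate=False),
            RuvConfig(method="ruv2", k=3),
            RuvConfig(method="ruv4", k=3),
            RuvConfig(method="ruvinv"),
            RuvConfig(method="ruvrinv"),
        ]
    cell_type = cell_type or next(iter(cohort.expression))
    es = cohort.expression[cell_type]
    truth = cohort.truth
    rows = []
    for cfg in methods:
        scan_g = run_eqtl_scan(es, cohort.genotypes, cfg)
        scan_p = run_phenotype_scan(es, cohort.genotypes, cfg, family="near_snp_pairs")
        status = _truth_pair_status(scan_g, truth, cohort.genotypes)
        hc = {(r.snp_id, r.gene_id) for r in truth.pair_effects.itertuples()
              if r.high_confidence and r.beta_g != 0}
        is_hc = scan_g.apply(lambda r: (r.snp_id, r.gene_id) in hc, axis=1)
        det_hc = float((scan_g.q[is_hc] < fdr_q).mean()) if is_hc.any() else np.nan
        det_all = float((scan_g.q[status == "causal"] < fdr_q).mean()) if (status == "causal").any() else np.nan
        null_g = scan_g.p[status == "null"]
        null_p = scan_p.p[(status == "null").to_numpy()]
        rows.append(
            {
                "method": cfg.method,
                "k": cfg.k if cfg.method in ("ruv2", "ruv4") else np.nan,
                "calibrated": cfg.calibrate,
                "hc_detection": det_hc,
                "detection": det_all,
                "null_fpr_G": float((null_g < 0.05).mean()),
                "null_fpr_P": float((null_p < 0.05).mean()),
                "n_hc": int(is_hc.sum()),
            }
        )
    return pd.DataFrame(rows)
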