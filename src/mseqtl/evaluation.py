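"""Truth-table scoring of the pipeline on synthetic cohorts.

Each function simulates a cohort under a stated study condition, runs the
relevant estimator, and scores it against the generator's ground truth:
type-I error under a confounded null, false-discovery proportion and power
of the BH-controlled cis scan, recovery of planted effect sizes, detection
of genotype-by-phenotype interactions invisible to the additive model,
attenuation classification under tagging, batch removal by
cross-normalization, and the method benchmark. These are the quantities a
practitioner would check before trusting the pipeline on real data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diagnostics
from .eqtl_pipeline import (
    _truth_pair_status,
    benchmark_methods,
    conditional_adjust,
    run_eqtl_scan,
    run_interaction_scan,
)
from .ruv_core import RuvConfig, RuvDesign, fit
from .synthetic_data import CohortConfig, annotate_genes, simulate_cohort, simulate_expression, simulate_genotypes

__all__ = [
    "null_calibration",
    "fdr_power_recovery",
    "interaction_rates",
    "conditional_rates",
    "crossnorm_metrics",
    "benchmark_rates",
]


def _null_config(seed: int) -> CohortConfig:
    """The confounded null: no planted effects, 3 unwanted factors with the
    last correlated 0.8 with phenotype, 130 samples, 2,000 genes of which
    200 are negative controls, 100 SNPs."""
    return CohortConfig(
        n_cases=52,
        n_controls=78,
        n_snps=100,
        n_genes=2000,
        n_controls_genes=200,
        effect_grid=[],
        ld_pairs=[],
        n_uv_factors=3,
        uv_confounding=0.8,
        seed=seed,
    )


def null_calibration(seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of calibrated RUV-rinv vs naive OLS on a confounded null.

    Per SNP the two-factor model (G, P) is fit to every gene; the fraction
    of null (non-control) gene p-values below ``alpha`` is pooled over all
    SNP fits — well over 50,000 genotype tests. Reported for the genotype
    and phenotype coefficients of calibrated RUV-rinv and of ordinary least
    squares with no unwanted-variation adjustment (whose phenotype tests
    the phenotype-correlated factor inflates).
    """
    cohort = simulate_cohort(_null_config(seed))
    es = next(iter(cohort.expression.values()))
    Y = es.matrix()
    ctl = es.control_mask
    P = es.phenotype
    dosage = cohort.genotypes.dosage.loc[es.sample_ids]
    counts = {("ruvrinv", "G"): 0, ("ruvrinv", "P"): 0, ("ols", "G"): 0, ("ols", "P"): 0}
    totals = dict.fromkeys(counts, 0)
    cfgs = {"ruvrinv": RuvConfig(method="ruvrinv"), "ols": RuvConfig(method="ols", calibrate=False)}
    free = ~ctl
    for snp_id in cohort.genotypes.snp_ids:
        g = dosage[snp_id].to_numpy(dtype=float)
        keep = np.isfinite(g)
        if np.ptp(g[keep]) == 0:
            continue
        X = np.column_stack([g[keep], P[keep]])
        design = RuvDesign(Y=Y[keep], X=X, ctl=ctl, factor_names=["G", "P"])
        for name, cfg in cfgs.items():
            res = fit(design, cfg)
            for f_idx, coef in enumerate(["G", "P"]):
                pv = res.p[f_idx, free]
                counts[(name, coef)] += int((pv < alpha).sum())
                totals[(name, coef)] += pv.size
    out = {f"{name}_{coef}": counts[(name, coef)] / totals[(name, coef)] for name, coef in counts}
    out["n_tests"] = totals[("ruvrinv", "G")]
    return out


def _fdr_config(seed: int) -> CohortConfig:
    """Planted-effect cohort for FDR/power/recovery scoring: 131 samples,
    30 SNPs without LD (so per-pair truth is unambiguous), 800 genes with
    150 controls, 10% of cis genes carrying an anchor-SNP effect from the
    grid 0.2..0.6."""
    return CohortConfig(
        n_snps=30,
        n_genes=800,
        n_controls_genes=150,
        cis_fraction=0.7,
        ld_pairs=[],
        effect_fraction=0.10,
        seed=seed,
    )


def fdr_power_recovery(seeds=range(20), fdr_q: float = 0.05) -> dict:
    """BH false-discovery proportion, power at beta=0.5, and recovery.

    Per seed the cis scan runs on a planted cohort; discoveries at
    q < ``fdr_q`` are scored against the truth table. Returns the
    seed-averaged FDP, the detection rate among pairs planted at exactly
    0.5 log2/allele, and (pooled over seeds) the Pearson correlation and
    mean absolute bias of the estimated vs planted genotype coefficients.
    """
    fdps, powers = [], []
    est, truth_b = [], []
    for seed in seeds:
        cohort = simulate_cohort(_fdr_config(int(seed)))
        es = next(iter(cohort.expression.values()))
        res = run_eqtl_scan(es, cohort.genotypes)
        planted = cohort.truth.pair_effects
        causal = {(r.snp_id, r.gene_id): r.beta_g for r in planted.itertuples() if r.beta_g != 0}
        sig = res[res.q < fdr_q]
        n_disc = len(sig)
        n_false = sum((r.snp_id, r.gene_id) not in causal for r in sig.itertuples())
        fdps.append(n_false / max(n_disc, 1))
        lookup = res.set_index(["snp_id", "gene_id"])
        hits05 = []
        for (s, g), b in causal.items():
            row = lookup.loc[(s, g)]
            est.append(float(row.beta))
            truth_b.append(b)
            if b == 0.5:
                hits05.append(bool(row.q < fdr_q))
        powers.append(np.mean(hits05))
    est, truth_b = np.asarray(est), np.asarray(truth_b)
    return {
        "fdp": float(np.mean(fdps)),
        "power_beta05": float(np.mean(powers)),
        "beta_corr": float(np.corrcoef(est, truth_b)[0, 1]),
        # systematic bias: |mean signed error| across planted pairs
        "beta_abs_bias": float(abs(np.mean(est - truth_b))),
        "beta_rmse": float(np.sqrt(np.mean((est - truth_b) ** 2))),
        "n_planted": int(truth_b.size),
    }


def _interaction_config(seed: int, null: bool = False) -> CohortConfig:
    """Opposing-sign interaction scenario: one cis pair with slope +0.3 in
    controls and -0.3 in cases (beta_GP = -0.6); no other planted effects."""
    return CohortConfig(
        n_snps=10,
        n_genes=400,
        n_controls_genes=100,
        cis_fraction=0.7,
        ld_pairs=[],
        effect_grid=[],
        interaction_effects=[] if null else [(0.3, -0.6)],
        seed=seed,
    )


def interaction_rates(seeds=range(20), fdr_q: float = 0.05) -> dict:
    """Detection of an opposing-sign GxP effect and its additive blind spot.

    Per seed: is the planted pair's interaction significant (q < ``fdr_q``
    over the all-pairs family) with the correct sign, and does the additive
    two-factor scan miss the same pair? The unadjusted interaction type-I
    error is pooled over the unplanted pairs of the same scans.
    """
    detected, correct_sign, additive_missed = [], [], []
    null_p = []
    for seed in seeds:
        cohort = simulate_cohort(_interaction_config(int(seed)))
        es = next(iter(cohort.expression.values()))
        planted = cohort.truth.pair_effects.iloc[0]
        inter = run_interaction_scan(es, cohort.genotypes, family="all_pairs")
        inter_i = inter.set_index(["snp_id", "gene_id"])
        row = inter_i.loc[(planted.snp_id, planted.gene_id)]
        detected.append(bool(row.q < fdr_q))
        correct_sign.append(bool(np.sign(row.beta) == np.sign(planted.beta_gp)))
        other = inter[~((inter.snp_id == planted.snp_id) & (inter.gene_id == planted.gene_id))]
        null_p.extend(other.p.dropna().tolist())
        add = run_eqtl_scan(es, cohort.genotypes).set_index(["snp_id", "gene_id"])
        additive_missed.append(bool(add.loc[(planted.snp_id, planted.gene_id)].q >= fdr_q))
    null_p = np.asarray(null_p)
    return {
        "detection_rate": float(np.mean(detected)),
        "sign_correct_rate": float(
            np.mean([s for s, d in zip(correct_sign, detected) if d]) if any(detected) else np.nan
        ),
        "additive_miss_rate": float(np.mean(additive_missed)),
        "null_type1": float((null_p < 0.05).mean()),
        "n_null_tests": int(null_p.size),
    }


def _conditional_cohort(seed: int, causal_is_risk: bool):
    """Two-SNP locus: risk SNP snp_0000, a second local SNP snp_0001 in LD
    at target r^2 0.6, plus a weaker tag and unrelated loci. The planted
    eQTL (beta = 0.5) sits on the risk SNP itself or on the LD partner."""
    config = CohortConfig(
        n_snps=6,
        n_genes=300,
        n_controls_genes=100,
        cis_fraction=0.7,
        ld_pairs=[(0, 1, 0.6), (0, 2, 0.3)],
        effect_grid=[],
        seed=seed,
    )
    genotypes = simulate_genotypes(config)
    genes = annotate_genes(genotypes, config)
    gene = genes.index[genes.anchor_snp == "snp_0000"][0]
    causal = "snp_0000" if causal_is_risk else "snp_0001"
    effects = pd.DataFrame({"snp_id": [causal], "gene_id": [gene], "beta_g": [0.5]})
    expression, truth = simulate_expression(genotypes, config, effects=effects)
    return genotypes, next(iter(expression.values())), gene


def conditional_rates(seeds=range(20)) -> dict:
    """Attenuation classification under tagging vs a causal risk SNP.

    Tagging scenario: the risk SNP's association is borrowed through LD
    (r^2 ~ 0.6) from a causal partner; conditioning on the lead local SNP
    should collapse the risk-SNP coefficient (class attenuated_major).
    Causal scenario: the risk SNP itself drives expression; the class
    should stay lead_or_proxy or attenuated_minor.
    """
    major_when_tagging, major_when_causal = [], []
    for seed in seeds:
        genotypes, es, gene = _conditional_cohort(int(seed), causal_is_risk=False)
        rec = conditional_adjust("snp_0000", gene, es, genotypes)
        major_when_tagging.append(rec.attenuation_class == "attenuated_major")
        genotypes, es, gene = _conditional_cohort(int(seed), causal_is_risk=True)
        rec = conditional_adjust("snp_0000", gene, es, genotypes)
        major_when_causal.append(rec.attenuation_class == "attenuated_major")
    return {
        "tagging_attenuated_major_rate": float(np.mean(major_when_tagging)),
        "causal_attenuated_major_rate": float(np.mean(major_when_causal)),
    }


def _crossnorm_config(seed: int) -> CohortConfig:
    """Batch-removal scenario: a dominant binary batch factor (loading SD
    0.6 vs 0.15 for the two minor factors, none phenotype-correlated) and
    ten genes carrying a +0.3 log2 case/control shift."""
    return CohortConfig(
        n_snps=10,
        n_genes=600,
        n_controls_genes=150,
        cis_fraction=0.7,
        ld_pairs=[],
        effect_grid=[],
        phenotype_effects=[0.3] * 10,
        n_uv_factors=3,
        uv_confounding=0.0,
        uv_strengths=(0.6, 0.15, 0.15),
        seed=seed,
    )


def crossnorm_metrics(seed: int = 0) -> dict:
    """Batch removal and signal retention under cross-normalization (X = P).

    Reports the fraction of genes whose adjusted values correlate with the
    planted batch at |r| <= 0.1, the mean recovered case/control difference
    across the planted genes relative to the planted +0.3 shift, and the
    first SVD sample score's correlation with batch before and after.
    """
    cohort = simulate_cohort(_crossnorm_config(seed))
    cell, es = next(iter(cohort.expression.items()))
    batch = cohort.truth.W[cell]["W1"].to_numpy()
    P = es.phenotype
    design = RuvDesign(Y=es.matrix(), X=P, ctl=es.control_mask, factor_names=["P"])
    adj = diagnostics.cross_normalize(design)
    Y_adj = adj.Y_adjusted  # samples x genes

    cors = np.abs(
        [np.corrcoef(Y_adj[:, j], batch)[0, 1] for j in range(Y_adj.shape[1])]
    )
    frac_low = float((cors <= 0.1).mean())

    planted = cohort.truth.gene_info.index[cohort.truth.gene_info.beta_p != 0]
    gene_pos = {g: i for i, g in enumerate(es.gene_ids)}
    diffs = [
        Y_adj[P == 1, gene_pos[g]].mean() - Y_adj[P == 0, gene_pos[g]].mean() for g in planted
    ]
    rel_err = abs(float(np.mean(diffs)) - 0.3) / 0.3

    sv_before = diagnostics.svd_scores(es.values, d=1)
    sv_after = diagnostics.svd_scores(
        pd.DataFrame(Y_adj.T, index=es.gene_ids, columns=es.sample_ids), d=1
    )
    cor_before = abs(float(np.corrcoef(sv_before.scores[:, 0], batch)[0, 1]))
    cor_after = abs(float(np.corrcoef(sv_after.scores[:, 0], batch)[0, 1]))
    return {
        "frac_genes_batch_decorrelated": frac_low,
        "phenotype_effect_rel_error": rel_err,
        "svd1_batch_corr_before": cor_before,
        "svd1_batch_corr_after": cor_after,
    }


def _benchmark_config(seed: int) -> CohortConfig:
    """Confounded planted cohort for the method comparison: unwanted factor
    correlated 0.8 with phenotype, 10% of cis genes carrying effects."""
    return CohortConfig(
        n_snps=30,
        n_genes=800,
        n_controls_genes=200,
        cis_fraction=0.7,
        ld_pairs=[],
        effect_fraction=0.10,
        uv_confounding=0.8,
        seed=seed,
    )


def benchmark_rates(seed: int = 0) -> pd.DataFrame:
    """Detection/false-positive table for OLS vs the RUV estimators on a
    confounded cohort with planted high-confidence eQTLs."""
    cohort = simulate_cohort(_benchmark_config(seed))
    methods = [
        RuvConfig(method="ols", calibrate=False),
        RuvConfig(method="ruv2", k=3),
        RuvConfig(method="ruv4", k=3),
        RuvConfig(method="ruvinv"),
        RuvConfig(method="ruvrinv"),
    ]
    return benchmark_methods(cohort, methods=methods)
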