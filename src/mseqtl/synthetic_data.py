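"""Synthetic case/control cohorts with planted cis-eQTL structure.

The generator emulates the data structure of an immune-cell eQTL study of a
case/control cohort genotyped on a candidate risk-SNP panel: SNPs in
Hardy-Weinberg equilibrium (some pairs in LD, produced by haplotype copying
with a controlled flip rate), five purifiable cell types with per-cell-type
sample subsets, log2 expression driven by planted additive genotype effects
on nearby (cis) genes, genotype-by-phenotype interaction effects,
case/control shifts, latent unwanted-variation factors (batch, sample
quality, one partially confounded with phenotype) loading on every gene
including a set of housekeeping negative controls, plus iid Gaussian noise.

Everything is seed-deterministic and a machine-readable truth table records
the planted parameters, so downstream estimators can be tested for
calibration and parameter recovery without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionSet, GenotypeTable
from .genotype_qc import dosage_r2

__all__ = ["CohortConfig", "TruthTable", "Cohort", "simulate_genotypes",
           "annotate_genes", "simulate_expression", "simulate_cohort", "write_cohort"]

# independent substream labels hashed together with the user seed
_GENO, _GENES, _EFFECTS, _EXPR = 11, 22, 33, 44

#: bp between neighbouring SNP loci; cis windows of distinct loci never overlap
_LOCUS_SPACING = 2_000_000
_FIRST_LOCUS = 1_000_000
_LOCI_PER_CHROM = 20
#: max |TSS - anchor SNP| for a cis gene; < 500 kb also for the anchor's LD partner
_CIS_OFFSET = 450_000
_LD_PARTNER_OFFSET = 40_000


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the monocyte arm of the study design the package
    targets: 53 cases / 78 controls, a panel of 172 risk SNPs with a few LD
    proxy pairs, ~1,500 cis genes plus background genes and 575 housekeeping
    negative controls, three latent unwanted factors with the last partially
    confounded with phenotype. All counts are configurable.

    Notes on individual fields:

    - ``ld_pairs``: (i, j, target_r2) triples of SNP indices; SNP j is
      generated from SNP i's haplotypes by allele copying with flip
      probability f solving r^2 = (1 - 2f)^2, and is placed within 40 kb of
      SNP i so both see the same cis genes.
    - ``effect_grid`` / ``effect_fraction``: a fraction of cis genes receive
      an additive per-allele log2 effect on their anchor SNP, cycling
      through the grid.
    - ``interaction_effects``: each entry plants one cis pair with a
      genotype-by-phenotype interaction; an entry may be a plain beta_GP
      (genotype effect confined to the interaction) or a ``(beta_G,
      beta_GP)`` tuple, where beta_G is the slope in controls and
      beta_G + beta_GP the slope in cases.
    - ``phenotype_effects``: each entry plants one gene with a case/control
      log2 shift beta_P.
    - ``uv_confounding``: target correlation between the last unwanted
      factor and the phenotype indicator.
    - ``uv_strengths``: per-factor SD of the gene loadings alpha (log2
      units); cycled if shorter than ``n_uv_factors``.
    """

    n_cases: int = 53
    n_controls: int = 78
    n_snps: int = 172
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_pairs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, 1, 0.6), (2, 3, 0.7), (4, 5, 0.8), (6, 7, 0.9), (8, 9, 1.0)]
    )
    n_genes: int = 2275
    n_controls_genes: int = 575
    cis_fraction: float = 0.88
    effect_grid: list[float] = field(default_factory=lambda: [0.2, 0.3, 0.4, 0.5, 0.6])
    effect_fraction: float = 0.10
    interaction_effects: list = field(default_factory=list)
    phenotype_effects: list[float] = field(default_factory=list)
    n_uv_factors: int = 3
    uv_confounding: float = 0.3
    uv_strengths: tuple[float, ...] = (0.4, 0.25, 0.25)
    noise_sd_range: tuple[float, float] = (0.2, 0.4)
    missing_rate: float = 0.005
    cell_types: tuple[str, ...] = ("monocytes",)
    cell_type_counts: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range frequencies must lie in (0, 1)")
        if self.n_controls_genes >= self.n_genes:
            raise ValueError("n_controls_genes must be < n_genes")
        if self.n_uv_factors < 0:
            raise ValueError("n_uv_factors must be >= 0")
        s_lo, s_hi = self.noise_sd_range
        if not (0 < s_lo <= s_hi):
            raise ValueError("noise SDs must be positive")
        if not 0 <= self.uv_confounding < 1:
            raise ValueError("uv_confounding must lie in [0, 1)")
        derived = set()
        for i, j, r2 in self.ld_pairs:
            if not 0 < r2 <= 1:
                raise ValueError(f"LD pair ({i},{j}) target r2 {r2} outside (0, 1]")
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps) or i == j:
                raise ValueError(f"LD pair ({i},{j}) has invalid SNP indices")
            if j in derived or any(i == jj for _, jj, _ in self.ld_pairs if jj != j and False):
                raise ValueError(f"SNP {j} derived twice in ld_pairs")
            derived.add(j)
        if derived & {i for i, _, _ in self.ld_pairs}:
            raise ValueError("chained ld_pairs are not supported")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    def counts_for(self, cell_type: str) -> tuple[int, int]:
        if self.cell_type_counts and cell_type in self.cell_type_counts:
            return tuple(self.cell_type_counts[cell_type])
        return (self.n_cases, self.n_controls)

    @classmethod
    def study_default(cls, **kw) -> "CohortConfig":
        """Five-cell-type configuration with the study's per-cell sample sizes."""
        counts = {
            "monocytes": (53, 78),
            "nk": (45, 78),
            "b": (37, 87),
            "cd4": (38, 85),
            "cd8": (55, 91),
        }
        base = dict(
            n_cases=73,
            n_controls=97,
            cell_types=tuple(counts),
            cell_type_counts=counts,
        )
        base.update(kw)
        return cls(**base)


@dataclass
class TruthTable:
    """Ground truth of one simulated cohort.

    - ``pair_effects``: one row per planted SNP-gene pair (snp_id, gene_id,
      beta_g, beta_gp, high_confidence); pairs not listed have zero effects.
    - ``gene_info``: per gene: control flag, residual SD sigma, baseline
      mean mu, phenotype shift beta_p.
    - ``W``: per cell type, samples x factors DataFrame of unwanted factors.
    - ``ld_realized``: realized dosage r^2 per configured LD pair.
    """

    pair_effects: pd.DataFrame
    gene_info: pd.DataFrame
    W: dict
    ld_realized: pd.DataFrame

    def beta_g(self, snp_id: str, gene_id: str) -> float:
        rows = self.pair_effects
        hit = rows[(rows.snp_id == snp_id) & (rows.gene_id == gene_id)]
        return float(hit.beta_g.iloc[0]) if len(hit) else 0.0

    def causal_snps(self, gene_id: str) -> list[str]:
        rows = self.pair_effects
        return list(rows.loc[(rows.gene_id == gene_id) & (rows.beta_g != 0), "snp_id"])

    def validate(self) -> None:
        ctl = set(self.gene_info.index[self.gene_info.control])
        if len(self.pair_effects) and self.pair_effects.gene_id.isin(ctl).any():
            raise AssertionError("control gene carries a planted pair effect")
        if (self.gene_info.loc[self.gene_info.control, "beta_p"] != 0).any():
            raise AssertionError("control gene carries a phenotype effect")


@dataclass
class Cohort:
    genotypes: GenotypeTable
    expression: dict  # cell_type -> ExpressionSet
    truth: TruthTable
    config: CohortConfig

    @property
    def samples(self) -> pd.DataFrame:
        frames = [es.samples for es in self.expression.values()]
        return pd.concat(frames).loc[lambda d: ~d.index.duplicated()]


def _flip_rate(target_r2: float) -> float:
    """Flip probability f with (1 - 2f)^2 = r^2 for the haplotype-copy LD model."""
    return 0.5 * (1.0 - np.sqrt(target_r2))


def simulate_genotypes(config: CohortConfig) -> GenotypeTable:
    """Draw a risk-SNP panel under HWE with configured LD pairs.

    Base SNPs: two independent Bernoulli(MAF) haplotypes per sample (hence
    HWE). A derived SNP j in an LD pair (i, j, r2) copies SNP i's haplotypes
    and flips each independently with probability f = (1 - sqrt(r2))/2, so
    the expected haplotype correlation is 1 - 2f = sqrt(r2). Loci are placed
    2 Mb apart on synthetic chromosomes (20 per chromosome) so distinct
    loci's cis windows never overlap; LD partners sit within 40 kb of their
    base SNP. Missing calls are masked at ``config.missing_rate``; the
    complete matrix is retained on the returned table for expression
    generation.
    """
    rng = np.random.default_rng([_GENO, config.seed])
    n, m = config.n_samples, config.n_snps
    derived = {j: (i, r2) for i, j, r2 in config.ld_pairs}

    mafs = rng.uniform(*config.maf_range, size=m)
    haps = np.zeros((n, 2, m), dtype=np.int8)
    for s in range(m):
        if s not in derived:
            haps[:, :, s] = rng.random((n, 2)) < mafs[s]
    for j, (i, r2) in derived.items():
        flips = rng.random((n, 2)) < _flip_rate(r2)
        haps[:, :, j] = haps[:, :, i] ^ flips
        mafs[j] = mafs[i]
    dosage = haps.sum(axis=1).astype(float)

    # positions: base SNPs claim successive loci; derived SNPs share the locus
    chroms, poss = [], []
    locus = 0
    base_pos: dict[int, tuple[str, int]] = {}
    for s in range(m):
        if s in derived:
            chroms.append(None)
            poss.append(None)
            continue
        chrom = f"chr{1 + locus // _LOCI_PER_CHROM}"
        pos = _FIRST_LOCUS + (locus % _LOCI_PER_CHROM) * _LOCUS_SPACING
        base_pos[s] = (chrom, pos)
        chroms.append(chrom)
        poss.append(pos)
        locus += 1
    for j, (i, _) in derived.items():
        chrom, pos = base_pos[i]
        chroms[j] = chrom
        poss[j] = pos + int(rng.integers(1, _LD_PARTNER_OFFSET))

    alleles = np.array(["A", "C", "G", "T"])
    ref = alleles[rng.integers(0, 4, size=m)]
    alt = np.array([alleles[(list(alleles).index(r) + 1 + rng.integers(0, 3)) % 4] for r in ref])

    snp_ids = [f"snp_{s:04d}" for s in range(m)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    complete = pd.DataFrame(dosage, index=sample_ids, columns=snp_ids)
    observed = complete.copy()
    if config.missing_rate > 0:
        mask = rng.random(observed.shape) < config.missing_rate
        observed = observed.mask(mask)
    snps = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "risk_allele": alt, "other_allele": ref},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    table = GenotypeTable(observed, snps)
    table.complete_dosage = complete  # pre-missingness matrix for the generator
    return table


def annotate_genes(genotypes: GenotypeTable, config: CohortConfig) -> pd.DataFrame:
    """Deterministic gene annotation for a cohort configuration.

    Non-control genes are split into cis genes — each anchored within
    +-450 kb of a uniformly chosen panel SNP — and background genes placed
    midway between SNP loci (>= 500 kb from every SNP). Housekeeping
    control genes live on a separate chromosome carrying no SNPs. Columns:
    chrom, tss, strand, control, anchor_snp.
    """
    rng = np.random.default_rng([_GENES, config.seed])
    n_ctl = config.n_controls_genes
    n_free = config.n_genes - n_ctl
    n_cis = int(round(config.cis_fraction * n_free))
    snp_ids = genotypes.snp_ids
    rows = []
    for g in range(config.n_genes):
        gene_id = f"gene_{g:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if g < n_cis:
            anchor = snp_ids[int(rng.integers(0, len(snp_ids)))]
            meta = genotypes.snps.loc[anchor]
            tss = int(meta.pos) + int(rng.integers(-_CIS_OFFSET, _CIS_OFFSET + 1))
            rows.append((gene_id, meta.chrom, max(tss, 1), strand, False, anchor))
        elif g < n_free:
            chrom = f"chr{1 + int(rng.integers(0, max(1, (len(snp_ids) // _LOCI_PER_CHROM) + 1)))}"
            slot = int(rng.integers(0, _LOCI_PER_CHROM))
            tss = _FIRST_LOCUS + _LOCUS_SPACING * slot + _LOCUS_SPACING // 2 + int(
                rng.integers(-300_000, 300_000)
            )
            rows.append((gene_id, chrom, tss, strand, False, None))
        else:
            rows.append((gene_id, "chrHK", 10_000 * (g - n_free + 1), strand, True, None))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "strand", "control", "anchor_snp"]
    ).set_index("gene_id")
    return genes


def _default_pair_effects(genes: pd.DataFrame, config: CohortConfig, rng) -> pd.DataFrame:
    """Random planting: a fraction of cis genes get a beta_G on their anchor
    SNP (cycling the effect grid), further cis genes carry the configured
    interaction pairs, and further genes the phenotype shifts."""
    cis_genes = list(genes.index[genes.anchor_snp.notna()])
    rows = []
    pheno: dict[str, float] = {}
    pool = list(rng.permutation(cis_genes))
    n_eff = int(round(config.effect_fraction * len(cis_genes))) if config.effect_grid else 0
    for idx in range(min(n_eff, len(pool))):
        gene = pool.pop()
        beta = config.effect_grid[idx % len(config.effect_grid)]
        rows.append((genes.loc[gene, "anchor_snp"], gene, beta, 0.0))
    for entry in config.interaction_effects:
        if not pool:
            raise ValueError("not enough cis genes for interaction effects")
        gene = pool.pop()
        beta_g, beta_gp = entry if isinstance(entry, (tuple, list)) else (0.0, float(entry))
        rows.append((genes.loc[gene, "anchor_snp"], gene, float(beta_g), float(beta_gp)))
    for beta_p in config.phenotype_effects:
        if not pool:
            raise ValueError("not enough cis genes for phenotype effects")
        pheno[pool.pop()] = float(beta_p)
    effects = pd.DataFrame(rows, columns=["snp_id", "gene_id", "beta_g", "beta_gp"])
    effects["beta_p"] = 0.0
    for gene, beta_p in pheno.items():
        effects.loc[len(effects)] = [None, gene, 0.0, 0.0, beta_p]
    return effects


def _check_cis(effects: pd.DataFrame, genes: pd.DataFrame, genotypes: GenotypeTable,
               window: int = 500_000) -> None:
    for _, row in effects.iterrows():
        if row.snp_id is None or (isinstance(row.snp_id, float) and np.isnan(row.snp_id)):
            continue
        if row.beta_g == 0 and row.beta_gp == 0:
            continue
        meta = genotypes.snps.loc[row.snp_id]
        gene = genes.loc[row.gene_id]
        if gene.chrom != meta.chrom or abs(int(gene.tss) - int(meta.pos)) > window:
            raise ValueError(
                f"effect assigned to a non-cis pair: {row.snp_id} x {row.gene_id}"
            )


def simulate_expression(
    genotypes: GenotypeTable,
    config: CohortConfig,
    effects: pd.DataFrame | None = None,
) -> tuple[dict, TruthTable]:
    """Generate per-cell-type log2 expression and the matching truth table.

    The generative model per gene g and sample s is

        Y[g, s] = mu_g + sum_pairs G[s] beta_G + G[s] P[s] beta_GP
                  + P[s] beta_P + W[s, :] alpha[:, g] + eps,   eps ~ N(0, sigma_g^2)

    Control genes receive unwanted-factor loadings alpha but no beta of any
    kind. One W column correlates with the phenotype indicator at
    ``config.uv_confounding``. An explicit ``effects`` DataFrame (columns
    snp_id, gene_id, beta_g, beta_gp, beta_p) overrides the default random
    planting; effects on pairs outside the 500 kb cis window are rejected.
    """
    rng_eff = np.random.default_rng([_EFFECTS, config.seed])
    genes = annotate_genes(genotypes, config)
    if effects is None:
        effects = _default_pair_effects(genes, config, rng_eff)
    else:
        effects = effects.copy()
        for col, default in (("beta_g", 0.0), ("beta_gp", 0.0), ("beta_p", 0.0)):
            if col not in effects:
                effects[col] = default
    ctl_set = set(genes.index[genes.control])
    if effects.gene_id.isin(ctl_set).any():
        raise ValueError("effects may not target negative-control genes")
    _check_cis(effects, genes, genotypes)

    # per-gene nuisance parameters shared across cell types
    m_genes = config.n_genes
    sigma = rng_eff.uniform(*config.noise_sd_range, size=m_genes)
    mu = rng_eff.uniform(4.0, 12.0, size=m_genes)
    gene_ids = list(genes.index)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    dosage = getattr(genotypes, "complete_dosage", None)
    if dosage is None:
        dosage = genotypes.dosage.fillna(genotypes.dosage.mean())
    all_samples = list(dosage.index)

    k = config.n_uv_factors
    strengths = [config.uv_strengths[f % len(config.uv_strengths)] for f in range(k)]

    beta_p_gene = np.zeros(m_genes)
    for _, row in effects.iterrows():
        if row.beta_p != 0:
            beta_p_gene[gene_pos[row.gene_id]] += row.beta_p

    expression: dict[str, ExpressionSet] = {}
    W_by_cell: dict[str, pd.DataFrame] = {}
    for ct_idx, cell_type in enumerate(config.cell_types):
        rng = np.random.default_rng([_EXPR, config.seed, ct_idx])
        n_case, n_ctrl = config.counts_for(cell_type)
        case_ids = all_samples[:n_case]
        n_total_cases = config.n_cases
        ctrl_ids = all_samples[n_total_cases:n_total_cases + n_ctrl]
        samp_ids = case_ids + ctrl_ids
        n_s = len(samp_ids)
        P = np.array([1.0] * n_case + [0.0] * n_ctrl)
        G = dosage.loc[samp_ids].to_numpy()

        W = np.zeros((n_s, k))
        for f in range(k):
            if f == 0 and k >= 2:
                W[:, f] = (rng.random(n_s) < 0.5).astype(float)
                W[:, f] = (W[:, f] - W[:, f].mean()) / max(W[:, f].std(), 1e-12)
            elif f == k - 1 and config.uv_confounding > 0:
                p_std = (P - P.mean()) / max(P.std(), 1e-12)
                c = config.uv_confounding
                W[:, f] = c * p_std + np.sqrt(1 - c * c) * rng.normal(size=n_s)
            else:
                W[:, f] = rng.normal(size=n_s)
        alpha = np.column_stack(
            [rng.normal(scale=strengths[f], size=m_genes) for f in range(k)]
        ).T if k else np.zeros((0, m_genes))

        Y = np.tile(mu, (n_s, 1)) + P[:, None] * beta_p_gene[None, :]
        snp_col = {s: i for i, s in enumerate(dosage.columns)}
        for _, row in effects.iterrows():
            if row.snp_id is None or (isinstance(row.snp_id, float) and np.isnan(row.snp_id)):
                continue
            g = G[:, snp_col[row.snp_id]]
            j = gene_pos[row.gene_id]
            Y[:, j] += g * row.beta_g + g * P * row.beta_gp
        if k:
            Y += W @ alpha
        Y += rng.normal(size=(n_s, m_genes)) * sigma[None, :]

        samples = pd.DataFrame(
            {
                "phenotype": ["case"] * n_case + ["control"] * n_ctrl,
                "cell_type": cell_type,
            },
            index=pd.Index(samp_ids, name="sample_id"),
        )
        expression[cell_type] = ExpressionSet(
            values=pd.DataFrame(Y.T, index=gene_ids, columns=samp_ids),
            genes=genes[["chrom", "tss", "strand"]].copy(),
            controls=genes["control"].copy(),
            samples=samples,
            cell_type=cell_type,
        )
        W_by_cell[cell_type] = pd.DataFrame(
            W, index=samp_ids, columns=[f"W{f+1}" for f in range(k)]
        )

    hc_cut = float(np.quantile(np.abs(config.effect_grid), 0.5)) if config.effect_grid else 0.0
    pair_rows = effects[(effects.beta_g != 0) | (effects.beta_gp != 0)].copy()
    pair_rows["high_confidence"] = pair_rows.beta_g.abs() >= max(hc_cut, 0.4)
    ld_rows = []
    comp = getattr(genotypes, "complete_dosage", genotypes.dosage)
    for i, j, r2 in config.ld_pairs:
        si, sj = comp.columns[i], comp.columns[j]
        ld_rows.append((si, sj, r2, dosage_r2(comp[si], comp[sj])))
    truth = TruthTable(
        pair_effects=pair_rows[["snp_id", "gene_id", "beta_g", "beta_gp", "high_confidence"]]
        .reset_index(drop=True),
        gene_info=pd.DataFrame(
            {"control": genes.control.to_numpy(), "sigma": sigma, "mu": mu,
             "beta_p": beta_p_gene},
            index=genes.index,
        ),
        W=W_by_cell,
        ld_realized=pd.DataFrame(
            ld_rows, columns=["snp_i", "snp_j", "target_r2", "realized_r2"]
        ),
    )
    truth.validate()
    return expression, truth


def simulate_cohort(config: CohortConfig, effects: pd.DataFrame | None = None) -> Cohort:
    """Genotypes + expression + truth in one call."""
    genotypes = simulate_genotypes(config)
    expression, truth = simulate_expression(genotypes, config, effects=effects)
    return Cohort(genotypes=genotypes, expression=expression, truth=truth, config=config)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write a cohort to disk in the package's exchange formats.

    Emits ``genotypes.vcf`` (GT calls, risk allele = ALT), one
    ``expression_<cell>.tsv`` per cell type (genes x samples), ``genes.tsv``
    (chrom, tss, strand, gene_id), ``samples.tsv``, ``controls.txt`` and the
    truth tables. Returns a manifest of paths. Round-trips losslessly
    through :mod:`mseqtl.io` readers.
    """
    from . import io as _io

    return _io.write_cohort(cohort, out_dir)
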