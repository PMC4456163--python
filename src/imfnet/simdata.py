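"""Synthetic study generator.

Emulates the statistical structure of an extreme-GEBV two-group RNA-seq
design: a polygenic trait on a few hundred genotyped animals, selection of
the k highest- and k lowest-GEBV animals, and a two-group count matrix with
a minority of differentially expressed genes and latent regulators whose
coupling to their target modules differs between the groups (differential
wiring).  Every stage is seeded hierarchically from one integer so the whole
bundle is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import gblup
from .gblup import GenotypeMatrix


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated design at desk scale: heritability 0.29 on
    200 animals x 1000 SNPs, 7 high / 7 low GEBV extremes, 2000 genes with a
    3% DE minority, and regulators coupled to 20-gene target modules at 0.9
    in the high group versus 0.2 in the low group.
    """

    n_animals: int = 200
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_true: float = 0.29
    n_qtl: int = 100
    group_size: int = 7
    n_genes: int = 2000
    n_de: int = 60
    lfc_scale: float = 2.0
    n_regulators: int = 2
    module_size: int = 20
    coupling_high: float = 0.9
    coupling_low: float = 0.2
    dispersion: float = 0.05
    mean_library_size: float = 2e7
    gene_length_range: tuple[float, float] = (500.0, 5000.0)
    seed: int = 1
    # generative details (see docs/methods.md)
    de_target_frac: float = 1.0      # fraction of each module drawn from the DE set
    signal_sd: float = 2.0           # log2 amplitude of regulator-activity effects
    regulator_noise_sd: float = 0.1  # log2 measurement noise on regulator transcripts
    # Baseline log2 mean counts per kb: N(8.5, 1.5) puts the median gene near
    # 1e3 reads and ~20 FPKM at a 2e7-read library, matching a ~40x-coverage
    # muscle transcriptome, so the log2(FPKM+1) offset stays negligible.
    base_logmean: tuple[float, float] = (8.5, 1.5)
    trait_mean: float = 3.0          # IMF-like percentage scale
    trait_var: float = 0.686         # total of genetic + residual variance

    def __post_init__(self):
        for name in ("n_animals", "n_snps", "n_qtl", "group_size", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.h2_true <= 1:
            raise ValueError("h2_true must lie in [0, 1]")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.n_regulators * self.module_size + self.n_regulators > self.n_genes:
            raise ValueError("regulators plus their modules exceed the gene universe")
        if 2 * self.group_size > self.n_animals:
            raise ValueError("2 * group_size cannot exceed n_animals")
        for name in ("coupling_high", "coupling_low"):
            c = getattr(self, name)
            if not 0 <= c < 1:
                raise ValueError(f"{name} must lie in [0, 1): correlation degenerates at 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.de_target_frac <= 1:
            raise ValueError("de_target_frac must lie in [0, 1]")

    def spawn_seeds(self) -> dict[str, np.random.SeedSequence]:
        """Named per-stage sub-seeds from the single study seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("genotypes", "trait", "expression", "extra"), children))


@dataclass
class SimTruth:
    true_breeding_values: dict[str, float]
    de_gene_ids: list[str]
    de_signs: dict[str, int]
    planted_regulator_ids: list[str]
    regulator_targets: dict[str, list[str]]
    group_assignment: dict[str, str]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TraitSim:
    phenotypes: pd.DataFrame  # columns: trait, fixed_class, covariate
    breeding_values: np.ndarray
    residuals: np.ndarray


@dataclass
class ExpressionSim:
    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series  # per-sample sequencing depth (total mapped reads)
    de_gene_ids: list[str]
    de_signs: dict[str, int]
    regulator_ids: list[str]
    regulator_targets: dict[str, list[str]]
    activities: pd.DataFrame  # regulators x samples latent activity


@dataclass
class StudyBundle:
    config: SimConfig
    genotypes: GenotypeMatrix
    trait: TraitSim
    fit: gblup.GblupFit
    extremes: gblup.ExtremeGroups
    groups: pd.Series  # sample -> {high, low}
    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series
    truth: SimTruth


def simulate_genotypes(n_animals: int, n_snps: int, maf_range=(0.05, 0.5), seed=None) -> GenotypeMatrix:
    """Independent HWE genotypes: p_j ~ U(maf_range), dosage ~ Binomial(2, p_j)."""
    if n_animals <= 0 or n_snps <= 0:
        raise ValueError("empty genotype dimensions")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, p, size=(n_animals, n_snps)).astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        animal_ids=[f"animal_{i + 1:04d}" for i in range(n_animals)],
        snp_ids=[f"snp_{j + 1:05d}" for j in range(n_snps)],
    )


def simulate_trait(
    geno: GenotypeMatrix,
    h2_true: float,
    n_qtl: int,
    seed=None,
    mean: float = 3.0,
    var_total: float = 0.686,
    include_fixed: bool = True,
) -> TraitSim:
    """Polygenic trait y = mean (+ fixed effects) + u + e.

    u = W_qtl @ alpha with alpha ~ Normal, rescaled so the sample variance of
    u is exactly h2_true * var_total; e ~ Normal(0, (1 - h2_true) * var_total)
    left unscaled (its realised variance carries Monte-Carlo noise).  Optional
    fixed effects: a 4-level contemporary-group class and a carcass-weight
    covariate.
    """
    if not 0 <= h2_true <= 1:
        raise ValueError("h2_true must lie in [0, 1]")
    n, m = geno.dosages.shape
    if not 1 <= n_qtl <= m:
        raise ValueError("n_qtl must lie in [1, n_snps]")
    rng = _rng(seed)
    qtl = rng.choice(m, size=n_qtl, replace=False)
    Wq = geno.dosages[:, qtl].astype(float)
    Wq -= Wq.mean(axis=0)
    alpha = rng.normal(size=n_qtl)
    u = Wq @ alpha
    var_u = u.var()
    if h2_true > 0:
        if var_u == 0:
            raise ValueError("all QTL monomorphic: no genetic variance with h2_true > 0")
        u *= np.sqrt(h2_true * var_total / var_u)
    else:
        u = np.zeros(n)
    e = rng.normal(0.0, np.sqrt((1 - h2_true) * var_total), size=n) if h2_true < 1 else np.zeros(n)

    classes = rng.integers(0, 4, size=n)
    class_effects = np.array([0.0, 0.25, -0.2, 0.1])
    covariate = rng.normal(280.0, 25.0, size=n)
    fixed_part = class_effects[classes] + 0.004 * (covariate - 280.0) if include_fixed else 0.0
    y = mean + fixed_part + u + e
    phen = pd.DataFrame(
        {
            "trait": y,
            "fixed_class": [f"cg{c + 1}" for c in classes],
            "covariate": covariate,
        },
        index=pd.Index(geno.animal_ids, name="animal_id"),
    )
    return TraitSim(phenotypes=phen, breeding_values=u, residuals=e)


def simulate_expression(config: SimConfig, group_assignment: pd.Series, seed=None) -> ExpressionSim:
    """Two-group NB counts with planted DE genes and differentially wired modules.

    Per gene, a baseline log2 mean is drawn; DE genes get a half-shift of
    +/- lfc_scale/2 per group; each regulator has a latent per-sample
    activity a_rs ~ N(0, 1) and its targets receive
    signal_sd * (c_g * a_rs + sqrt(1 - c_g^2) * eta) in group g, so
    regulator-target correlations scale with c_g and target-target
    correlations with c_g^2 while total signal variance stays constant.
    Counts are NB with mean 2^log2mean * (length/1kb) * depth and dispersion
    alpha (Poisson at alpha = 0).  Module targets are drawn from the DE set
    first (``de_target_frac``), since regulator scoring operates on
    regulator-DE correlations.

    The emitted per-sample library sizes are the true sequencing depths
    (Poisson around ``mean_library_size``).  Use them — not column totals of
    the emitted matrix — as FPKM denominators: real total-mapped-read counts
    are dominated by the rest of the transcriptome, which the generator does
    not emit, so subset column totals would inject a shared normalisation
    factor that does not exist at genome scale.
    """
    groups = pd.Series(group_assignment)
    labels = set(groups.unique())
    if labels != {"high", "low"}:
        raise ValueError(f"group assignment must use labels 'high'/'low', got {sorted(labels)}")
    rng = _rng(seed if seed is not None else config.spawn_seeds()["expression"])
    n_g, n_s = config.n_genes, len(groups)
    genes = [f"gene_{i + 1:05d}" for i in range(n_g)]
    samples = list(groups.index)
    is_high = (groups == "high").to_numpy()

    loc, sd = config.base_logmean
    base = rng.normal(loc, sd, size=n_g)
    lengths = rng.uniform(*config.gene_length_range, size=n_g).round()
    lib = rng.poisson(config.mean_library_size, size=n_s)
    depth = lib / config.mean_library_size

    # planted roles: regulators, their target modules, DE genes
    perm = rng.permutation(n_g)
    reg_idx = perm[: config.n_regulators]
    # Regulators are emitted as well-expressed transcripts: their measured
    # profile must track the latent activity with only small noise, and
    # low-abundance counts would add Poisson noise and log-offset
    # compression that break that premise mechanically.
    base[reg_idx] = loc + 1.5 * sd + rng.normal(0.0, sd / 3.0, size=len(reg_idx))
    pool = perm[config.n_regulators:]
    n_de_targets = int(round(config.de_target_frac * config.module_size))
    de_idx = list(pool[: config.n_de])
    non_de_pool = list(pool[config.n_de:])
    targets: dict[int, list[int]] = {}
    de_cursor = 0
    nd_cursor = 0
    for r in reg_idx:
        take_de = min(n_de_targets, config.n_de - de_cursor)
        mod = de_idx[de_cursor: de_cursor + take_de]
        de_cursor += take_de
        need = config.module_size - len(mod)
        mod += non_de_pool[nd_cursor: nd_cursor + need]
        nd_cursor += need
        if len(mod) < config.module_size:
            raise ValueError("gene universe too small for the requested modules")
        targets[r] = mod

    # DE directions: random per gene, except that the DE targets of one
    # regulator share a common direction — a regulator pushes its module
    # coherently, and mixed-sign modules would cancel in PIF-weighted
    # regulator scores by construction rather than by biology.
    signs = np.where(rng.random(config.n_de) < 0.5, 1, -1)
    de_pos = {gi: j for j, gi in enumerate(de_idx)}
    for r in reg_idx:
        module_sign = 1 if rng.random() < 0.5 else -1
        for gi in targets[r]:
            if gi in de_pos:
                signs[de_pos[gi]] = module_sign
    x = np.tile(base[:, None], (1, n_s))
    half = config.lfc_scale / 2.0
    for j, gi in enumerate(de_idx):
        x[gi, is_high] += signs[j] * half
        x[gi, ~is_high] -= signs[j] * half

    coupling = np.where(is_high, config.coupling_high, config.coupling_low)
    # Latent activities are standardised within each group so the realised
    # per-group spread is exactly 1: coupling_g then sets the within-group
    # correlation scale on every draw, not just in expectation (a raw 7-draw
    # normal sample can easily realise half the nominal spread and wash the
    # planted wiring out).
    activities = rng.normal(size=(config.n_regulators, n_s))
    for g_mask in (is_high, ~is_high):
        sub = activities[:, g_mask]
        sd_g = sub.std(axis=1, keepdims=True)
        sd_g[sd_g == 0] = 1.0
        activities[:, g_mask] = (sub - sub.mean(axis=1, keepdims=True)) / sd_g
    for k, r in enumerate(reg_idx):
        a = activities[k]
        x[r] += config.signal_sd * a + config.regulator_noise_sd * rng.normal(size=n_s)
        for gi in targets[r]:
            eta = rng.normal(size=n_s)
            x[gi] += config.signal_sd * (coupling * a + np.sqrt(1 - coupling**2) * eta)

    mu = (2.0 ** x) * (lengths[:, None] / 1000.0) * depth[None, :]
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    gene_index = pd.Index(genes, name="gene_id")
    return ExpressionSim(
        counts=pd.DataFrame(counts, index=gene_index, columns=samples),
        gene_lengths=pd.Series(lengths, index=gene_index, name="length"),
        library_sizes=pd.Series(lib.astype(float), index=samples, name="library_size"),
        de_gene_ids=[genes[i] for i in de_idx],
        de_signs={genes[gi]: int(signs[j]) for j, gi in enumerate(de_idx)},
        regulator_ids=[genes[i] for i in reg_idx],
        regulator_targets={genes[r]: [genes[i] for i in mod] for r, mod in targets.items()},
        activities=pd.DataFrame(activities, index=[genes[i] for i in reg_idx], columns=samples),
    )


def fixed_design(phenotypes: pd.DataFrame) -> np.ndarray:
    """Intercept + contemporary-group dummies + covariate design matrix."""
    classes = pd.get_dummies(phenotypes["fixed_class"], drop_first=True).to_numpy(dtype=float)
    cov = phenotypes["covariate"].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(phenotypes)), classes, cov - cov.mean()])


def generate_study(config: SimConfig) -> StudyBundle:
    """Simulate the full design: population, GBLUP, extremes, expression."""
    seeds = config.spawn_seeds()
    geno = simulate_genotypes(config.n_animals, config.n_snps, config.maf_range, seeds["genotypes"])
    trait = simulate_trait(
        geno, config.h2_true, config.n_qtl, seeds["trait"],
        mean=config.trait_mean, var_total=config.trait_var,
    )
    G = gblup.vanraden_g(geno)
    spec = gblup.MixedModelSpec(
        response=trait.phenotypes["trait"].to_numpy(),
        fixed_design=fixed_design(trait.phenotypes),
        relationship=G,
    )
    varcomps = gblup.em_reml(spec)
    fit = gblup.solve_mme(spec, varcomps)
    extremes = gblup.select_extremes(fit.gebv, config.group_size, geno.animal_ids)
    groups = pd.Series(
        {**{a: "high" for a in extremes.high_ids}, **{a: "low" for a in extremes.low_ids}},
        name="group",
    )
    groups = groups.loc[extremes.high_ids + extremes.low_ids]
    groups.index.name = "sample_id"
    expr = simulate_expression(config, groups, seeds["expression"])
    truth = SimTruth(
        true_breeding_values=dict(zip(geno.animal_ids, trait.breeding_values.tolist())),
        de_gene_ids=expr.de_gene_ids,
        de_signs=expr.de_signs,
        planted_regulator_ids=expr.regulator_ids,
        regulator_targets=expr.regulator_targets,
        group_assignment=groups.to_dict(),
    )
    return StudyBundle(
        config=config,
        genotypes=geno,
        trait=trait,
        fit=fit,
        extremes=extremes,
        groups=groups,
        counts=expr.counts,
        gene_lengths=expr.gene_lengths,
        library_sizes=expr.library_sizes,
        truth=truth,
    )
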