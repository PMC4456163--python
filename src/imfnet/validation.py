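"""Seeded simulation studies that validate the pipeline's statistical claims.

Three canned experiments, shared by the test suite and the acceptance
script: EM-REML heritability recovery, type-I error of the NB exact test
under a global null, and recovery of a planted differentially wired
regulator by differential hubbing and RIF1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import diffexpr, gblup, impact, pcit, simdata


def reml_recovery(
    h2_values=(0.1, 0.29, 0.5),
    n_replicates: int = 50,
    n_animals: int = 500,
    n_snps: int = 2000,
    base_seed: int = 1,
) -> pd.DataFrame:
    """EM-REML heritability estimates across simulated replicates.

    Returns one row per (h2_true, replicate) with the estimate; summarise
    with ``groupby('h2_true')['h2_hat'].mean()``.
    """
    rows = []
    ss = np.random.SeedSequence(base_seed)
    for h2 in h2_values:
        for rep, child in enumerate(ss.spawn(n_replicates)):
            g_seed, t_seed = child.spawn(2)
            geno = simdata.simulate_genotypes(n_animals, n_snps, seed=g_seed)
            trait = simdata.simulate_trait(geno, h2, n_qtl=100, seed=t_seed)
            spec = gblup.MixedModelSpec(
                response=trait.phenotypes["trait"].to_numpy(),
                fixed_design=simdata.fixed_design(trait.phenotypes),
                relationship=gblup.vanraden_g(geno),
            )
            vc = gblup.em_reml(spec)
            rows.append({"h2_true": h2, "replicate": rep,
                         "h2_hat": gblup.heritability(vc)})
    return pd.DataFrame(rows)


def null_type_i_error(
    n_replicates: int = 20,
    n_genes: int = 2000,
    n_per_group: int = 7,
    alpha_true: float = 0.05,
    level: float = 0.05,
    base_seed: int = 1,
) -> pd.DataFrame:
    """Fraction of raw exact-test p-values below ``level`` with no true DE.

    Counts are NB with a lognormal mean profile and common dispersion; the
    full estimation path (filter, size factors, dispersion trend, exact
    test) is rerun per replicate.
    """
    samples = [f"s{j}" for j in range(2 * n_per_group)]
    groups = pd.Series(["high"] * n_per_group + ["low"] * n_per_group, index=samples)
    rows = []
    for rep, child in enumerate(np.random.SeedSequence(base_seed).spawn(n_replicates)):
        rng = np.random.default_rng(child)
        mu = 2.0 ** rng.normal(6.0, 1.5, size=n_genes)
        mean = np.tile(mu[:, None], (1, len(samples)))
        if alpha_true > 0:
            lam = rng.gamma(1 / alpha_true, mean * alpha_true)
        else:
            lam = mean
        counts = pd.DataFrame(rng.poisson(lam),
                              index=[f"g{i}" for i in range(n_genes)], columns=samples)
        counts = diffexpr.filter_counts(counts)
        sf = diffexpr.size_factors(counts)
        disp = diffexpr.estimate_dispersions(counts, sf)
        p = diffexpr.nbinom_exact_test(counts, sf, disp, groups)
        rows.append({"replicate": rep, "n_genes": len(counts),
                     "frac_p_below": float((p.to_numpy() < level).mean())})
    return pd.DataFrame(rows)


def regulator_recovery(
    n_seeds: int = 20,
    base_seed: int = 1,
    top_frac: float = 0.05,
    **config_overrides,
) -> pd.DataFrame:
    """Recovery of one planted differentially wired regulator, per seed.

    Study conditions: 200 genes, one regulator with a 20-gene module coupled
    at 0.9 in the high group and 0.0 in the low group, 7 vs 7 samples
    (overridable).  Per seed the full expression pipeline runs — filtering,
    exact-test DE at FDR 0.10, per-group PCIT networks at |r| >= 0.90, DH
    and RIF — and two outcomes are scored: does the regulator attain the
    maximum DH, and does it rank in the top ``top_frac`` of candidates by
    |RIF1 z-score|.
    """
    defaults = dict(n_genes=200, n_de=30, n_regulators=1, module_size=20,
                    coupling_high=0.9, coupling_low=0.0)
    defaults.update(config_overrides)
    rows = []
    for rep, child in enumerate(np.random.SeedSequence(base_seed).spawn(n_seeds)):
        cfg = simdata.SimConfig(seed=int(child.generate_state(1)[0] % (2**31)), **defaults)
        samples = [f"s{j}" for j in range(2 * cfg.group_size)]
        groups = pd.Series(["high"] * cfg.group_size + ["low"] * cfg.group_size,
                           index=samples)
        expr_sim = simdata.simulate_expression(cfg, groups, seed=child)
        reg = expr_sim.regulator_ids[0]

        counts = diffexpr.filter_counts(expr_sim.counts)
        de_res = diffexpr.run_de(counts, groups, fdr=0.10)
        de_ids = list(de_res.index[de_res["de"]])
        logexpr = pcit.log_transform(pcit.fpkm(counts, expr_sim.gene_lengths.reindex(counts.index),
                                               library_sizes=expr_sim.library_sizes))
        nets = {
            label: pcit.group_network(
                logexpr.values[groups.index[groups == label]], r_min=0.90, group=label)
            for label in ("high", "low")
        }
        dh = impact.differential_hubbing(nets["high"], nets["low"])
        max_dh = bool(reg in dh.index and dh.loc[reg, "dh"] == dh["dh"].max())

        candidates = impact.candidate_regulators(nets["high"], nets["low"])
        top_rif = False
        if de_ids and reg in candidates:
            expr_h = logexpr.values[groups.index[groups == "high"]]
            expr_l = logexpr.values[groups.index[groups == "low"]]
            rif = impact.rif_scores(expr_h, expr_l, de_ids, candidates)
            rank = rif["rif1_z"].abs().rank(ascending=False, method="min")
            cutoff = max(1, int(np.ceil(top_frac * len(rif))))
            top_rif = bool(rank.loc[reg] <= cutoff)
        rows.append({"replicate": rep, "n_de_detected": len(de_ids),
                     "n_candidates": len(candidates),
                     "dh_regulator": int(dh.loc[reg, "dh"]) if reg in dh.index else 0,
                     "dh_max": int(dh["dh"].max()),
                     "max_dh": max_dh, "top_rif1": top_rif,
                     "recovered": max_dh and top_rif})
    return pd.DataFrame(rows)
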