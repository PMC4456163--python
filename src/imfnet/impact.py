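"""Differential hubbing and regulator impact scores.

DH_i is the difference in a transcript's number of significant network
connections between the two condition networks.  PIF_i = abar_i * d_i with
abar the average and d the difference of the two group-mean (log) expressions.
RIF1 weighs a candidate regulator's squared change in correlation to each DE
gene by that gene's PIF (differential wiring); RIF2 contrasts the squared
product of DE-gene expression and regulator-gene correlation between the
conditions (predictive ability).  RIF scores are reported raw and z-scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pcit import CorrelationNetwork


def differential_hubbing(
    net_high: CorrelationNetwork,
    net_low: CorrelationNetwork,
    union: bool = False,
    sign: str = "high_minus_low",
) -> pd.DataFrame:
    """Per-gene degree in each network and their difference.

    By default requires both networks to share one gene universe; pass
    ``union=True`` to take the union instead.  ``sign`` picks the DH
    convention (``high_minus_low`` or ``low_minus_high``).
    """
    if sign not in ("high_minus_low", "low_minus_high"):
        raise ValueError(f"unknown sign convention {sign!r}")
    uni_h, uni_l = set(net_high.gene_universe), set(net_low.gene_universe)
    if uni_h != uni_l and not union:
        raise ValueError("networks cover different gene universes; pass union=True")
    genes = sorted(uni_h | uni_l)
    k_h = net_high.degrees.reindex(genes).fillna(0).astype(int)
    k_l = net_low.degrees.reindex(genes).fillna(0).astype(int)
    dh = k_h - k_l if sign == "high_minus_low" else k_l - k_h
    return pd.DataFrame({"k_high": k_h, "k_low": k_l, "dh": dh}, index=pd.Index(genes, name="gene"))


def top_dh(dh_table: pd.DataFrame, k: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The k most positively and k most negatively DH transcripts.

    Ties are broken by gene id (ascending) so the ranking is deterministic.
    """
    if dh_table.empty:
        raise ValueError("empty DH table")
    df = dh_table.reset_index(names="gene") if "gene" not in dh_table.columns else dh_table.copy()
    pos = df.sort_values(["dh", "gene"], ascending=[False, True]).head(k).set_index("gene")
    neg = df.sort_values(["dh", "gene"], ascending=[True, True]).head(k).set_index("gene")
    return pos, neg


def _group_means(expr_high: pd.DataFrame, expr_low: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    if not expr_high.index.equals(expr_low.index):
        missing = expr_high.index.symmetric_difference(expr_low.index)
        raise ValueError(f"genes absent from one group: {list(missing[:5])}")
    return expr_high.mean(axis=1), expr_low.mean(axis=1)


def pif_scores(expr_high: pd.DataFrame, expr_low: pd.DataFrame) -> pd.DataFrame:
    """PIF_i = abar_i * d_i on group-mean expression (genes x samples inputs).

    abar_i = (e_iH + e_iL)/2, d_i = e_iH - e_iL.  Antisymmetric under group
    swap.
    """
    if expr_high.shape[1] < 2 or expr_low.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    mean_h, mean_l = _group_means(expr_high, expr_low)
    abar = (mean_h + mean_l) / 2.0
    d = mean_h - mean_l
    return pd.DataFrame({"abar": abar, "d": d, "pif": abar * d})


def candidate_regulators(net_high: CorrelationNetwork, net_low: CorrelationNetwork) -> list[str]:
    """Transcripts with at least one significant edge in either group network."""
    ids = set(net_high.degrees.index[net_high.degrees > 0])
    ids |= set(net_low.degrees.index[net_low.degrees > 0])
    return sorted(ids)


def _corr_to_targets(expr: pd.DataFrame, cand: list[str], de: list[str]) -> np.ndarray:
    """Candidate x DE-gene Pearson correlations within one group.

    Constant genes (zero variance) correlate 0 with everything, flagged by a
    warning.
    """
    n = expr.shape[1]
    arr = expr.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    n_const = int((sd == 0).sum())
    if n_const:
        warnings.warn(f"{n_const} constant genes in one group: correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mu) / sd
    z[~np.isfinite(z)] = 0.0
    zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    return (zdf.loc[cand].to_numpy() @ zdf.loc[de].to_numpy().T) / (n - 1)


def rif_scores(
    expr_high: pd.DataFrame,
    expr_low: pd.DataFrame,
    de_gene_ids,
    candidates,
) -> pd.DataFrame:
    """RIF1/RIF2 for candidate regulators against the DE gene set.

    RIF1_i = mean_j PIF_j * (r_ijH - r_ijL)^2
    RIF2_i = mean_j [(e_jH * r_ijH)^2 - (e_jL * r_ijL)^2]

    with j running over DE genes (a candidate that is itself DE skips its
    self-pair; the mean is over the pairs actually summed) and correlations
    computed within each group across its samples.  Returns abar/d/pif of the
    candidate itself plus raw and z-scored RIF1/RIF2.
    """
    de = [g for g in de_gene_ids if g in expr_high.index]
    cand = [g for g in candidates if g in expr_high.index]
    if len(de) == 0:
        raise ValueError("need at least one DE gene")
    if len(cand) == 0:
        raise ValueError("need at least one candidate regulator")
    mean_h, mean_l = _group_means(expr_high, expr_low)
    pif_all = pif_scores(expr_high, expr_low)

    r_h = _corr_to_targets(expr_high, cand, de)
    r_l = _corr_to_targets(expr_low, cand, de)

    pif_de = pif_all.loc[de, "pif"].to_numpy()
    e_h = mean_h.loc[de].to_numpy()
    e_l = mean_l.loc[de].to_numpy()

    term1 = pif_de[None, :] * (r_h - r_l) ** 2
    term2 = (e_h[None, :] * r_h) ** 2 - (e_l[None, :] * r_l) ** 2

    include = np.ones((len(cand), len(de)), dtype=bool)
    de_pos = {g: j for j, g in enumerate(de)}
    for i, g in enumerate(cand):
        j = de_pos.get(g)
        if j is not None:
            include[i, j] = False
    denom = include.sum(axis=1)
    if (denom == 0).any():
        raise ValueError("a candidate has no non-self DE gene to score against")
    rif1 = np.where(include, term1, 0.0).sum(axis=1) / denom
    rif2 = np.where(include, term2, 0.0).sum(axis=1) / denom

    out = pd.DataFrame(
        {
            "abar": pif_all.loc[cand, "abar"],
            "d": pif_all.loc[cand, "d"],
            "pif": pif_all.loc[cand, "pif"],
            "rif1_raw": rif1,
            "rif2_raw": rif2,
        },
        index=pd.Index(cand, name="gene"),
    )
    for col in ("rif1", "rif2"):
        raw = out[f"{col}_raw"].to_numpy()
        out[f"{col}_z"] = zscore(raw) if len(raw) > 1 and raw.std(ddof=1) > 0 else 0.0
    return out


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, sd 1 (sample sd, n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread: cannot z-score a constant vector")
    return (v - v.mean()) / sd


def top_pif(pif: pd.Series, k: int = 3000, use_abs: bool = False) -> list[str]:
    """Ids of the k genes with the largest (signed, or absolute) PIF.

    Sorted descending by score, ties by gene id.
    """
    score = pif.abs() if use_abs else pif
    df = pd.DataFrame({"score": score, "gene": score.index})
    df = df.sort_values(["score", "gene"], ascending=[False, True])
    return df["gene"].head(k).tolist()
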