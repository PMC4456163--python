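"""Two-group differential expression for RNA-seq counts.

Count filtering (three rules), median-of-ratios size factors, method-of-moments
negative-binomial dispersions with a mean-dispersion trend, the conditioned
NB exact test on group sums, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# Outcomes of the exact test are enumerated directly up to this total count;
# beyond it the enumeration window is restricted to outcomes whose
# probability is non-negligible relative to the mode (tail mass bound
# asserted < 1e-10).
ENUMERATION_CAP = 100_000
_TAIL_Q = 1e-18


@dataclass
class DispersionModel:
    """Per-gene NB dispersions alpha (variance = mu + alpha mu^2).

    ``final`` is either the gene-wise estimate, the fitted trend
    a0 + a1/mu, or their maximum, depending on the sharing mode.
    """

    raw: np.ndarray
    a0: float
    a1: float
    final: np.ndarray
    base_means: np.ndarray

    def fitted(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            f = self.a0 + self.a1 / mu
        return np.clip(np.where(mu > 0, f, 0.0), 0.0, None)


def _as_count_frame(counts) -> pd.DataFrame:
    df = pd.DataFrame(counts)
    arr = df.to_numpy()
    if arr.size and (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return df


def filter_counts(counts: pd.DataFrame, min_mean: float = 1.0, min_present: int = 3) -> pd.DataFrame:
    """Drop unexpressed, very lowly expressed and rarely expressed genes.

    Keeps genes with (i) a nonzero total, (ii) an average of at least
    ``min_mean`` reads per sample (strictly-less-than removal), and
    (iii) a nonzero count in at least ``min_present`` samples.
    Row order is preserved; the operation is idempotent.
    """
    df = _as_count_frame(counts)
    if df.empty:
        return df
    arr = df.to_numpy()
    total = arr.sum(axis=1)
    mean = arr.mean(axis=1)
    present = (arr > 0).sum(axis=1)
    keep = (total > 0) & (mean >= min_mean) & (present >= min_present)
    return df.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation.

    s_j = median over genes of k_ij / geometric-mean_i; only genes with
    all-positive counts contribute to the reference.
    """
    df = _as_count_frame(counts)
    arr = df.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with all-positive counts; cannot form the reference")
    logs = np.log(arr[allpos])
    log_gm = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_gm[:, None], axis=0))
    return pd.Series(sf, index=df.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    sharing: str = "fit-only",
) -> DispersionModel:
    """Method-of-moments dispersions on normalised counts, with a trend fit.

    Gene-wise: alpha_i = max(0, (var_i - mu_i * mean_j 1/s_j) / mu_i^2) on
    z_ij = k_ij / s_j.  The trend alpha(mu) = a0 + a1/mu is fit by least
    squares over genes with positive mean.  ``sharing``:

    - ``"fit-only"``: final alpha = fitted trend at the gene's mean
      (gene-wise noise at these sample sizes is large; the trend keeps the
      test close to its nominal level);
    - ``"maximum"``: final alpha = max(gene-wise, fitted) — conservative.
    """
    df = _as_count_frame(counts)
    sf = sf.reindex(df.columns)
    z = df.to_numpy(dtype=float) / sf.to_numpy()
    mu = z.mean(axis=1)
    if df.shape[1] < 2 or np.all(z.std(axis=1) == 0):
        raise ValueError("cannot estimate dispersions: no variation")
    var = z.var(axis=1, ddof=1)
    xi = float(np.mean(1.0 / sf.to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_unfloored = np.where(mu > 0, (var - mu * xi) / mu**2, 0.0)
    raw = np.clip(raw_unfloored, 0.0, None)

    ok = mu > 0
    if ok.sum() >= 2:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(A, raw_unfloored[ok], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0, a1 = float(raw.mean()), 0.0

    model = DispersionModel(raw=raw, a0=a0, a1=a1, final=raw.copy(), base_means=mu)
    fitted = model.fitted(mu)
    if sharing == "fit-only":
        model.final = fitted
    elif sharing == "maximum":
        model.final = np.maximum(raw, fitted)
    else:
        raise ValueError(f"unknown sharing mode {sharing!r}")
    return model


def _nb_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """NB (or Poisson when var <= mean) log-pmf parametrised by moments."""
    if var > mean:
        size = mean**2 / (var - mean)
        prob = size / (size + mean)
        return stats.nbinom.logpmf(k, size, prob)
    return stats.poisson.logpmf(k, mean)


def _group_sum_moments(q0: float, sf_group: np.ndarray, alpha: float):
    """Moments of the group's count sum under the null common mean q0."""
    mean = q0 * sf_group.sum()
    var = q0 * sf_group.sum() + alpha * q0**2 * np.sum(sf_group**2)
    return mean, var


def _exact_window(mean_a, var_a, mean_b, var_b, k_s):
    """Outcome range for group-A's sum when full enumeration is too large."""
    def rng(mean, var):
        if var > mean:
            size = mean**2 / (var - mean)
            prob = size / (size + mean)
            lo = stats.nbinom.ppf(_TAIL_Q, size, prob)
            hi = stats.nbinom.isf(_TAIL_Q, size, prob)
        else:
            lo = stats.poisson.ppf(_TAIL_Q, mean)
            hi = stats.poisson.isf(_TAIL_Q, mean)
        return float(lo), float(hi)

    lo_a, hi_a = rng(mean_a, var_a)
    lo_b, hi_b = rng(mean_b, var_b)
    lo = int(max(0, min(lo_a, k_s - hi_b)))
    hi = int(min(k_s, max(hi_a, k_s - lo_b)))
    return lo, hi


def nbinom_exact_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    disp: DispersionModel,
    group_labels: pd.Series,
) -> pd.Series:
    """Conditional NB exact test on the two group sums, per gene.

    Under the null, both groups share the per-sample mean q0 (the pooled mean
    of normalised counts).  Each group's sum is modelled as NB with mean
    q0 * sum(s_j) and variance q0 * sum(s_j) + alpha * q0^2 * sum(s_j^2).
    The two-sided p-value sums P(a)P(k_S - a) over all splits a of the
    conditioning total k_S whose probability does not exceed the observed
    one, normalised by the total over all splits.  k_S = 0 gives p = 1.
    """
    df = _as_count_frame(counts)
    groups = pd.Series(group_labels).reindex(df.columns)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    mask_a = (groups == labels[0]).to_numpy()
    sf_arr = sf.reindex(df.columns).to_numpy(dtype=float)
    sf_a, sf_b = sf_arr[mask_a], sf_arr[~mask_a]
    arr = df.to_numpy(dtype=float)

    pvals = np.ones(arr.shape[0])
    for i in range(arr.shape[0]):
        k_a = float(arr[i, mask_a].sum())
        k_b = float(arr[i, ~mask_a].sum())
        k_s = int(round(k_a + k_b))
        if k_s == 0:
            continue
        q0 = float(np.mean(arr[i] / sf_arr))
        alpha = float(disp.final[i])
        mean_a, var_a = _group_sum_moments(q0, sf_a, alpha)
        mean_b, var_b = _group_sum_moments(q0, sf_b, alpha)
        if k_s <= ENUMERATION_CAP:
            a = np.arange(k_s + 1)
        else:
            lo, hi = _exact_window(mean_a, var_a, mean_b, var_b, k_s)
            a = np.arange(lo, hi + 1)
        logp = _nb_logpmf(a, mean_a, var_a) + _nb_logpmf(k_s - a, mean_b, var_b)
        mode = logp.max()
        w = np.exp(logp - mode)
        total = w.sum()
        if k_s > ENUMERATION_CAP:
            # symmetric truncation bound: edge terms must be negligible
            edge = max(w[0], w[-1])
            assert edge * k_s / total < 1e-10, "exact-test truncation bound exceeded"
        obs = np.exp(
            _nb_logpmf(np.array([k_a]), mean_a, var_a)[0]
            + _nb_logpmf(np.array([k_b]), mean_b, var_b)[0]
            - mode
        )
        keep = w <= obs * (1 + 1e-7)
        pvals[i] = min(1.0, float(w[keep].sum() / total))
    return pd.Series(pvals, index=df.index, name="pval")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: pd.DataFrame,
    group_labels: pd.Series,
    fdr: float = 0.10,
    high_label: str = "high",
    low_label: str = "low",
    sharing: str = "fit-only",
) -> pd.DataFrame:
    """Full DE analysis on an already-filtered count matrix.

    Returns one row per gene: baseMean, meanHigh, meanLow (normalised scale),
    foldChange = meanHigh / meanLow (NaN for 0/0, inf for x/0), log2FC, pval,
    padj and the DE flag padj <= fdr.
    """
    df = _as_count_frame(counts)
    groups = pd.Series(group_labels).reindex(df.columns)
    sf = size_factors(df)
    disp = estimate_dispersions(df, sf, sharing=sharing)
    pvals = nbinom_exact_test(df, sf, disp, groups)
    padj = bh_adjust(pvals.to_numpy())

    z = df.to_numpy(dtype=float) / sf.to_numpy()
    mask_h = (groups == high_label).to_numpy()
    mask_l = (groups == low_label).to_numpy()
    if not mask_h.any() or not mask_l.any():
        raise ValueError(f"need samples labelled {high_label!r} and {low_label!r}")
    mean_h = z[:, mask_h].mean(axis=1)
    mean_l = z[:, mask_l].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_h / mean_l
        log2fc = np.log2(fc)
    n_inf = int(np.isinf(fc).sum())
    if n_inf:
        warnings.warn(f"{n_inf} genes have infinite fold change (zero low-group mean)")
    return pd.DataFrame(
        {
            "baseMean": z.mean(axis=1),
            "meanHigh": mean_h,
            "meanLow": mean_l,
            "foldChange": fc,
            "log2FC": log2fc,
            "pval": pvals.to_numpy(),
            "padj": padj,
            "de": padj <= fdr,
        },
        index=df.index,
    )
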