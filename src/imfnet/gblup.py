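"""Genomic BLUP: VanRaden relationship matrix, EM-REML variance components,
mixed-model equations, extreme-GEBV group selection and the group t-test.

The animal model is ``y = Xb + Zu + e`` with ``Var(u) = G sigma2_m`` and
``Var(e) = I sigma2_e``, where ``G`` is the genomic relationship matrix built
from allele-frequency-centred SNP dosages.  Heritability is
``sigma2_m / (sigma2_m + sigma2_e)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


class ConvergenceError(RuntimeError):
    """EM-REML failed to converge; ``last`` carries the last iterate."""

    def __init__(self, msg: str, last: "VarianceComponents"):
        super().__init__(msg)
        self.last = last


@dataclass
class GenotypeMatrix:
    """Animals x SNPs allele-dosage codes in {0, 1, 2}."""

    dosages: np.ndarray
    animal_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (animals x SNPs)")
        n, m = self.dosages.shape
        if n == 0 or m == 0:
            raise ValueError("empty genotype matrix")
        if len(self.animal_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id lists inconsistent with dosage dimensions")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosage codes must be 0, 1 or 2 (no missing values)")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class Gmatrix:
    values: np.ndarray
    denominator: float


@dataclass
class MixedModelSpec:
    """y = Xb + Zu + e.  ``relationship=None`` means Var(u) proportional to I."""

    response: np.ndarray
    fixed_design: np.ndarray
    random_design: np.ndarray | None = None
    relationship: Gmatrix | None = None

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.fixed_design = np.atleast_2d(np.asarray(self.fixed_design, dtype=float))
        n = self.response.size
        if self.fixed_design.shape[0] != n:
            raise ValueError("fixed_design row count disagrees with response length")
        if np.linalg.matrix_rank(self.fixed_design) < self.fixed_design.shape[1]:
            raise ValueError("fixed_design is rank deficient; drop redundant columns")
        if self.random_design is not None:
            self.random_design = np.asarray(self.random_design, dtype=float)
            if self.random_design.shape[0] != n:
                raise ValueError("random_design row count disagrees with response")

    @property
    def n(self) -> int:
        return self.response.size

    def z_matrix(self) -> np.ndarray:
        if self.random_design is not None:
            return self.random_design
        return np.eye(self.n)

    def k_matrix(self) -> np.ndarray:
        """Covariance structure of Zu (up to sigma2_m): Z G Z'."""
        Z = self.z_matrix()
        if self.relationship is None:
            return Z @ Z.T
        return Z @ self.relationship.values @ Z.T


@dataclass
class VarianceComponents:
    sigma2_m: float
    sigma2_e: float

    def __post_init__(self):
        if self.sigma2_m < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if self.sigma2_m == 0 and self.sigma2_e == 0:
            raise ValueError("variance components cannot both be zero")


@dataclass
class GblupFit:
    fixed_effects: np.ndarray
    gebv: np.ndarray
    varcomps: VarianceComponents
    heritability: float


@dataclass
class ExtremeGroups:
    high_ids: list[str]
    low_ids: list[str]
    k: int


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP allele frequency p_j = mean dosage / 2."""
    if geno.n_animals == 0:
        raise ValueError("no animals")
    return geno.dosages.mean(axis=0) / 2.0


def vanraden_g(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> Gmatrix:
    """G = WW' / (2 sum p_j (1 - p_j)) with W the dosages centred at 2p_j."""
    if freqs is None:
        freqs = allele_frequencies(geno)
    freqs = np.asarray(freqs, dtype=float)
    denom = float(2.0 * np.sum(freqs * (1.0 - freqs)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    W = geno.dosages.astype(float) - 2.0 * freqs
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return Gmatrix(values=G, denominator=denom)


def heritability(varcomps: VarianceComponents) -> float:
    """h2 = sigma2_m / (sigma2_m + sigma2_e)."""
    total = varcomps.sigma2_m + varcomps.sigma2_e
    if total <= 0:
        raise ValueError("total variance is zero")
    return varcomps.sigma2_m / total


def _reml_quantities(d, ytil, Xtil, s2m, s2e):
    """Score ingredients in the eigenbasis of K = U diag(d) U'.

    Returns y'PKPy, y'PPy, tr(PK), tr(P) where P is the REML projection
    of V = s2m*K + s2e*I against the fixed design.
    """
    w = s2m * d + s2e
    Xw = Xtil / w[:, None]
    XtVX = Xtil.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ ytil)
    Py = ytil / w - Xw @ beta  # = P y in rotated coordinates
    yPKPy = float(np.sum(d * Py**2))
    yPPy = float(np.sum(Py**2))

    def tr_P_times(diag_mult):
        trV = float(np.sum(diag_mult / w))
        M = Xtil.T @ (Xtil * (diag_mult / w**2)[:, None])
        return trV - float(np.trace(np.linalg.solve(XtVX, M)))

    return yPKPy, yPPy, tr_P_times(d), tr_P_times(np.ones_like(d))


def em_reml(
    spec: MixedModelSpec,
    init: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 20000,
) -> VarianceComponents:
    """Estimate (sigma2_m, sigma2_e) by EM-REML.

    Expectation-maximisation updates on the restricted likelihood,
    sigma2_i <- sigma2_i + sigma2_i^2 (y'P V_i P y - tr(P V_i)) / n,
    computed in the eigenbasis of K = Z G Z' so each iteration is O(n p).
    The fixed point solves the REML score equations.  Components are floored
    at a small positive fraction of Var(y) (boundary estimates converge to
    the floor rather than crossing zero).  Convergence is declared when the
    per-iteration change in both components, scaled by Var(y), drops below
    ``tol`` (EM steps shrink geometrically near a zero boundary, so a
    component-relative criterion would never trigger there).
    """
    y = spec.response
    n, p = spec.n, spec.fixed_design.shape[1]
    if n <= p:
        raise ValueError("need more records than fixed-effect parameters")
    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("response has zero variance")
    if init is None:
        init = (vary / 2.0, vary / 2.0)
    if init[0] <= 0 or init[1] <= 0:
        raise ValueError("initial components must be positive")

    K = spec.k_matrix()
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    d = np.clip(d, 0.0, None)
    ytil = U.T @ y
    Xtil = U.T @ spec.fixed_design

    floor = 1e-8 * vary
    s2m, s2e = float(init[0]), float(init[1])
    for _ in range(max_iter):
        yPKPy, yPPy, trPK, trP = _reml_quantities(d, ytil, Xtil, s2m, s2e)
        s2m_new = max(floor, s2m + s2m**2 * (yPKPy - trPK) / n)
        s2e_new = max(floor, s2e + s2e**2 * (yPPy - trP) / n)
        delta = max(abs(s2m_new - s2m), abs(s2e_new - s2e)) / vary
        s2m, s2e = s2m_new, s2e_new
        if delta < tol:
            return VarianceComponents(sigma2_m=s2m, sigma2_e=s2e)
    raise ConvergenceError(
        f"EM-REML did not converge in {max_iter} iterations",
        VarianceComponents(sigma2_m=s2m, sigma2_e=s2e),
    )


def solve_mme(
    spec: MixedModelSpec,
    varcomps: VarianceComponents,
    g_stabilizer: float = 0.01,
) -> GblupFit:
    """Solve Henderson's mixed-model equations for b and u.

    lambda = sigma2_e / sigma2_m; G^-1 * lambda is added to the random block.
    When a genomic relationship is supplied, ``g_stabilizer`` is added to its
    diagonal before inversion (G from markers is often near-singular); an
    identity relationship is used as-is.
    """
    if varcomps.sigma2_m <= 0:
        raise ValueError("sigma2_m must be positive to solve the MME")
    lam = varcomps.sigma2_e / varcomps.sigma2_m
    y = spec.response
    X = spec.fixed_design
    Z = spec.z_matrix()
    q = Z.shape[1]
    if spec.relationship is None:
        Kinv = np.eye(q)
    else:
        G = spec.relationship.values
        if G.shape != (q, q):
            raise ValueError("relationship dimension disagrees with random design")
        try:
            Kinv = np.linalg.inv(G + g_stabilizer * np.eye(q))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
            raise ValueError("relationship matrix singular after stabilization") from exc

    p = X.shape[1]
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + Kinv * lam]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular MME coefficient matrix") from exc
    b, u = sol[:p], sol[p:]
    return GblupFit(
        fixed_effects=b,
        gebv=u,
        varcomps=varcomps,
        heritability=heritability(varcomps),
    )


def select_extremes(
    gebv: Sequence[float],
    k: int,
    animal_ids: Sequence[str] | None = None,
) -> ExtremeGroups:
    """k animals with the largest and k with the smallest GEBV.

    Ties are broken by stable (GEBV, animal id) order; a tie straddling
    either cut emits a warning.
    """
    gebv = np.asarray(gebv, dtype=float)
    n = gebv.size
    if animal_ids is None:
        animal_ids = [str(i) for i in range(n)]
    animal_ids = list(animal_ids)
    if len(animal_ids) != n:
        raise ValueError("animal_ids length disagrees with gebv")
    if 2 * k > n:
        raise ValueError(f"cannot select 2x{k} animals from {n}")
    order = sorted(range(n), key=lambda i: (gebv[i], animal_ids[i]))
    low = [animal_ids[i] for i in order[:k]]
    high = [animal_ids[i] for i in order[-k:]][::-1]  # most extreme first
    if k < n and gebv[order[k - 1]] == gebv[order[k]]:
        warnings.warn("tie in GEBV straddles the low-group cut", stacklevel=2)
    if k < n and gebv[order[n - k]] == gebv[order[n - k - 1]]:
        warnings.warn("tie in GEBV straddles the high-group cut", stacklevel=2)
    return ExtremeGroups(high_ids=high, low_ids=low, k=k)


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]):
    """Welch's unequal-variance two-sided t-test (the R ``t.test`` default).

    Returns (t, df, p) for the contrast A - B.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
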