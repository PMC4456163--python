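"""Per-group co-expression networks.

FPKM normalisation, log transform, Pearson correlations, first-order partial
correlations, the PCIT trio-elimination algorithm, and network construction
with an absolute-correlation floor (default |r| >= 0.90).

PCIT keeps an edge (x, y) unless some third gene z dominates it: with the
three first-order partial correlations of the trio and the local tolerance
eps = mean(partial/direct over the trio), the edge is eliminated when
|r_xy| < |eps * r_xz| and |r_xy| < |eps * r_yz|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

#: |r| is clipped here before entering partial-correlation denominators.
CLIP = 0.999999

#: Gene-count cap for the O(n^3) trio scan; raise explicitly if you mean it.
DEFAULT_MAX_GENES = 5000


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with a scale tag (``fpkm`` or ``log2fpkm1``)."""

    values: pd.DataFrame
    scale: str

    def __post_init__(self):
        if self.scale not in ("fpkm", "log2fpkm1"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")


@dataclass
class CorrelationNetwork:
    group: str
    edges: pd.DataFrame  # columns: gene_a, gene_b, r
    degrees: pd.Series
    gene_universe: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """FPKM_ij = k_ij * 1e9 / (L_i * N_j).

    ``library_sizes`` defaults to the column totals of ``counts``.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = pd.Series(library_sizes).reindex(counts.columns)
    if lib.isna().any() or (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    vals = counts.to_numpy(dtype=float) * 1e9
    vals /= lengths.to_numpy()[:, None]
    vals /= lib.to_numpy()[None, :]
    return ExpressionMatrix(values=pd.DataFrame(vals, index=counts.index, columns=counts.columns), scale="fpkm")


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """v -> log2(v + 1), tagging the result ``log2fpkm1``."""
    if expr.scale != "fpkm":
        raise ValueError("log_transform expects an fpkm-scale matrix")
    vals = expr.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative expression values")
    return ExpressionMatrix(values=np.log2(expr.values + 1.0), scale="log2fpkm1")


def pearson_matrix(values: pd.DataFrame | np.ndarray):
    """Gene x gene Pearson correlations across samples.

    Returns (R, constant_mask).  Genes with zero variance get r = 0 against
    everything (flagged in the mask) and 1 on the diagonal.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    sd = arr.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(arr)
    R = np.atleast_2d(R)
    R[np.isnan(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    return R, constant


def partial_correlation(r_xy, r_xz, r_yz):
    """First-order partial correlation r_xy.z."""
    r_xy, r_xz, r_yz = (np.asarray(v, dtype=float) for v in (r_xy, r_xz, r_yz))
    if np.any(np.abs(r_xz) >= 1) or np.any(np.abs(r_yz) >= 1):
        raise ValueError("degenerate conditioning: |r| = 1 with the third gene")
    out = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    return out if out.ndim else float(out)


@njit(cache=True)
def _pcit_scan(R, clip):  # pragma: no cover - exercised via pcit_edges
    n = R.shape[0]
    sig = np.ones((n, n), dtype=np.bool_)
    s = np.empty((n, n))
    c = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            v = R[i, j]
            if v > clip:
                v = clip
            elif v < -clip:
                v = -clip
            c[i, j] = v
            s[i, j] = 1.0 / np.sqrt(1.0 - v * v)
    for x in range(n - 2):
        for y in range(x + 1, n - 1):
            rxy = R[x, y]
            cxy = c[x, y]
            for z in range(y + 1, n):
                rxz = R[x, z]
                ryz = R[y, z]
                if rxy == 0.0 or rxz == 0.0 or ryz == 0.0:
                    continue  # tolerance ratio undefined: trio abstains
                cxz = c[x, z]
                cyz = c[y, z]
                pxy = (cxy - cxz * cyz) * s[x, z] * s[y, z]
                pxz = (cxz - cxy * cyz) * s[x, y] * s[y, z]
                pyz = (cyz - cxy * cxz) * s[x, y] * s[x, z]
                eps = (pxy / cxy + pxz / cxz + pyz / cyz) / 3.0
                ae = abs(eps)
                axy, axz, ayz = abs(rxy), abs(rxz), abs(ryz)
                if axy < ae * axz and axy < ae * ayz:
                    sig[x, y] = False
                    sig[y, x] = False
                if axz < ae * axy and axz < ae * ayz:
                    sig[x, z] = False
                    sig[z, x] = False
                if ayz < ae * axy and ayz < ae * axz:
                    sig[y, z] = False
                    sig[z, y] = False
    return sig


def pcit_edges(corr_matrix: np.ndarray) -> np.ndarray:
    """Boolean significance mask over gene pairs after PCIT trio elimination.

    An edge is significant iff no trio eliminates it.  With fewer than 3
    genes every edge is significant.  The diagonal is False.
    """
    R = np.asarray(corr_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    n = R.shape[0]
    if n < 3:
        mask = np.ones((n, n), dtype=bool)
    else:
        mask = np.asarray(_pcit_scan(np.ascontiguousarray(R), CLIP))
    np.fill_diagonal(mask, False)
    return mask


def group_network(
    expr_group: pd.DataFrame,
    r_min: float = 0.90,
    group: str = "",
    max_genes: int = DEFAULT_MAX_GENES,
) -> CorrelationNetwork:
    """PCIT-significant edges with absolute direct correlation >= r_min.

    ``expr_group`` is genes x samples for one group (at least 3 samples).
    Degrees cover the full gene universe (zero for unconnected genes).
    """
    if expr_group.shape[0] > max_genes:
        raise ValueError(
            f"{expr_group.shape[0]} genes exceeds the cap of {max_genes}; "
            "raise max_genes explicitly if intended"
        )
    genes = list(expr_group.index)
    R, _ = pearson_matrix(expr_group)
    mask = pcit_edges(R)
    mask &= np.abs(R) >= r_min
    iu, ju = np.triu_indices(len(genes), k=1)
    hit = mask[iu, ju]
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[hit]],
            "gene_b": [genes[j] for j in ju[hit]],
            "r": R[iu[hit], ju[hit]],
        }
    )
    deg = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    if len(edges):
        counts = pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts()
        deg.loc[counts.index] = counts.astype(int)
    return CorrelationNetwork(group=group, edges=edges, degrees=deg, gene_universe=genes)
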