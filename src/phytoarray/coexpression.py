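"""Weighted correlation-network module detection (topological overlap).

Genes with highly correlated expression across the T24 samples are grouped
into modules: an unsigned adjacency ``a_ij = |cor(x_i, x_j)|^beta`` is
raised to a soft power chosen for approximate scale-free topology, the
adjacency is transformed to the topological overlap measure (TOM), and
modules are cut from an average-linkage tree on the TOM dissimilarity.
Each module is summarized by its eigengene, the first principal component
of the standardized member submatrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


@dataclass
class ModuleAssignment:
    labels: pd.Series                     # gene -> module (0 = unassigned)
    beta: int
    scale_free_r2: float
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})


def drop_constant_rows(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        log.warning("dropping %d constant gene rows before correlation",
                    int((~keep).sum()))
    return expr.loc[keep]


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned weighted adjacency |cor|^beta over gene rows."""
    r = np.corrcoef(expr.to_numpy())
    np.fill_diagonal(r, 1.0)
    return np.abs(np.clip(r, -1, 1)) ** beta


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over binned connectivity.

    Positive only when the fit slope is negative (frequency decreasing in
    connectivity), as scale-free topology requires; otherwise 0.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins) / len(k)
    dk = np.array([k[which == b].mean() if (which == b).any() else np.nan
                   for b in range(n_bins)])
    ok = (freq > 0) & np.isfinite(dk) & (dk > 0)
    if ok.sum() < 3:
        return 0.0
    x, y = np.log10(dk[ok]), np.log10(freq[ok])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    r2 = 1 - (resid ** 2).sum() / ss_tot
    return float(r2) if slope < 0 else 0.0


def pick_soft_power(expr: pd.DataFrame, candidates=range(1, 21),
                    target_r2: float = 0.8) -> tuple[int, float]:
    """Smallest candidate soft power with scale-free fit R^2 >= target.

    Falls back (with a warning) to the power with the best fit when none
    reaches the target.
    """
    if expr.shape[1] < 8:
        raise ValueError("need >= 8 samples for a stable correlation network")
    expr = drop_constant_rows(expr)
    r = np.abs(np.clip(np.corrcoef(expr.to_numpy()), -1, 1))
    np.fill_diagonal(r, 0.0)
    best_beta, best_r2 = None, -np.inf
    for beta in candidates:
        k = (r ** beta).sum(axis=1)
        r2 = scale_free_fit(k)
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
        if r2 >= target_r2:
            log.info("soft power %d reaches scale-free R^2 %.3f", beta, r2)
            return int(beta), float(r2)
    log.warning("no candidate power reached R^2 %.2f; using beta=%d "
                "(R^2=%.3f)", target_r2, best_beta, best_r2)
    return int(best_beta), float(best_r2)


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with k_i the connectivity excluding the diagonal; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    shared = a @ a - 2.0 * a  # sum over u != i,j of a_iu a_uj (diag = 1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 1.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cut_modules(tom: np.ndarray, genes: pd.Index, min_module_size: int = 10,
                cut_height_frac: float = 0.92) -> pd.Series:
    """Static cut of the average-linkage tree on TOM dissimilarity.

    Clusters below ``min_module_size`` are unassigned (label 0). Module
    labels are 1..K ordered by decreasing size.
    """
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    height = cut_height_frac * z[:, 2].max()
    raw = hierarchy.fcluster(z, t=height, criterion="distance")
    labels = pd.Series(0, index=genes, dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_label = 1
    for cluster_id, size in sizes.items():
        if size >= min_module_size:
            labels[raw == cluster_id] = next_label
            next_label += 1
    log.info("modules: %d assigned across %d modules (%d genes unassigned)",
             int((labels > 0).sum()), next_label - 1,
             int((labels == 0).sum()))
    return labels


def module_eigengene(expr: pd.DataFrame, members: pd.Index) -> pd.Series:
    """First principal component across samples of the member submatrix.

    Member genes are standardized first; the eigengene has unit norm and
    its sign is fixed so it correlates positively with the module's mean
    expression profile.
    """
    block = expr.loc[members].to_numpy(dtype=float)
    mu = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (block - mu) / sd
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = expr.loc[members].mean(axis=0).to_numpy()
    centered = mean_profile - mean_profile.mean()
    if float(eig @ centered) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns)


def detect_modules(expr_t24: pd.DataFrame, min_module_size: int = 10,
                   target_r2: float = 0.8, cut_height_frac: float = 0.92
                   ) -> ModuleAssignment:
    """Full pipeline: soft power -> adjacency -> TOM -> cut -> eigengenes."""
    expr_t24 = drop_constant_rows(expr_t24)
    beta, r2 = pick_soft_power(expr_t24, target_r2=target_r2)
    tom = compute_tom(adjacency_matrix(expr_t24, beta))
    labels = cut_modules(tom, expr_t24.index,
                         min_module_size=min_module_size,
                         cut_height_frac=cut_height_frac)
    eigs = {}
    for mod in sorted(set(labels) - {0}):
        members = labels.index[labels == mod]
        eigs[f"ME{mod}"] = module_eigengene(expr_t24, members)
    eigengenes = pd.DataFrame(eigs)
    return ModuleAssignment(labels=labels, beta=beta, scale_free_r2=r2,
                            eigengenes=eigengenes)
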