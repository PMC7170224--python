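"""Euclidean distances, non-metric MDS, and group-distance summaries.

Samples are compared by the Euclidean distance between their log2
transcript profiles over the detected-gene universe. NMDS follows
Kruskal's formulation: coordinates are updated by SMACOF majorization
against disparities obtained by monotone (isotonic) regression of the
embedded distances on the rank order of the input dissimilarities, and
the reported badness-of-fit is stress-1,

    stress = sqrt( sum (dhat_ij - d_ij)^2 / sum d_ij^2 ).

The best of several seeded random starts (plus one classical-scaling
start) is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .design import SampleSheet
from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)


def euclidean_distances(expr: ExpressionMatrix,
                        gene_universe: pd.Index | None = None
                        ) -> pd.DataFrame:
    """Pairwise sample distances over log2 levels of detected genes.

    The universe defaults to targets detected in at least one sample;
    undetected cells contribute their normalized background value rather
    than being masked.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    if gene_universe is None:
        gene_universe = expr.values.index[expr.detected.any(axis=1)]
    block = expr.values.loc[gene_universe]
    d = squareform(pdist(block.T.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=block.columns, columns=block.columns)


def monotone_regression(values, order: np.ndarray | None = None
                        ) -> np.ndarray:
    """Least-squares non-decreasing fit (pool adjacent violators).

    ``order`` gives the target ordering (indices into ``values``); the
    fitted values are returned in the original positions.
    """
    values = np.asarray(values, dtype=float)
    if order is None:
        order = np.arange(len(values))
    fitted = isotonic_regression(values[order], increasing=True).x
    out = np.empty_like(values)
    out[order] = fitted
    return out


def _stress1(dhat: np.ndarray, d: np.ndarray) -> float:
    denom = float((d ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - d) ** 2).sum() / denom))


def _guttman_update(x: np.ndarray, dhat_sq: np.ndarray) -> np.ndarray:
    """One SMACOF majorization step toward disparities ``dhat_sq``."""
    n = x.shape[0]
    d = squareform(pdist(x))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat_sq / d, 0.0)
    b = -ratio
    np.fill_diagonal(b, 0.0)
    np.fill_diagonal(b, -b.sum(axis=1))
    return (b @ x) / n


def _kruskal_run(diss: np.ndarray, x0: np.ndarray, max_iter: int,
                 tol: float) -> tuple[np.ndarray, float, list[float]]:
    """Alternate isotonic disparities and majorization from one start."""
    n = x0.shape[0]
    iu = np.triu_indices(n, 1)
    # ties broken by current embedded distance = Kruskal's primary approach
    x = x0.copy()
    stress_path: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        d = pdist(x)
        order = np.lexsort((d, diss))
        dhat = monotone_regression(d, order)
        ssd = float((d ** 2).sum())
        ssh = float((dhat ** 2).sum())
        if ssh > 0:
            dhat = dhat * np.sqrt(ssd / ssh)
        stress = _stress1(dhat, d)
        stress_path.append(stress)
        if prev - stress < tol:
            break
        prev = stress
        x = _guttman_update(x, squareform(dhat))
        x -= x.mean(axis=0)
    return x, stress_path[-1], stress_path


def _classical_init(diss_sq: np.ndarray, dim: int) -> np.ndarray:
    n = diss_sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (diss_sq ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dim]
    lam = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(lam)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    best_start: int          # -1 = classical-scaling start
    converged: bool
    stress_path: list[float]


def nmds(d: pd.DataFrame, dim: int = 2, restarts: int = 20,
         seed: int = 0, max_iter: int = 500, tol: float = 1e-6
         ) -> OrdinationResult:
    """Non-metric MDS of a symmetric distance matrix, best of many starts."""
    dm = d.to_numpy(dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = dm.shape[0]
    diss = dm[np.triu_indices(n, 1)]
    rng = np.random.default_rng(seed)
    scale = diss.max() or 1.0
    starts: list[tuple[int, np.ndarray]] = [(-1, _classical_init(dm, dim))]
    for i in range(restarts):
        starts.append((i, rng.normal(0.0, scale / 2.0, (n, dim))))
    best = None
    for start_id, x0 in starts:
        x, stress, path = _kruskal_run(diss, x0, max_iter, tol)
        if best is None or stress < best[1] - 1e-15:
            best = (x, stress, path, start_id)
    x, stress, path, start_id = best
    converged = len(path) < max_iter
    if not converged:
        log.warning("NMDS did not converge in %d iterations (best start)",
                    max_iter)
    coords = pd.DataFrame(x, index=d.index,
                          columns=[f"NMDS{k + 1}" for k in range(dim)])
    log.info("NMDS stress-1 = %.4f (best of %d starts)", stress,
             len(starts))
    return OrdinationResult(coordinates=coords, stress=stress,
                            n_restarts=restarts, best_start=start_id,
                            converged=converged, stress_path=path)


def group_distance_summary(d: pd.DataFrame, sheet: SampleSheet,
                           reference: tuple[str, str] = ("T0", "control")
                           ) -> pd.Series:
    """Median pairwise distance from each condition to the reference group.

    For the reference condition itself, zero self-pairs are excluded and
    the median is over distinct within-group pairs. Conditions are
    returned ordered by increasing median distance.
    """
    ref_ids = sheet.condition_samples(*reference)
    if not ref_ids:
        raise ValueError(f"reference condition {reference} is empty")
    out = {}
    for tp, tr in sheet.conditions():
        ids = sheet.condition_samples(tp, tr)
        if not ids:
            log.warning("condition (%s, %s) empty; omitted", tp, tr)
            continue
        if (tp, tr) == reference:
            pairs = [d.loc[a, b] for i, a in enumerate(ids)
                     for b in ids[i + 1:]]
        else:
            pairs = [d.loc[a, b] for a in ids for b in ref_ids]
        out[f"{tp}_{tr}"] = float(np.median(pairs))
    return pd.Series(out).sort_values()
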