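"""Probe summarization, quantile normalization, and detection calling.

Probes for a target are combined on the log2 scale by Tukey median polish
(the robust multi-array style additive probe + array fit); columns are then
quantile-normalized across samples so every array shares the same intensity
distribution. A target's transcript is called detected in a sample when its
normalized level exceeds the negative-control mean plus ``k`` control
standard deviations for that sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ArrayDesign

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Target-level normalized log2 levels with per-cell detection flags."""

    values: pd.DataFrame            # target × sample, log2
    detected: pd.DataFrame          # same shape, bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detected.index) or \
                not self.values.columns.equals(self.detected.columns):
            raise ValueError("values/detected must share index and columns")
        if not np.isfinite(self.values.values).all():
            raise ValueError("expression values must be finite")

    def linear_detected(self) -> pd.DataFrame:
        """Linear-scale levels of detected cells; undetected cells are 0."""
        return (2.0 ** self.values).where(self.detected, 0.0)


def median_polish(x: np.ndarray, tol: float = 1e-9, max_iter: int = 200
                  ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish of a 2-D array (rows + columns additive fit).

    Returns ``(overall, row_effects, col_effects, residuals)``. NaN cells
    are ignored by the medians and left NaN in the residuals.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("median_polish expects a 2-D array")
    resid = x.copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    scale = np.nansum(np.abs(x)) or 1.0
    prev = np.inf
    for _ in range(max_iter):
        with np.errstate(all="ignore"):
            rmed = np.nanmedian(resid, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        resid -= rmed[:, None]
        row += rmed
        cdelta = np.median(col)
        col -= cdelta
        overall += cdelta
        with np.errstate(all="ignore"):
            cmed = np.nanmedian(resid, axis=0)
        cmed = np.where(np.isnan(cmed), 0.0, cmed)
        resid -= cmed[None, :]
        col += cmed
        rdelta = np.median(row)
        row -= rdelta
        overall += rdelta
        total = np.nansum(np.abs(resid))
        if abs(prev - total) <= tol * scale:
            break
        prev = total
    return overall, row, col, resid


def summarize_probes(raw: pd.DataFrame, design: ArrayDesign,
                     tol: float = 1e-9) -> pd.DataFrame:
    """Combine probe rows per target into a target × sample log2 matrix.

    Per target the log2 probe intensities are fit as
    ``overall + probe_effect + sample_effect`` by median polish and the
    summarized level is ``overall + sample_effect``. Single-probe targets
    pass through as plain log2. Control probes (present in ``raw`` but not
    mapped to targets) are carried through unchanged as their own rows so
    that detection thresholds see the same transformations.
    """
    probe2target = design.probe_to_target()
    log2 = np.log2(raw.clip(lower=1.0))
    out_rows: dict[str, np.ndarray] = {}
    n_missing = 0
    for target, probes in probe2target.groupby(probe2target):
        pids = [p for p in probes.index if p in log2.index]
        if not pids:
            n_missing += 1
            continue
        block = log2.loc[pids].to_numpy()
        if block.shape[0] == 1:
            out_rows[target] = block[0]
        else:
            overall, _row, col, _res = median_polish(block, tol=tol)
            out_rows[target] = overall + col
    if n_missing:
        log.warning("%d targets had no probes with data and were flagged "
                    "missing", n_missing)
    ctrl_ids = [p for p in design.controls["probe_id"] if p in log2.index]
    for pid in ctrl_ids:
        out_rows[pid] = log2.loc[pid].to_numpy()
    targets_in_design = [t for t in design.target_ids if t in out_rows]
    order = targets_in_design + ctrl_ids
    summarized = pd.DataFrame(
        np.vstack([out_rows[t] for t in order]) if order else
        np.empty((0, log2.shape[1])),
        index=pd.Index(order, name="target_id"), columns=log2.columns)
    log.info("summarized %d probes into %d target rows (+%d control rows)",
             len(raw), len(targets_in_design), len(ctrl_ids))
    return summarized


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean of the columns' order statistics.

    Ties within a column receive the mean of the reference quantile values
    they span, so identical inputs stay identical after normalization.
    """
    if m.shape[1] < 2:
        log.warning("quantile_normalize: single column, returned unchanged")
        return m.copy()
    if m.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix")
    arr = m.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # average assigned reference values within tie blocks
        col = pd.Series(assigned)
        out[:, j] = col.groupby(pd.Series(arr[:, j])).transform("mean").to_numpy()
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def call_detection(m: pd.DataFrame, design: ArrayDesign,
                   k: float = 2.0,
                   fixed_threshold: float | None = None) -> pd.DataFrame:
    """Per-cell detection flags from negative-control probe statistics.

    A cell is detected iff its value is strictly greater than
    ``mean(negative controls in that sample) + k * sd(negative controls)``.
    ``m`` may contain the negative-control rows (they are used and the
    returned flags cover only the target rows). Without negative controls a
    ``fixed_threshold`` must be supplied.
    """
    neg = [p for p in design.negative_control_probes() if p in m.index]
    target_rows = [t for t in m.index if t in set(design.target_ids)]
    vals = m.loc[target_rows]
    if neg:
        stats = m.loc[neg]
        thresh = stats.mean(axis=0) + k * stats.std(axis=0, ddof=1)
    elif fixed_threshold is not None:
        thresh = pd.Series(fixed_threshold, index=m.columns)
    else:
        raise ValueError(
            "design has no negative-control probes; supply fixed_threshold "
            "to use a constant detection cutoff")
    flags = vals.gt(thresh, axis=1)
    log.info("detection: %.1f%% of %d x %d cells detected",
             100 * flags.values.mean(), *flags.shape)
    return flags


def normalize_pipeline(raw: pd.DataFrame, design: ArrayDesign,
                       detection_k: float = 2.0,
                       normalize_level: str = "target",
                       fixed_threshold: float | None = None
                       ) -> ExpressionMatrix:
    """summarize → quantile-normalize → call detection, in one step.

    ``normalize_level`` selects whether quantile normalization runs on the
    target-level summaries (default) or on probe-level log2 intensities
    before summarization (the RMA convention).
    """
    if normalize_level == "probe":
        log2 = np.log2(raw.clip(lower=1.0))
        normed_probes = quantile_normalize(log2)
        summarized = summarize_probes(2.0 ** normed_probes, design)
    else:
        summarized = quantile_normalize(summarize_probes(raw, design))
    flags = call_detection(summarized, design, k=detection_k,
                           fixed_threshold=fixed_threshold)
    target_rows = [t for t in summarized.index if t in set(design.target_ids)]
    values = summarized.loc[target_rows]
    return ExpressionMatrix(
        values=values, detected=flags.loc[target_rows],
        provenance={"normalize_level": normalize_level,
                    "detection_k": detection_k,
                    "n_negative_controls": len(design.negative_control_probes())})
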