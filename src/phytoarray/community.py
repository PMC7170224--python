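"""Strain presence, relative transcript abundance, and phylogroup shares.

A strain is "present" in a sample when at least five of its gene targets
are detected there, or at least half (rounded up) when it has fewer than
five targets. Transcript sums use linear-scale values of detected cells
only; undetected cells are background and contribute zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ArrayDesign, IntegrityError, SampleSheet
from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)


def presence_threshold(n_targets: int) -> int:
    """Minimum detected targets for presence: 5, or ceil(n/2) if n < 5."""
    if n_targets <= 0:
        raise IntegrityError("strain with zero targets in design")
    return 5 if n_targets >= 5 else math.ceil(n_targets / 2)


@dataclass
class StrainPresence:
    present: pd.DataFrame          # strain × sample bool
    detected_targets: pd.DataFrame  # strain × sample detected-target counts


def detect_strains(flags: pd.DataFrame, design: ArrayDesign
                   ) -> StrainPresence:
    """Apply the presence rule to a target × sample detection matrix."""
    strain_of = design.target_annotation()["strain_id"]
    counts = flags.groupby(strain_of.loc[flags.index]).sum()
    n_targets = design.strain_catalog.set_index("strain_id")["n_targets"]
    counts = counts.reindex(n_targets.index, fill_value=0)
    thresh = n_targets.map(presence_threshold)
    present = counts.ge(thresh, axis=0)
    log.info("strain presence: mean %.1f strains per sample (of %d)",
             present.sum(axis=0).mean(), len(present))
    return StrainPresence(present=present, detected_targets=counts)


def strain_abundance(expr: ExpressionMatrix, design: ArrayDesign,
                     scale: float = 1e5) -> pd.DataFrame:
    """Per-strain relative transcript abundance score.

    score(s, j) = [strain s's share of sample j's detected linear
    transcript sum] / n_targets(s) × scale. Zero iff the strain
    contributes no detected transcripts.
    """
    linear = expr.linear_detected()
    totals = linear.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero detected transcripts: {empty}")
    strain_of = design.target_annotation()["strain_id"]
    sums = linear.groupby(strain_of.loc[linear.index]).sum()
    n_targets = design.strain_catalog.set_index("strain_id")["n_targets"]
    sums = sums.reindex(n_targets.index, fill_value=0.0)
    share = sums.div(totals, axis=1)
    return share.div(n_targets, axis=0) * scale


def phylogroup_proportions(expr: ExpressionMatrix, design: ArrayDesign,
                           sheet: SampleSheet) -> pd.DataFrame:
    """Mean share of detected transcripts per phylogroup and condition.

    Shares sum to 1 over phylogroups within each sample before averaging
    across replicates of each (timepoint, treatment) condition.
    """
    linear = expr.linear_detected()
    totals = linear.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero detected transcripts")
    group_of = design.target_annotation()["phylogroup"]
    sums = linear.groupby(group_of.loc[linear.index]).sum()
    share = sums.div(totals, axis=1)
    cond = sheet.samples.set_index("sample_id")[["timepoint", "treatment"]]
    labels = cond.loc[share.columns, "timepoint"] + "_" + \
        cond.loc[share.columns, "treatment"]
    out = share.T.groupby(labels.to_numpy()).mean().T
    return out
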