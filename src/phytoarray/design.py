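"""Array design and sample sheet containers.

The array is organized as a probe → gene-target → strain → phylogroup
hierarchy: each oligonucleotide probe interrogates exactly one gene target,
each target belongs to one strain, and strains are grouped into major
phylogroups (e.g. high-light adapted *Prochlorococcus*, *Synechococcus*,
photosynthetic eukaryotes). Negative-control and spike-in probes sit outside
the hierarchy and are used for detection calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

TIMEPOINTS = ("T0", "T24")
TREATMENTS = ("control", "NO3", "NH4", "urea", "Fe", "NplusFe", "FDW")
CONTROL_ROLES = ("negative", "spike_in")


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class IntegrityError(ValueError):
    """A table violates a structural invariant of the design hierarchy."""


@dataclass
class ArrayDesign:
    """Probe/target/strain/phylogroup hierarchy plus control-probe roster.

    Parameters
    ----------
    probes : DataFrame with columns ``probe_id, target_id``.
    targets : DataFrame with columns
        ``target_id, gene, process, strain_id, phylogroup`` and optionally
        ``ecotype``.
    controls : DataFrame with columns ``probe_id, role`` where role is
        ``negative`` or ``spike_in``.
    """

    probes: pd.DataFrame
    targets: pd.DataFrame
    controls: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["probe_id", "role"]))

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        self.targets = self.targets.reset_index(drop=True)
        self.controls = self.controls.reset_index(drop=True)
        if "ecotype" not in self.targets.columns:
            self.targets = self.targets.assign(ecotype="")
        self.validate()

    def validate(self) -> None:
        if self.probes["probe_id"].duplicated().any():
            dups = self.probes.loc[self.probes["probe_id"].duplicated(), "probe_id"]
            raise IntegrityError(f"duplicate probe ids: {sorted(set(dups))[:5]}")
        if self.targets["target_id"].duplicated().any():
            raise IntegrityError("duplicate target ids in design")
        known = set(self.targets["target_id"])
        unknown = set(self.probes["target_id"]) - known
        if unknown:
            raise IntegrityError(
                f"{len(unknown)} probes map to targets absent from the design, "
                f"e.g. {sorted(unknown)[:5]}")
        overlap = set(self.controls["probe_id"]) & set(self.probes["probe_id"])
        if overlap:
            raise IntegrityError(
                f"control probes also mapped to targets: {sorted(overlap)[:5]}")
        bad_roles = set(self.controls["role"]) - set(CONTROL_ROLES)
        if bad_roles:
            raise IntegrityError(f"unknown control roles: {bad_roles}")
        # each strain must belong to exactly one phylogroup
        per_strain = self.targets.groupby("strain_id")["phylogroup"].nunique()
        if (per_strain > 1).any():
            bad = per_strain[per_strain > 1].index.tolist()
            raise IntegrityError(f"strains in multiple phylogroups: {bad[:5]}")

    # -- derived views ----------------------------------------------------
    @property
    def target_ids(self) -> pd.Index:
        return pd.Index(self.targets["target_id"])

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.probes["probe_id"])

    @property
    def strain_catalog(self) -> pd.DataFrame:
        """One row per strain: strain_id, phylogroup, n_targets."""
        cat = (self.targets.groupby(["strain_id", "phylogroup"], sort=True)
               .size().rename("n_targets").reset_index())
        return cat

    def probe_to_target(self) -> pd.Series:
        return self.probes.set_index("probe_id")["target_id"]

    def target_annotation(self) -> pd.DataFrame:
        return self.targets.set_index("target_id")

    def negative_control_probes(self) -> list[str]:
        mask = self.controls["role"] == "negative"
        return self.controls.loc[mask, "probe_id"].tolist()


@dataclass
class SampleSheet:
    """Sample metadata: one row per array with timepoint/treatment/replicate.

    With ``strict=True`` (default) the full experimental-design invariants
    are enforced: every (timepoint, treatment) group has at least two
    replicates and control samples exist at both T0 and T24. Readers of
    partial data (e.g. a subset of a deposited series) may pass
    ``strict=False`` to keep only the per-row format checks.
    """

    samples: pd.DataFrame  # sample_id, timepoint, treatment, replicate
    strict: bool = True

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        required = {"sample_id", "timepoint", "treatment", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            raise IntegrityError("duplicate sample ids")
        bad_tp = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise IntegrityError(f"unknown timepoints: {bad_tp}")
        bad_tr = set(self.samples["treatment"]) - set(TREATMENTS)
        if bad_tr:
            raise IntegrityError(f"unknown treatments: {bad_tr}")
        if not self.strict:
            return
        sizes = self.samples.groupby(["timepoint", "treatment"]).size()
        small = sizes[sizes < 2]
        if len(small):
            raise IntegrityError(
                f"conditions with <2 replicates: {small.index.tolist()}")
        for tp in TIMEPOINTS:
            if not ((self.samples["timepoint"] == tp)
                    & (self.samples["treatment"] == "control")).any():
                raise IntegrityError(f"no control samples at {tp}")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.samples["sample_id"])

    def condition_samples(self, timepoint: str, treatment: str) -> list[str]:
        m = ((self.samples["timepoint"] == timepoint)
             & (self.samples["treatment"] == treatment))
        return self.samples.loc[m, "sample_id"].tolist()

    def conditions(self) -> list[tuple[str, str]]:
        seen = self.samples[["timepoint", "treatment"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]
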