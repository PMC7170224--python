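"""Synthetic multi-strain array experiments with known ground truth.

The generator emulates the study design the pipeline targets: hundreds of
gene targets spread over strains and phylogroups, several probes per
target, seven nutrient-amendment conditions plus a T0 baseline (23 arrays;
the NH4 treatment has two replicates), lognormal probe noise, a
background/detection floor, and directional log2 effects implanted on
defined gene sets. Every downstream stage can therefore be scored against
recorded truth.

Model, per sample ``s`` with condition ``t`` and probe ``j`` of target ``i``:

    log2 intensity = mu_i + delta_{i,t} + a_j + eps,   eps ~ N(0, sigma_resid)

where ``mu_i`` is the target's baseline log2 abundance, ``delta_{i,t}`` the
implanted condition effect, and ``a_j`` a fixed probe affinity. Cells whose
expected level falls below the background floor, and all cells of strains
absent from a sample, are replaced by background draws
``N(floor_mean, floor_sd)``. Intensities are exponentiated to the linear
scale, which makes them lognormal as raw scanner output is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ArrayDesign, SampleSheet
from .genesets import GENE_SETS

DEFAULT_PHYLOGROUPS = ("HL_Pro", "LL_Pro", "Synechococcus", "PE",
                       "Pelagibacter")

#: genes every sufficiently large strain carries, so that the standard
#: response gene sets are constructible per phylogroup
CORE_GENES = ("ntcA", "urtA", "amt", "glnA", "rbcL", "psbA", "psaA",
              "fur", "isiA", "pstS")
#: additional vocabulary drawn at random for the remaining targets
EXTRA_GENES = ("cynA", "ureA", "nirA", "nrtP", "isiB", "isiP", "idiA",
               "dpsA", "phoB", "phoH", "psaB", "psbB", "pstA", "pstB",
               "pstC", "psiP", "mfs", "phrB", "nudix", "pmm1359",
               "carA", "glnB", "petB", "sodN", "bop")

_GENE_TO_LABEL = {g: label for label, genes in GENE_SETS.items()
                  for g in genes}


@dataclass
class TruthEffect:
    """One implanted directional response.

    ``kind`` selects the scope: ``"set"`` shifts all member targets of the
    response gene set within the phylogroup, ``"gene"`` shifts all targets
    of one gene symbol (applied after set effects, overriding them), and
    ``"all"`` shifts every target of the phylogroup equally — a pure
    abundance change with no regulation, used to exercise the artifact
    filter.
    """

    phylogroup: str
    treatment: str
    log2fc: float
    kind: str = "set"          # {"set", "gene", "all"}
    label: str | None = None   # response label for kind == "set"
    gene: str | None = None    # gene symbol for kind == "gene"


@dataclass
class TruthConfig:
    effects: list[TruthEffect] = field(default_factory=list)
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    affinity_sd: float = 0.3
    resid_sd: float = 0.25
    floor_mean: float = 4.0
    floor_sd: float = 0.5
    spike_mean: float = 13.0
    spike_sd: float = 0.1
    #: fraction of strains absent from the community (all samples); bottles
    #: drawn from one water mass share their composition
    absent_fraction: float = 0.1
    #: optional per-(strain, sample) dropout for bottle-to-bottle
    #: compositional variability; the study design holds composition fixed
    dropout_fraction: float = 0.0
    replicate_plan: dict = field(default_factory=lambda: {
        ("T0", "control"): 3, ("T24", "control"): 3, ("T24", "NO3"): 3,
        ("T24", "NH4"): 2, ("T24", "urea"): 3, ("T24", "Fe"): 3,
        ("T24", "NplusFe"): 3, ("T24", "FDW"): 3})
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "affinity_sd", "resid_sd", "floor_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if ("T0", "control") not in self.replicate_plan:
            raise ValueError("replicate plan must include the T0 control")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one simulated experiment."""

    effects: pd.DataFrame    # target × treatment realized log2 effects (T24)
    baseline: pd.Series      # per-target baseline log2 level
    presence: pd.DataFrame   # strain × sample bool
    expressed: pd.DataFrame  # target × sample bool (truth for detection)
    config: TruthConfig

    def null_targets(self) -> pd.Index:
        """Targets with zero implanted effect in every treatment."""
        return self.effects.index[(self.effects == 0).all(axis=1)]


def _draw_count(rng: np.random.Generator, spec) -> int:
    if np.isscalar(spec):
        return int(spec)
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def simulate_design(n_phylogroups: int = 5,
                    strains_per_group: int = 8,
                    targets_per_strain=(10, 16),
                    probes_per_target=(2, 4),
                    seed: int = 0,
                    n_negative_controls: int = 32,
                    n_spike_ins: int = 8,
                    phylogroup_names: tuple[str, ...] | None = None
                    ) -> ArrayDesign:
    """Generate a reduced-scale multi-strain array design.

    Each strain receives the core response genes first (so phylogroup-level
    gene sets are constructible) and random extra vocabulary after that.
    """
    if n_phylogroups < 1 or strains_per_group < 1:
        raise ValueError("counts must be >= 1")
    if _spec_max(probes_per_target) < 1:
        raise ValueError("probes per target must be >= 1")
    if _spec_max(targets_per_strain) < 1:
        raise ValueError("targets per strain must be >= 1")
    rng = np.random.default_rng(seed)
    if phylogroup_names is None:
        base = list(DEFAULT_PHYLOGROUPS)
        while len(base) < n_phylogroups:
            base.append(f"group{len(base) + 1}")
        phylogroup_names = tuple(base[:n_phylogroups])
    probe_rows, target_rows = [], []
    for g, group in enumerate(phylogroup_names):
        ecotype = {"HL_Pro": "HL", "LL_Pro": "LL"}.get(group, "")
        for s in range(strains_per_group):
            strain = f"{group}_str{s + 1:02d}"
            n_targets = _draw_count(rng, targets_per_strain)
            genes = list(CORE_GENES[:n_targets])
            while len(genes) < n_targets:
                genes.append(str(rng.choice(EXTRA_GENES)))
            for k, gene in enumerate(genes):
                tid = f"{strain}_t{k + 1:03d}"
                target_rows.append((tid, gene, _GENE_TO_LABEL.get(gene, "other"),
                                    strain, group, ecotype))
                for p in range(_draw_count(rng, probes_per_target)):
                    probe_rows.append((f"{tid}_p{p + 1}", tid))
    controls = (
        [(f"NEG_{i + 1:03d}", "negative") for i in range(n_negative_controls)]
        + [(f"SPIKE_{i + 1:02d}", "spike_in") for i in range(n_spike_ins)])
    return ArrayDesign(
        probes=pd.DataFrame(probe_rows, columns=["probe_id", "target_id"]),
        targets=pd.DataFrame(target_rows, columns=[
            "target_id", "gene", "process", "strain_id", "phylogroup",
            "ecotype"]),
        controls=pd.DataFrame(controls, columns=["probe_id", "role"]))


def _spec_max(spec) -> int:
    return int(spec) if np.isscalar(spec) else int(spec[1])


def default_truth_config(seed: int = 0) -> TruthConfig:
    """The default implanted-response table.

    The pattern mirrors the qualitative response map of a late-summer
    N-limited picophytoplankton community: HL *Prochlorococcus* N-stress
    genes fall and RuBisCO rises after reduced-N additions (NH4, urea),
    photosynthetic eukaryote RuBisCO rises most strongly after nitrate,
    picocyanobacterial *urtA* rises across strains in filtered deep water
    (a correlated cross-strain effect that exercises module recovery), and
    one phylogroup receives a uniform pure-abundance shift with no
    regulation (exercising the abundance-artifact filter). Magnitudes are
    not reported by any field study at this resolution; defaults of
    0.6–1.0 log2 (1.5–2.0×) are documented placeholders.
    """
    e = []
    for tr in ("NH4", "urea"):
        e += [TruthEffect("HL_Pro", tr, -0.8, label="N stress"),
              TruthEffect("HL_Pro", tr, +0.8, label="RuBisCO"),
              TruthEffect("LL_Pro", tr, +0.8, label="RuBisCO")]
    e += [TruthEffect("LL_Pro", "NH4", +0.8, label="photosynthesis"),
          TruthEffect("HL_Pro", "FDW", -0.6, label="N stress")]
    for tr in ("NO3", "NH4", "urea", "FDW"):
        e.append(TruthEffect("Synechococcus", tr, +0.8, label="RuBisCO"))
    e.append(TruthEffect("Synechococcus", "NO3", +0.8, label="photosynthesis"))
    e.append(TruthEffect("PE", "NO3", +1.0, label="RuBisCO"))
    for tr in ("NH4", "urea", "Fe", "FDW"):
        e.append(TruthEffect("PE", tr, +0.6, label="RuBisCO"))
    # correlated urtA response across picocyanobacteria in deep water
    for group in ("HL_Pro", "LL_Pro", "Synechococcus"):
        e.append(TruthEffect(group, "FDW", +1.0, kind="gene", gene="urtA"))
    # pure abundance shift: every Pelagibacter target up equally in Fe
    e.append(TruthEffect("Pelagibacter", "Fe", +0.6, kind="all"))
    return TruthConfig(effects=e, seed=seed)


def null_truth_config(seed: int = 0) -> TruthConfig:
    """All effects zero — the calibration condition."""
    return TruthConfig(effects=[], seed=seed)


def realize_effects(design: ArrayDesign, truth: TruthConfig) -> pd.DataFrame:
    """Per-target × treatment matrix of implanted log2 effects at T24."""
    treatments = sorted({tr for (_tp, tr) in truth.replicate_plan})
    ann = design.target_annotation()
    eff = pd.DataFrame(0.0, index=ann.index, columns=treatments)
    for kind in ("all", "set", "gene"):  # gene-level overrides set-level
        for item in truth.effects:
            if item.kind != kind:
                continue
            in_group = ann["phylogroup"] == item.phylogroup
            if kind == "all":
                mask = in_group
            elif kind == "set":
                members = GENE_SETS[item.label]
                mask = in_group & ann["gene"].isin(members)
            else:
                mask = in_group & (ann["gene"] == item.gene)
            eff.loc[mask, item.treatment] = item.log2fc
    eff["control"] = 0.0
    return eff


def simulate_experiment(design: ArrayDesign, truth: TruthConfig
                        ) -> tuple[pd.DataFrame, SampleSheet, SyntheticTruth]:
    """Draw one probe × sample intensity matrix plus its truth ledger."""
    rng = np.random.default_rng(truth.seed)
    ann = design.target_annotation()
    targets = ann.index
    n_t = len(targets)

    samples = []
    for (tp, tr), n_rep in sorted(truth.replicate_plan.items()):
        for r in range(1, n_rep + 1):
            samples.append((f"{tp}_{tr}_{r}", tp, tr, r))
    sheet = SampleSheet(pd.DataFrame(
        samples, columns=["sample_id", "timepoint", "treatment", "replicate"]))
    sample_ids = sheet.sample_ids

    baseline = pd.Series(
        rng.normal(truth.baseline_mean, truth.baseline_sd, n_t),
        index=targets, name="baseline")
    effects = realize_effects(design, truth)

    # per-sample condition effect: treatments act at T24 only
    delta = np.zeros((n_t, len(sample_ids)))
    for j, (_sid, tp, tr, _r) in enumerate(samples):
        if tp == "T24" and tr != "control":
            delta[:, j] = effects[tr].to_numpy()
    mean_level = baseline.to_numpy()[:, None] + delta

    strains = ann["strain_id"]
    strain_ids = strains.unique()
    in_community = rng.random(len(strain_ids)) >= truth.absent_fraction
    dropout = rng.random((len(strain_ids), len(sample_ids))) \
        < truth.dropout_fraction
    presence = pd.DataFrame(
        in_community[:, None] & ~dropout,
        index=strain_ids, columns=sample_ids)
    present_t = presence.loc[strains.to_numpy()].to_numpy()

    expressed = present_t & (mean_level > truth.floor_mean)
    expressed_df = pd.DataFrame(expressed, index=targets, columns=sample_ids)

    probe_targets = design.probes["target_id"]
    t_pos = pd.Series(np.arange(n_t), index=targets)
    p_idx = t_pos[probe_targets.to_numpy()].to_numpy()
    affinity = rng.normal(0.0, truth.affinity_sd, len(probe_targets))

    signal = (mean_level[p_idx, :] + affinity[:, None]
              + rng.normal(0.0, truth.resid_sd,
                           (len(probe_targets), len(sample_ids))))
    background = rng.normal(truth.floor_mean, truth.floor_sd,
                            (len(probe_targets), len(sample_ids)))
    log2_probe = np.where(expressed[p_idx, :], signal, background)

    frames = [pd.DataFrame(2.0 ** log2_probe,
                           index=design.probes["probe_id"].to_numpy(),
                           columns=sample_ids)]
    neg = design.controls.loc[design.controls["role"] == "negative", "probe_id"]
    if len(neg):
        frames.append(pd.DataFrame(
            2.0 ** rng.normal(truth.floor_mean, truth.floor_sd,
                              (len(neg), len(sample_ids))),
            index=neg.to_numpy(), columns=sample_ids))
    spike = design.controls.loc[design.controls["role"] == "spike_in",
                                "probe_id"]
    if len(spike):
        frames.append(pd.DataFrame(
            2.0 ** rng.normal(truth.spike_mean, truth.spike_sd,
                              (len(spike), len(sample_ids))),
            index=spike.to_numpy(), columns=sample_ids))
    intensities = pd.concat(frames)
    intensities.index.name = "probe_id"

    treatment_cols = [c for c in effects.columns if c != "control"]
    truth_out = SyntheticTruth(
        effects=effects[treatment_cols], baseline=baseline,
        presence=presence, expressed=expressed_df,
        config=replace(truth))
    return intensities, sheet, truth_out
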