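"""Ensemble gene-set testing with an abundance-artifact filter.

Gene sets pair a phylogroup (or single strain) with a physiological
response label — N stress, Fe stress, P stress, photosynthesis, RuBisCO,
light stress — whose member genes move together when the stress changes.
Each set is tested competitively against the other detected genes of its
phylogroup by a battery of base statistics from four families (rank,
permutation, count, distribution):

1. rank-sum of member gene t-statistics vs non-members,
2. mean member t-statistic,
3. the 2x2 count of DE calls among members vs non-members (hypergeometric),
4. the Kolmogorov-Smirnov distance between member and non-member t's.

The per-method p-values are combined by Wilkinson's method (the r-th
smallest p referred to Beta(r, K-r+1)). Because the four statistics are
computed from the same genes they are strongly dependent, so the Wilkinson
score is calibrated by membership permutation: the same random member
subsets provide the joint null reference for every method and for the
combined score (the reported combined p is its permutation tail
probability). Base statistics are two-sided; the response direction is
reported separately as the sign of the set's average fold change.

A set call that merely tracks a phylogroup-wide abundance change is
removed by the artifact filter: with ``a_g`` the average (geometric-mean)
fold change of member genes and ``a_tot`` that of all detected targets of
the phylogroup, an increase is retained only when ``a_g / a_tot > 1`` and
a decrease only when ``a_g / a_tot < 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ArrayDesign
from .diffexpr import bh_adjust

log = logging.getLogger(__name__)

#: response gene sets: label -> member gene symbols
GENE_SETS: dict[str, list[str]] = {
    "Fe stress": ["fur", "isiA", "isiP", "isiB", "idiA", "dpsA"],
    "N stress": ["ntcA", "urtA", "cynA", "amt", "glnA", "ureA", "nirA",
                 "nrtP"],
    "P stress": ["psiP", "pstS", "phoH", "mfs", "phoB", "pstA", "pstB",
                 "pstC"],
    "photosynthesis": ["psaB", "psbA", "psbB", "psaA"],
    "RuBisCO": ["rbcL"],
    "light stress": ["phrB", "nudix", "pmm1359"],
}
RESPONSE_LABELS = tuple(GENE_SETS)


@dataclass
class GeneSet:
    set_id: str
    scope_kind: str          # {"phylogroup", "strain"}
    scope: str               # phylogroup name or strain id
    phylogroup: str
    label: str
    members: list[str]       # target ids


def build_gene_sets(design: ArrayDesign, scope_mode: str = "phylogroup",
                    labels=None) -> list[GeneSet]:
    """One set per (scope, response label) with at least one member target."""
    if scope_mode not in ("phylogroup", "strain"):
        raise ValueError("scope_mode must be 'phylogroup' or 'strain'")
    labels = list(labels) if labels is not None else list(RESPONSE_LABELS)
    unknown = set(labels) - set(GENE_SETS)
    if unknown:
        raise ValueError(f"unknown response labels: {sorted(unknown)}")
    ann = design.target_annotation()
    scope_col = "phylogroup" if scope_mode == "phylogroup" else "strain_id"
    out: list[GeneSet] = []
    for scope, block in ann.groupby(scope_col, sort=True):
        group = block["phylogroup"].iloc[0]
        for label in labels:
            members = block.index[block["gene"].isin(GENE_SETS[label])]
            if len(members) == 0:
                log.info("set (%s, %s) has no member targets; omitted",
                         scope, label)
                continue
            out.append(GeneSet(set_id=f"{scope}|{label}",
                               scope_kind=scope_mode, scope=str(scope),
                               phylogroup=str(group), label=label,
                               members=list(members)))
    return out


def wilkinson_combine(p, r: int) -> float:
    """Wilkinson's combined p: Pr(Beta(r, K - r + 1) <= p_(r))."""
    p = np.asarray(p, dtype=float)
    k = len(p)
    if k == 0:
        raise ValueError("need at least one p-value")
    if not 1 <= r <= k:
        raise ValueError(f"r={r} out of range for K={k}")
    p_r = np.sort(p)[r - 1]
    return float(stats.beta.cdf(p_r, r, k - r + 1))


def rank_sum_p(member_scores, nonmember_scores,
               alternative: str = "greater") -> float:
    """Exact rank-sum (Mann-Whitney) p of member vs non-member scores."""
    res = stats.mannwhitneyu(member_scores, nonmember_scores,
                             alternative=alternative, method="auto")
    return float(res.pvalue)


def _fisher_two_sided_table(n: int, n_de: int, m: int) -> np.ndarray:
    """Two-sided hypergeometric p for x = 0..m DE members (Fisher 2x2)."""
    x = np.arange(m + 1)
    pmf = stats.hypergeom.pmf(x, n, n_de, m)
    p = np.array([pmf[pmf <= pmf[i] * (1 + 1e-9)].sum() for i in x])
    return np.minimum(p, 1.0)


def _perm_member_subsets(rng: np.random.Generator, n: int, m: int,
                         n_perm: int) -> np.ndarray:
    """(n_perm, m) random member index subsets, uniform without replacement."""
    u = rng.random((n_perm, n))
    return np.argpartition(u, m - 1, axis=1)[:, :m]


def _ensemble_stats(t: np.ndarray, de: np.ndarray, member_mask: np.ndarray,
                    subsets: np.ndarray) -> tuple[dict, dict, list[str]]:
    """Observed and permuted two-sided base statistics.

    Returns (observed stats, permuted stat arrays, active method names).
    Rank-based methods go degenerate (p = 1) when all scores are tied; the
    count method is dropped when the DE margin is empty or full.
    """
    n = len(t)
    m = int(member_mask.sum())
    n_perm = subsets.shape[0]
    ranks = stats.rankdata(t)
    order = np.argsort(t, kind="stable")

    ind = np.zeros((n_perm, n), dtype=bool)
    ind[np.arange(n_perm)[:, None], subsets] = True

    obs: dict[str, float] = {}
    perm: dict[str, np.ndarray] = {}
    mean_rank = (n + 1) / 2.0
    obs["ranksum"] = abs(ranks[member_mask].sum() - m * mean_rank)
    perm["ranksum"] = np.abs(ind @ ranks - m * mean_rank)
    overall_mean = t.mean()
    obs["meant"] = abs(t[member_mask].mean() - overall_mean)
    perm["meant"] = np.abs((ind @ t) / m - overall_mean)

    n_de = int(de.sum())
    active = ["ranksum", "meant"]
    if 0 < n_de < n:
        ptab = _fisher_two_sided_table(n, n_de, m)
        obs["fisher"] = -ptab[int(de[member_mask].sum())]
        perm["fisher"] = -ptab[(ind @ de.astype(int))]
        active.append("fisher")

    ind_sorted = ind[:, order]
    cum = np.cumsum(ind_sorted, axis=1)
    pos = np.arange(1, n + 1)
    d_perm = np.max(np.abs(cum / m - (pos - cum) / (n - m)), axis=1)
    cum_obs = np.cumsum(member_mask[order])
    obs["ks"] = float(np.max(np.abs(cum_obs / m - (pos - cum_obs) / (n - m))))
    perm["ks"] = d_perm
    active.append("ks")
    return obs, perm, active


def ensemble_set_test(t: np.ndarray, de: np.ndarray,
                      member_mask: np.ndarray, rng: np.random.Generator,
                      n_perm: int = 10000, wilkinson_r: int = 2,
                      chunk: int = 4096) -> dict:
    """Permutation-calibrated Wilkinson consensus over the base battery.

    Per-method p-values are permutation tail probabilities of the
    two-sided base statistics (observed pooled with the permutations); the
    combined p is the tail probability of the Wilkinson order statistic of
    those p-values across the same joint permutation null.
    """
    t = np.asarray(t, dtype=float)
    de = np.asarray(de, dtype=bool)
    member_mask = np.asarray(member_mask, dtype=bool)
    n, m = len(t), int(member_mask.sum())
    if m < 2 or n - m < 2:
        raise ValueError("need >=2 members and >=2 non-members")
    if np.ptp(t) == 0:
        log.info("degenerate set universe (all scores equal): p = 1")
        return {"p_combined": 1.0, "wilkinson": 1.0,
                "base_p": {k: 1.0 for k in
                           ("ranksum", "meant", "fisher", "ks")},
                "n_methods": 0}
    obs_parts, perm_parts = [], []
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        subsets = _perm_member_subsets(rng, n, m, size)
        obs_s, perm_s, active = _ensemble_stats(t, de, member_mask, subsets)
        obs_parts = obs_s  # identical every chunk
        perm_parts.append(perm_s)
        done += size
    perm_all = {k: np.concatenate([p[k] for p in perm_parts])
                for k in perm_parts[0]}

    r_eff = min(wilkinson_r, len(active))
    base_p: dict[str, float] = {}
    # pooled rows: observed first, then permutations
    pooled_p = np.empty((n_perm + 1, len(active)))
    for j, name in enumerate(active):
        s_all = np.concatenate(([obs_parts[name]], perm_all[name]))
        count_ge = stats.rankdata(-s_all, method="max")
        pooled_p[:, j] = count_ge / (n_perm + 1.0)
        base_p[name] = float(pooled_p[0, j])
    # Wilkinson order statistic per row; Beta cdf is monotone in p_(r),
    # so tail counting can use p_(r) directly
    p_r = np.sort(pooled_p, axis=1)[:, r_eff - 1]
    p_combined = float(np.mean(p_r <= p_r[0] + 1e-12))
    wilk = wilkinson_combine(pooled_p[0], r_eff)
    for name in ("ranksum", "meant", "fisher", "ks"):
        base_p.setdefault(name, float("nan"))
    return {"p_combined": p_combined, "wilkinson": wilk, "base_p": base_p,
            "n_methods": len(active)}


def base_set_tests(de_result: pd.DataFrame, gene_set: GeneSet,
                   universe: pd.Index, n_perm: int = 10000,
                   seed: int = 0) -> dict[str, float]:
    """The four base p-values for one set against its phylogroup universe."""
    rng = np.random.default_rng(seed)
    block = de_result.loc[universe]
    member_mask = universe.isin(gene_set.members)
    res = ensemble_set_test(block["t"].to_numpy(),
                            block["de"].to_numpy(),
                            member_mask, rng, n_perm=n_perm)
    return res["base_p"]


def average_fold_changes(de_result: pd.DataFrame, members: pd.Index,
                         universe: pd.Index) -> tuple[float, float]:
    """(a_g, a_tot): geometric-mean linear fold change of the member genes
    and of all detected targets of the phylogroup."""
    a_g = float(2.0 ** de_result.loc[members, "log2fc"].mean())
    a_tot = float(2.0 ** de_result.loc[universe, "log2fc"].mean())
    return a_g, a_tot


def artifact_filter(direction: int, a_g: float, a_tot: float) -> bool:
    """Retain only calls consistent with the phylogroup-total fold change."""
    if a_tot <= 0 or a_g <= 0:
        raise ValueError("fold changes must be positive linear ratios")
    ratio = a_g / a_tot
    if direction > 0:
        return ratio > 1.0
    if direction < 0:
        return ratio < 1.0
    return False


def classify_magnitude(direction: int, a_g: float,
                       fc_threshold: float = 1.2) -> bool:
    """Thick-arrow flag: average member fold change beyond the threshold."""
    if direction > 0:
        return a_g > fc_threshold
    if direction < 0:
        return a_g < 1.0 / fc_threshold
    return False


def test_gene_sets(de_results: dict[str, pd.DataFrame],
                   design: ArrayDesign, sets: list[GeneSet],
                   n_perm: int = 10000, wilkinson_r: int = 2,
                   alpha_set: float = 0.01, fc_threshold: float = 1.2,
                   seed: int = 0) -> pd.DataFrame:
    """Run the calibrated ensemble for every (set, contrast).

    BH adjustment is applied across all (set, contrast) combined p-values.
    Sets with fewer than two detected members in a contrast are skipped
    (logged). Every tested set is returned, including filtered ones
    (``retained`` False).
    """
    ann = design.target_annotation()
    rows = []
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = iter(seed_seq.generate_state(
        len(de_results) * len(sets) * 2, dtype=np.uint32).tolist())
    for cname in sorted(de_results):
        de = de_results[cname]
        tested_groups = {g: de.index.intersection(
            ann.index[ann["phylogroup"] == g])
            for g in ann["phylogroup"].unique()}
        for gs in sets:
            universe = tested_groups[gs.phylogroup]
            members = universe.intersection(gs.members)
            task_seed = next(child_seeds)
            if len(members) < 2 or len(universe) - len(members) < 2:
                log.info("set %s skipped in %s (<2 detected members or "
                         "non-members)", gs.set_id, cname)
                continue
            rng = np.random.default_rng(task_seed)
            block = de.loc[universe]
            res = ensemble_set_test(
                block["t"].to_numpy(), block["de"].to_numpy(),
                universe.isin(members), rng, n_perm=n_perm,
                wilkinson_r=wilkinson_r)
            a_g, a_tot = average_fold_changes(de, members, universe)
            direction = int(np.sign(np.log2(a_g))) if a_g != 1.0 else 0
            rows.append({
                "set_id": gs.set_id, "scope": gs.scope,
                "scope_kind": gs.scope_kind, "phylogroup": gs.phylogroup,
                "label": gs.label, "contrast": cname,
                "n_members_detected": len(members),
                "p_ranksum": res["base_p"]["ranksum"],
                "p_meant": res["base_p"]["meant"],
                "p_fisher": res["base_p"]["fisher"],
                "p_ks": res["base_p"]["ks"],
                "wilkinson": res["wilkinson"],
                "p_combined": res["p_combined"],
                "a_g": a_g, "a_tot": a_tot,
                "artifact_ratio": a_g / a_tot,
                "direction": direction,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["adj_p"] = bh_adjust(out["p_combined"].to_numpy())
    out["significant"] = out["adj_p"] < alpha_set
    out["retained"] = [artifact_filter(d, g, t) if d != 0 else False
                       for d, g, t in zip(out["direction"], out["a_g"],
                                          out["a_tot"])]
    out["thick"] = [classify_magnitude(d, g, fc_threshold)
                    for d, g in zip(out["direction"], out["a_g"])]
    return out


def summarize_responses(results: pd.DataFrame) -> pd.DataFrame:
    """Machine-readable arrow table: one row per (scope, contrast, set)."""
    cols = ["scope", "phylogroup", "label", "contrast", "direction",
            "significant", "retained", "thick", "a_g", "a_tot", "adj_p"]
    out = results[cols].copy()
    out["arrow"] = np.where(
        ~out["significant"], "o",
        np.where(out["direction"] > 0,
                 np.where(out["thick"], "UP*", "up"),
                 np.where(out["thick"], "DOWN*", "down")))
    return out.sort_values(["contrast", "scope", "label"]).reset_index(
        drop=True)
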