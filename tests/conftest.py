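"""Shared fixtures: one fully analyzed synthetic experiment per session."""

import numpy as np
import pandas as pd
import pytest

import phytoarray as pa

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale synthetic experiment with the standard response map."""
    design = pa.simulate_design(seed=FIXTURE_SEED)
    truth = pa.default_truth_config(seed=FIXTURE_SEED)
    intensities, sheet, truth_out = pa.simulate_experiment(design, truth)
    return design, intensities, sheet, truth_out


@pytest.fixture(scope="session")
def default_expr(default_sim):
    design, intensities, _sheet, _truth = default_sim
    return pa.normalize_pipeline(intensities, design)


@pytest.fixture(scope="session")
def default_de(default_sim, default_expr):
    _design, _intensities, sheet, _truth = default_sim
    return pa.run_differential_expression(default_expr, sheet)


@pytest.fixture(scope="session")
def default_set_results(default_sim, default_de):
    design = default_sim[0]
    sets = pa.build_gene_sets(design)
    return pa.test_gene_sets(default_de, design, sets, n_perm=10000,
                             seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def null_sim_compact():
    """Compact zero-effect experiment for calibration checks."""
    design = pa.simulate_design(n_phylogroups=3, strains_per_group=6, seed=3)
    truth = pa.null_truth_config(seed=3)
    intensities, sheet, truth_out = pa.simulate_experiment(design, truth)
    expr = pa.normalize_pipeline(intensities, design)
    return design, sheet, truth_out, expr


def toy_expression(values: np.ndarray, treatments, n_rep=3,
                   gene_ids=None) -> tuple[pa.ExpressionMatrix,
                                           pa.SampleSheet]:
    """Wrap a plain matrix as an all-detected ExpressionMatrix + sheet.

    ``treatments`` lists (timepoint, treatment) per replicate block of
    ``n_rep`` columns.
    """
    cols = []
    rows = []
    for tp, tr in treatments:
        for r in range(1, n_rep + 1):
            cols.append(f"{tp}_{tr}_{r}")
            rows.append((f"{tp}_{tr}_{r}", tp, tr, r))
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    vals = pd.DataFrame(values, index=gene_ids, columns=cols)
    det = pd.DataFrame(True, index=vals.index, columns=vals.columns)
    sheet = pa.SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "timepoint", "treatment", "replicate"]),
        strict=False)
    return pa.ExpressionMatrix(vals, det), sheet
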