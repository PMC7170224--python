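"""Soft-power choice, topological overlap, module cutting, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import phytoarray as pa
from phytoarray.coexpression import adjacency_matrix, scale_free_fit


def latent_factor_data(n_factors=3, genes_per_factor=15, n_noise=30,
                       n_samples=20, within_r=0.9, seed=9):
    """Blocks of genes driven by shared latent factors, plus noise genes."""
    rng = np.random.default_rng(seed)
    lam = np.sqrt(within_r)
    blocks, truth = [], []
    for b in range(n_factors):
        f = rng.normal(size=n_samples)
        g = lam * f + np.sqrt(1 - lam ** 2) * rng.normal(
            size=(genes_per_factor, n_samples))
        blocks.append(g)
        truth += [b + 1] * genes_per_factor
    blocks.append(rng.normal(size=(n_noise, n_samples)))
    truth += [0] * n_noise
    x = pd.DataFrame(np.vstack(blocks),
                     index=[f"g{i}" for i in range(len(truth))])
    return x, np.array(truth)


class TestSoftPower:
    def test_matches_exhaustive_scan(self):
        """The chosen power equals an independent scan over the same
        candidates: smallest beta with fit >= target, else argmax."""
        x, _ = latent_factor_data(seed=5)
        beta, r2 = pa.pick_soft_power(x, target_r2=0.8)
        r = np.abs(np.corrcoef(x.to_numpy()))
        np.fill_diagonal(r, 0.0)
        fits = {b: scale_free_fit((r ** b).sum(axis=1)) for b in range(1, 21)}
        reaching = [b for b, f in fits.items() if f >= 0.8]
        expected = min(reaching) if reaching else max(fits, key=fits.get)
        assert beta == expected
        assert r2 == pytest.approx(fits[expected])
        # reproducible
        assert pa.pick_soft_power(x, target_r2=0.8) == (beta, r2)

    def test_duplicate_genes_have_unit_adjacency(self):
        x = pd.DataFrame([[1.0, 2, 3, 4, 5]] * 2, index=["a", "b"])
        for beta in (1, 6, 12):
            assert adjacency_matrix(x, beta)[0, 1] == pytest.approx(1.0)

    def test_mean_adjacency_decreases_with_beta(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(40, 200)))
        means = []
        for beta in (1, 2, 4, 8):
            a = adjacency_matrix(x, beta)
            means.append(a[np.triu_indices(40, 1)].mean())
        assert all(np.diff(means) < 0)

    def test_too_few_samples_rejected(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5)))
        with pytest.raises(ValueError, match="samples"):
            pa.pick_soft_power(x)


def tom_oracle(a):
    """Triple-loop topological overlap, straight from the definition."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n)
                         if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTOM:
    def test_two_gene_network(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        tom = pa.compute_tom(a)
        # no shared neighbors: 0.5 / (0.5 + 1 - 0.5)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_identical_rows_with_unit_link(self):
        # identical (binary) neighborhoods plus a_ij = 1: maximal overlap
        a = np.array([[1.0, 1.0, 1.0, 0.0],
                      [1.0, 1.0, 1.0, 0.0],
                      [1.0, 1.0, 1.0, 0.0],
                      [0.0, 0.0, 0.0, 1.0]])
        tom = pa.compute_tom(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(6)
        half = rng.random((6, 6))
        a = (half + half.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.allclose(pa.compute_tom(a), tom_oracle(a), atol=1e-12)

    def test_bounds_symmetry_diagonal(self):
        rng = np.random.default_rng(7)
        half = rng.random((15, 15))
        a = (half + half.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = pa.compute_tom(a)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1).all()
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pa.compute_tom(np.array([[1.0, 0.2], [0.4, 1.0]]))


class TestCutModules:
    def test_duplicated_blocks_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = np.tile(rng.normal(size=20), (12, 1))
        b = np.tile(rng.normal(size=20), (12, 1))
        x = pd.DataFrame(np.vstack([a, b])
                         + rng.normal(0, 1e-6, (24, 20)),
                         index=[f"g{i}" for i in range(24)])
        mods = pa.detect_modules(x, min_module_size=10)
        labels = mods.labels.to_numpy()
        assert len(set(labels[:12])) == 1 and labels[0] > 0
        assert len(set(labels[12:])) == 1 and labels[12] > 0
        assert labels[0] != labels[12]

    def test_independent_genes_unassigned(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(60, 20)),
                         index=[f"g{i}" for i in range(60)])
        mods = pa.detect_modules(x, min_module_size=10)
        assert (mods.labels == 0).mean() > 0.9

    def test_three_block_recovery_ari(self):
        """Three implanted correlation blocks (r = 0.9 within, 0 between,
        15 genes each): adjusted Rand index vs truth >= 0.8."""
        x, truth = latent_factor_data(seed=9)
        mods = pa.detect_modules(x, min_module_size=10)
        assert adjusted_rand_score(truth, mods.labels.to_numpy()) >= 0.8


class TestEigengene:
    def test_identical_genes_give_standardized_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = pd.DataFrame([profile] * 4, index=list("abcd"))
        eig = pa.module_eigengene(x, x.index)
        z = (profile - profile.mean()) / profile.std()
        expected = z / np.linalg.norm(z)
        assert np.allclose(eig.to_numpy(), expected, atol=1e-9)

    def test_sign_fixed_to_mean_profile(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(6, 15)))
        eig = pa.module_eigengene(x, x.index)
        mean_profile = x.mean(axis=0)
        assert np.corrcoef(eig, mean_profile)[0, 1] > 0

    def test_anticorrelated_pair(self):
        profile = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        x = pd.DataFrame([profile, -profile], index=["a", "b"])
        eig = pa.module_eigengene(x, x.index)
        for g in ("a", "b"):
            r = np.corrcoef(eig, x.loc[g])[0, 1]
            assert abs(r) == pytest.approx(1.0)

    def test_unit_norm(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(8, 12)))
        eig = pa.module_eigengene(x, x.index)
        assert np.linalg.norm(eig) == pytest.approx(1.0)


class TestUrtaScenario:
    def test_urta_block_is_one_clean_module(self, default_sim, default_expr):
        """The cross-strain urtA response lands in a single module nearly
        free of other N-stress genes — the network restatement of a
        transporter regulated independently of the rest of the regulon."""
        design, _m, sheet, _truth = default_sim
        t24 = sheet.samples.loc[sheet.samples["timepoint"] == "T24",
                                "sample_id"].tolist()
        frac = default_expr.detected[t24].mean(axis=1)
        genes = frac.index[frac >= 0.75]
        mods = pa.detect_modules(default_expr.values.loc[genes, t24])
        ann = design.target_annotation()
        pico = ("HL_Pro", "LL_Pro", "Synechococcus")
        urta = [g for g in genes
                if ann.loc[g, "gene"] == "urtA"
                and ann.loc[g, "phylogroup"] in pico]
        labels = mods.labels
        urta_mods = labels.loc[urta]
        main = urta_mods.mode()[0]
        assert main > 0
        assert (urta_mods == main).mean() >= 0.9
        in_module = labels.index[labels == main]
        nstress = [g for g in in_module
                   if ann.loc[g, "gene"] in pa.GENE_SETS["N stress"]
                   and ann.loc[g, "gene"] != "urtA"]
        assert len(nstress) / len(in_module) < 0.10
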