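"""Spatial test: kernel, marginal likelihood, per-gene fit, scan, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, spearmanr

import scfuse as sf
from scfuse.errors import EmptyResultError, ParameterError, ValidationError
from scfuse.visgp import (
    LengthscaleCache,
    VisgpConfig,
    default_lengthscale_grid,
    results_to_frame,
)


# ---------------------------------------------------------------- kernel

def test_se_kernel_unit_diagonal_and_plugin_value():
    coords = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
    K = sf.se_kernel(coords, lengthscale=5.0)
    np.testing.assert_allclose(np.diag(K), 1.0)
    np.testing.assert_allclose(K[0, 1], np.exp(-0.5))
    with pytest.raises(ParameterError):
        sf.se_kernel(coords, 0.0)


def test_se_kernel_positive_semidefinite():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 10, (30, 2))
    K = sf.se_kernel(coords, 2.0)
    eigmin = np.linalg.eigvalsh(K + 1e-6 * np.eye(30)).min()
    assert eigmin >= 0


# ---------------------------------------------------------------- marginal

def test_gp_log_marginal_reduces_to_iid_normal():
    rng = np.random.default_rng(1)
    y = rng.normal(2.0, 1.5, 12)
    K = sf.se_kernel(rng.uniform(0, 5, (12, 2)), 1.0)
    got = sf.gp_log_marginal(y, K, sigma2_s=0.0, sigma2_n=1.5**2, mu=2.0, jitter=0)
    expected = norm.logpdf(y, 2.0, 1.5).sum()
    np.testing.assert_allclose(got, expected, atol=1e-8)


def test_gp_log_marginal_matches_dense_oracle():
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 5, (5, 2))
    y = rng.normal(size=5)
    K = sf.se_kernel(coords, 1.3)
    s2, n2, mu = 0.7, 0.4, 0.2
    Sigma = s2 * K + n2 * np.eye(5)
    r = y - mu
    naive = -0.5 * (
        r @ np.linalg.inv(Sigma) @ r
        + np.log(np.linalg.det(Sigma))
        + 5 * np.log(2 * np.pi)
    )
    got = sf.gp_log_marginal(y, K, s2, n2, mu, jitter=0)
    np.testing.assert_allclose(got, naive, atol=1e-8)


def test_gp_log_marginal_relabeling_invariant():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 5, (8, 2))
    y = rng.normal(size=8)
    K = sf.se_kernel(coords, 1.0)
    perm = rng.permutation(8)
    a = sf.gp_log_marginal(y, K, 0.5, 0.5, 0.0)
    b = sf.gp_log_marginal(y[perm], K[np.ix_(perm, perm)], 0.5, 0.5, 0.0)
    np.testing.assert_allclose(a, b, atol=1e-9)


# ---------------------------------------------------------------- fit_gene

def test_constant_gene_is_degenerate(grid_coords):
    res = sf.fit_gene(np.full(100, 3.0), grid_coords)
    assert res.llr == 0.0 and res.p == 1.0 and res.degenerate


def test_fit_gene_affine_and_rigid_invariance(grid_coords):
    rng = np.random.default_rng(4)
    y = grid_coords[:, 0] / 9.0 + rng.normal(0, 0.7, 100)
    base = sf.fit_gene(y, grid_coords)
    scaled = sf.fit_gene(5.0 * y - 2.0, grid_coords)
    np.testing.assert_allclose(scaled.llr, base.llr, atol=1e-6)
    # rigid rotation + translation of coordinates
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved = grid_coords @ R.T + np.array([3.0, -1.0])
    rot = sf.fit_gene(y, moved, VisgpConfig(
        lengthscale_grid=default_lengthscale_grid(grid_coords)))
    np.testing.assert_allclose(rot.llr, base.llr, rtol=1e-4, atol=1e-5)


def test_fit_gene_detects_planted_gp_signal(grid_coords):
    grid = default_lengthscale_grid(grid_coords)
    K = sf.se_kernel(grid_coords, grid[4])
    L = np.linalg.cholesky(0.9 * K + 0.1 * np.eye(100) + 1e-9 * np.eye(100))
    hits = 0
    for s in range(5):
        y = L @ np.random.default_rng(50 + s).standard_normal(100)
        res = sf.fit_gene(y, grid_coords)
        step = int(np.argmin(np.abs(grid - res.lengthscale)))
        if abs(step - 4) <= 1 and res.fsv >= 0.5 and res.p < 0.01:
            hits += 1
    assert hits >= 4


def test_mixture_p_monotone_in_llr():
    from scipy.stats import chi2

    llrs = np.linspace(0.01, 20, 50)
    ps = 0.5 * chi2.sf(2 * llrs, df=1)
    assert np.all(np.diff(ps) < 0)


def test_permutation_and_mixture_p_rank_concordantly(grid_coords):
    cache = LengthscaleCache(grid_coords, default_lengthscale_grid(grid_coords))
    rng = np.random.default_rng(5)
    pm, pp = [], []
    cfg_m = VisgpConfig()
    cfg_p = VisgpConfig(p_mode="permutation", n_permutations=60)
    for g in range(12):
        amp = 0.25 * (g % 4)
        y = amp * np.sin(grid_coords[:, 0]) + rng.standard_normal(100)
        pm.append(sf.fit_gene(y, grid_coords, cfg_m, _cache=cache).p)
        pp.append(sf.fit_gene(y, grid_coords, cfg_p, seed=g, _cache=cache).p)
    rho = spearmanr(pm, pp).statistic
    assert rho >= 0.9


# ---------------------------------------------------------------- BH

def test_bh_examples():
    np.testing.assert_allclose(
        sf.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
    )
    np.testing.assert_allclose(sf.bh_adjust([0.2]), [0.2])


def test_bh_matches_stepup_definition():
    rng = np.random.default_rng(6)
    p = rng.uniform(1e-6, 1.0, 100)
    got = sf.bh_adjust(p)
    m = len(p)
    order = np.argsort(p)
    expected = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        j = order[rank_from_top - 1]
        running = min(running, m * p[j] / rank_from_top)
        expected[j] = running
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        sf.bh_adjust([0.0, 0.5])


# ---------------------------------------------------------------- run_visgp

def _spatial_ds(counts, coords):
    n, g = counts.shape
    return sf.OmicsDataset(
        counts=counts,
        obs_names=pd.Index([f"s{i}" for i in range(n)]),
        var_names=pd.Index([f"g{j}" for j in range(g)]),
        modality="spatial",
        coords=coords,
    )


def test_run_visgp_constant_genes_all_null(grid_coords):
    counts = np.full((100, 20), 4.0)
    results = sf.run_visgp(_spatial_ds(counts, grid_coords))
    assert len(results) == 20
    assert all(r.p == 1.0 and r.q == 1.0 for r in results)


def test_run_visgp_output_sorted_and_counts_filtered(grid_coords):
    rng = np.random.default_rng(7)
    counts = rng.poisson(2.0, (100, 30)).astype(float)
    counts[:, 5] = 0.0  # total 0 < 10: filtered out
    results = sf.run_visgp(_spatial_ds(counts, grid_coords), seed=1)
    assert len(results) == 29
    ps = [r.p for r in results]
    assert ps == sorted(ps)
    frame = results_to_frame(results)
    assert set(frame.columns) == {
        "gene", "llr", "lengthscale", "fsv", "pval", "qval", "significant"
    }


def test_run_visgp_requires_coords_and_counts(grid_coords):
    counts = np.ones((100, 5))
    ds = _spatial_ds(counts, grid_coords)
    ds.coords = None
    with pytest.raises(ValidationError):
        sf.run_visgp(ds)


def test_run_visgp_detects_planted_pattern_genes(spatial_sim):
    ds, truth = spatial_sim
    results = sf.run_visgp(ds, seed=0)
    sig = {r.gene for r in results if r.q < 0.05}
    sv = {f"g{j}" for j in np.where(truth.sv_mask)[0]}
    # strong (periodic) patterns are always found; false positives stay rare
    periodic = {g for g, k in truth.pattern_kind.items() if k == "periodic"}
    assert periodic <= sig
    assert len(sig - sv) <= 5
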