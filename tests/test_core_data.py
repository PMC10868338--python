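"""Container invariants, readers/writers, and preprocessing operations."""

import os

import numpy as np
import pandas as pd
import pytest
import scipy.io
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import scfuse as sf
from scfuse.errors import (
    EmptyResultError,
    FormatError,
    ParameterError,
    ValidationError,
)


# ---------------------------------------------------------------- readers

def test_csv_reader_shape_and_names(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("cell,g1,g2\nc1,1,2\nc2,3,4\nc3,5,6\n")
    ds = sf.read_dataset(str(path), "csv")
    assert ds.shape == (3, 2)
    assert list(ds.obs_names) == ["c1", "c2", "c3"]
    assert list(ds.var_names) == ["g1", "g2"]
    assert ds.layer_state == "counts"


def test_csv_negative_value_rejected(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("cell,g1\nc1,-1\n")
    with pytest.raises(ValidationError):
        sf.read_dataset(str(path), "csv")


def test_mtx_dir_is_transposed_to_cells_by_features(tmp_path):
    # on-disk triplets are features x cells (3 features, 2 cells)
    M = sp.coo_matrix(np.array([[1, 0], [2, 3], [0, 4]], dtype=float))
    scipy.io.mmwrite(str(tmp_path / "matrix.mtx"), M)
    (tmp_path / "features.tsv").write_text("f1\nf2\nf3\n")
    (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
    ds = sf.read_dataset(str(tmp_path), "mtx_dir")
    assert ds.shape == (2, 3)
    assert ds.counts[1, 2] == 4  # cell c2, feature f3


def test_mtx_dimension_mismatch_names_both_lengths(tmp_path):
    M = sp.coo_matrix(np.ones((3, 2)))
    scipy.io.mmwrite(str(tmp_path / "matrix.mtx"), M)
    (tmp_path / "features.tsv").write_text("f1\nf2\n")  # wrong: 2 names, 3 rows
    (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
    with pytest.raises(FormatError, match="2"):
        sf.read_dataset(str(tmp_path), "mtx_dir")


def test_tenx_h5_roundtrip_orientation(tmp_path):
    import h5py

    X = np.array([[0, 1, 2], [3, 0, 0]], dtype=float)  # 2 features x 3 cells
    csc = sp.csc_matrix(X)
    path = tmp_path / "m.h5"
    with h5py.File(path, "w") as f:
        g = f.create_group("matrix")
        g.create_dataset("data", data=csc.data)
        g.create_dataset("indices", data=csc.indices)
        g.create_dataset("indptr", data=csc.indptr)
        g.create_dataset("shape", data=np.array(csc.shape))
        g.create_dataset("barcodes", data=np.array([b"c1", b"c2", b"c3"]))
        fg = g.create_group("features")
        fg.create_dataset("name", data=np.array([b"f1", b"f2"]))
    ds = sf.read_dataset(str(path), "tenx_h5")
    assert ds.shape == (3, 2)
    np.testing.assert_array_equal(ds.counts, X.T)


def test_duplicate_obs_names_rejected():
    with pytest.raises(ValidationError, match="duplicate"):
        sf.OmicsDataset(
            counts=np.ones((2, 1)),
            obs_names=pd.Index(["a", "a"]),
            var_names=pd.Index(["g"]),
        )


def test_coords_must_be_two_columns():
    with pytest.raises(ValidationError):
        sf.OmicsDataset(
            counts=np.ones((2, 1)),
            obs_names=pd.Index(["a", "b"]),
            var_names=pd.Index(["g"]),
            coords=np.ones((2, 3)),
        )


# ---------------------------------------------------------------- round trips

def test_h5ad_roundtrip_bit_exact(tiny_dataset, tmp_path):
    path = str(tmp_path / "x.h5ad")
    sf.write_h5ad(tiny_dataset, path)
    back = sf.read_dataset(path, "h5ad")
    assert np.array_equal(back.counts, tiny_dataset.counts)
    assert list(back.obs_names) == list(tiny_dataset.obs_names)
    assert list(back.var_names) == list(tiny_dataset.var_names)
    assert list(back.batch) == list(tiny_dataset.batch)
    assert np.array_equal(back.coords, tiny_dataset.coords)
    assert back.layer_state == tiny_dataset.layer_state
    assert back.modality == tiny_dataset.modality


def test_csv_roundtrip_exact(tiny_dataset, tmp_path):
    path = str(tmp_path / "x.csv")
    sf.write_csv(tiny_dataset, path)
    back = sf.read_dataset(path, "csv")
    assert np.allclose(back.counts, tiny_dataset.counts, atol=1e-12)
    assert list(back.obs_names) == list(tiny_dataset.obs_names)


# ---------------------------------------------------------------- filters

def test_filter_features_examples():
    ds = sf.OmicsDataset(
        counts=np.array([[5.0, 0.0, 12.0], [3.0, 0.0, 4.0]]),
        obs_names=pd.Index(["a", "b"]),
        var_names=pd.Index(["g1", "g2", "g3"]),
    )
    out = sf.filter_features(ds, 10)
    assert list(out.var_names) == ["g3"]  # totals 8, 0, 16
    # threshold 0 keeps everything
    assert sf.filter_features(ds, 0).n_vars == 3


def test_filter_features_matches_bruteforce():
    rng = np.random.default_rng(1)
    X = rng.poisson(0.5, (20, 200)).astype(float)
    ds = sf.OmicsDataset(
        counts=X,
        obs_names=pd.Index([f"c{i}" for i in range(20)]),
        var_names=pd.Index([f"g{j}" for j in range(200)]),
    )
    out = sf.filter_features(ds, 10)
    keep = [j for j in range(200) if sum(X[i, j] for i in range(20)) >= 10]
    assert list(out.var_names) == [f"g{j}" for j in keep]


def test_filter_features_idempotent():
    rng = np.random.default_rng(2)
    ds = sf.OmicsDataset(
        counts=rng.poisson(1.0, (10, 30)).astype(float),
        obs_names=pd.Index([f"c{i}" for i in range(10)]),
        var_names=pd.Index([f"g{j}" for j in range(30)]),
    )
    once = sf.filter_features(ds, 8)
    twice = sf.filter_features(once, 8)
    assert list(once.var_names) == list(twice.var_names)


def test_filter_observations_examples_and_coords_lockstep():
    ds = sf.OmicsDataset(
        counts=np.array([[5.0, 0.0], [0.0, 0.0], [7.0, 8.0]]),
        obs_names=pd.Index(["a", "b", "c"]),
        var_names=pd.Index(["g1", "g2"]),
        coords=np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]),
    )
    out = sf.filter_observations(ds, 5)
    assert list(out.obs_names) == ["a", "c"]
    np.testing.assert_array_equal(out.coords, [[0.0, 0.0], [2.0, 2.0]])
    zeros = sf.OmicsDataset(
        counts=np.zeros((2, 2)),
        obs_names=pd.Index(["a", "b"]),
        var_names=pd.Index(["g1", "g2"]),
    )
    with pytest.raises(EmptyResultError, match="1"):
        sf.filter_observations(zeros, 1)


def test_filter_observations_matches_bruteforce():
    rng = np.random.default_rng(3)
    X = rng.poisson(0.3, (100, 50)).astype(float)
    ds = sf.OmicsDataset(
        counts=X,
        obs_names=pd.Index([f"c{i}" for i in range(100)]),
        var_names=pd.Index([f"g{j}" for j in range(50)]),
    )
    out = sf.filter_observations(ds, 10)
    keep = [i for i in range(100) if X[i].sum() >= 10]
    assert list(out.obs_names) == [f"c{i}" for i in keep]


# ---------------------------------------------------------------- normalize

def test_normalize_log_closed_form_and_zero_row():
    ds = sf.OmicsDataset(
        counts=np.array([[2.0, 2.0], [0.0, 0.0]]),
        obs_names=pd.Index(["a", "b"]),
        var_names=pd.Index(["g1", "g2"]),
    )
    out = sf.normalize_log(ds, target_sum=4)
    np.testing.assert_allclose(out.counts[0], [np.log(3), np.log(3)])
    np.testing.assert_array_equal(out.counts[1], [0.0, 0.0])
    assert out.layer_state == "lognorm"
    with pytest.raises(ParameterError):
        sf.normalize_log(ds, target_sum=0)


def test_normalize_log_inverse_row_sums():
    rng = np.random.default_rng(4)
    X = rng.poisson(2.0, (15, 8)).astype(float)
    X[3] = 0
    ds = sf.OmicsDataset(
        counts=X,
        obs_names=pd.Index([f"c{i}" for i in range(15)]),
        var_names=pd.Index([f"g{j}" for j in range(8)]),
    )
    out = sf.normalize_log(ds, target_sum=100.0)
    sums = (np.exp(out.counts) - 1).sum(axis=1)
    nonzero = X.sum(axis=1) > 0
    np.testing.assert_allclose(sums[nonzero], 100.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    scale=st.floats(min_value=0.1, max_value=50.0),
    row=st.lists(st.integers(min_value=0, max_value=30), min_size=3, max_size=8),
)
def test_normalize_log_scale_invariant(scale, row):
    """Row c*x and x map to the same log-normalized values for any c > 0."""
    base = np.array([row, row], dtype=float)
    base[1] *= scale
    ds = sf.OmicsDataset(
        counts=base,
        obs_names=pd.Index(["a", "b"]),
        var_names=pd.Index([f"g{j}" for j in range(base.shape[1])]),
    )
    out = sf.normalize_log(ds, target_sum=10.0)
    np.testing.assert_allclose(out.counts[0], out.counts[1], atol=1e-9)


# ---------------------------------------------------------------- hvg

def test_select_hvg_prefers_variable_feature():
    rng = np.random.default_rng(5)
    X = np.column_stack([np.full(30, 5.0), rng.poisson(5.0, 30).astype(float)])
    ds = sf.OmicsDataset(
        counts=X,
        obs_names=pd.Index([f"c{i}" for i in range(30)]),
        var_names=pd.Index(["flat", "wiggly"]),
    )
    out = sf.select_hvg(ds, 1)
    assert list(out.var_names) == ["wiggly"]
    assert set(sf.select_hvg(ds, 2).var_names) == {"flat", "wiggly"}
    with pytest.raises(ParameterError):
        sf.select_hvg(ds, 3)


def test_select_hvg_matches_bruteforce_dispersion_sort():
    rng = np.random.default_rng(6)
    X = rng.poisson(rng.uniform(0.5, 8.0, 100), (40, 100)).astype(float)
    ds = sf.OmicsDataset(
        counts=X,
        obs_names=pd.Index([f"c{i}" for i in range(40)]),
        var_names=pd.Index([f"g{j}" for j in range(100)]),
    )
    L = sf.normalize_log(ds).counts
    disp = np.where(L.mean(0) > 0, L.var(0) / np.where(L.mean(0) > 0, L.mean(0), 1), 0)
    expected = set(
        ds.var_names[j] for j in sorted(range(100), key=lambda j: (-disp[j], j))[:25]
    )
    assert set(sf.select_hvg(ds, 25).var_names) == expected


# ---------------------------------------------------------------- concatenate

def _mk(names, vals, obs_prefix):
    vals = np.asarray(vals, dtype=float)
    return sf.OmicsDataset(
        counts=vals,
        obs_names=pd.Index([f"{obs_prefix}{i}" for i in range(vals.shape[0])]),
        var_names=pd.Index(names),
    )


def test_concatenate_intersection_keeps_first_order():
    d1 = _mk(["A", "B", "C"], np.arange(6).reshape(2, 3), "x")
    d2 = _mk(["B", "C", "D"], np.arange(9).reshape(3, 3), "y")
    out = sf.concatenate([d1, d2])
    assert list(out.var_names) == ["B", "C"]
    assert out.n_obs == 5
    assert set(out.batch) == {"0", "1"}


def test_concatenate_disjoint_features_error():
    d1 = _mk(["A"], [[1.0]], "x")
    d2 = _mk(["B"], [[1.0]], "y")
    with pytest.raises(EmptyResultError):
        sf.concatenate([d1, d2])


def test_concatenate_split_recovers_inputs():
    rng = np.random.default_rng(7)
    d1 = _mk(["A", "B", "C"], rng.poisson(3.0, (4, 3)), "x")
    d2 = _mk(["A", "B", "C"], rng.poisson(3.0, (6, 3)), "y")
    out = sf.concatenate([d1, d2])
    for label, src in (("0", d1), ("1", d2)):
        mask = out.batch == label
        np.testing.assert_array_equal(out.counts[mask], src.counts)
        assert list(out.obs_names[mask]) == list(src.obs_names)
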