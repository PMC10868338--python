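"""Annotated cell-by-feature container and preprocessing primitives.

The :class:`OmicsDataset` is the interchange currency of the whole package:
every model consumes one (or several), and every reader produces one.  Cells
are *always* rows, features *always* columns, regardless of the on-disk
orientation of the source format.  A ``layer_state`` flag records whether the
matrix still holds raw counts or has been library-size normalized and
log-transformed.

Supported input formats
-----------------------
``mtx_dir``
    A directory with ``matrix.mtx`` (Matrix Market triplets, features x cells
    as emitted by common pipelines), ``features.tsv``/``genes.tsv`` and
    ``barcodes.tsv``.
``csv``
    Dense comma-separated table; first row feature names, first column cell
    names.
``tenx_h5``
    HDF5 file holding a CSC matrix (cells in columns on disk) under a group
    with ``data``/``indices``/``indptr``/``shape`` plus barcode and feature
    name arrays.
``h5ad``
    The annotated-matrix HDF5 dialect shared with the scanpy ecosystem; read
    and written through :mod:`anndata`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    EmptyResultError,
    FormatError,
    ParameterError,
    ValidationError,
)

MODALITIES = ("rna", "atac", "protein", "spatial")


@dataclass
class OmicsDataset:
    """Cell-by-feature matrix with batch labels and optional spatial coordinates.

    Parameters
    ----------
    counts
        Dense ``(n_obs, n_vars)`` float array.  Non-negative when
        ``layer_state == "counts"``.
    obs_names, var_names
        Unique cell and feature identifiers.
    batch
        Per-cell categorical batch/dataset annotation (the decoder condition
        of the conditional integration model).
    modality
        One of ``rna | atac | protein | spatial``.
    coords
        Optional ``(n_obs, 2)`` spatial coordinates (spots).
    layer_state
        ``"counts"`` for raw counts, ``"lognorm"`` after
        :func:`normalize_log`.
    """

    counts: np.ndarray
    obs_names: pd.Index
    var_names: pd.Index
    batch: np.ndarray = None  # type: ignore[assignment]
    modality: str = "rna"
    coords: Optional[np.ndarray] = None
    layer_state: str = "counts"
    obs_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    var_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        self.obs_names = pd.Index(self.obs_names).astype(str)
        self.var_names = pd.Index(self.var_names).astype(str)
        n, p = self.counts.shape
        if len(self.obs_names) != n:
            raise FormatError(
                f"matrix has {n} rows but {len(self.obs_names)} cell names"
            )
        if len(self.var_names) != p:
            raise FormatError(
                f"matrix has {p} columns but {len(self.var_names)} feature names"
            )
        if self.obs_names.has_duplicates:
            dups = self.obs_names[self.obs_names.duplicated()].unique()[:3]
            raise ValidationError(f"duplicate cell names: {list(dups)}")
        if self.var_names.has_duplicates:
            dups = self.var_names[self.var_names.duplicated()].unique()[:3]
            raise ValidationError(f"duplicate feature names: {list(dups)}")
        if self.batch is None:
            self.batch = np.repeat("0", n)
        self.batch = np.asarray(self.batch, dtype=object).astype(str)
        if self.batch.shape != (n,):
            raise ValidationError("batch annotation length must equal cell count")
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality {self.modality!r} not in {MODALITIES}"
            )
        if self.layer_state not in ("counts", "lognorm"):
            raise ValidationError(f"unknown layer_state {self.layer_state!r}")
        if self.layer_state == "counts" and np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative entry {self.counts[i, j]} at cell {i}, feature {j}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.ndim != 2 or self.coords.shape[1] != 2:
                raise ValidationError("coords must be a cells x 2 matrix")
            if self.coords.shape[0] != n:
                raise ValidationError("coords row count must equal cell count")
            if not np.all(np.isfinite(self.coords)):
                raise ValidationError("coords contain missing/non-finite values")

    # ------------------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_vars(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_obs(self, mask_or_idx) -> "OmicsDataset":
        idx = np.asarray(mask_or_idx)
        return OmicsDataset(
            counts=self.counts[idx],
            obs_names=self.obs_names[idx],
            var_names=self.var_names,
            batch=self.batch[idx],
            modality=self.modality,
            coords=None if self.coords is None else self.coords[idx],
            layer_state=self.layer_state,
            obs_meta=self.obs_meta.iloc[idx].reset_index(drop=True)
            if len(self.obs_meta)
            else pd.DataFrame(),
            var_meta=self.var_meta.copy(),
        )

    def subset_vars(self, mask_or_idx) -> "OmicsDataset":
        idx = np.asarray(mask_or_idx)
        return OmicsDataset(
            counts=self.counts[:, idx],
            obs_names=self.obs_names,
            var_names=self.var_names[idx],
            batch=self.batch,
            modality=self.modality,
            coords=self.coords,
            layer_state=self.layer_state,
            obs_meta=self.obs_meta.copy(),
            var_meta=self.var_meta.iloc[idx].reset_index(drop=True)
            if len(self.var_meta)
            else pd.DataFrame(),
        )

    # ----------------------------- interop ----------------------------
    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(index=self.obs_names.copy())
        obs["batch"] = pd.Categorical(self.batch)
        for c in self.obs_meta.columns:
            obs[c] = np.asarray(self.obs_meta[c])
        var = pd.DataFrame(index=self.var_names.copy())
        for c in self.var_meta.columns:
            var[c] = np.asarray(self.var_meta[c])
        adata = ad.AnnData(X=self.counts.copy(), obs=obs, var=var)
        adata.uns["layer_state"] = self.layer_state
        adata.uns["modality"] = self.modality
        if self.coords is not None:
            adata.obsm["spatial"] = self.coords.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "OmicsDataset":
        X = adata.X
        if sp.issparse(X):
            X = np.asarray(X.todense())
        X = np.asarray(X, dtype=np.float64)
        batch = (
            np.asarray(adata.obs["batch"]).astype(str)
            if "batch" in adata.obs
            else None
        )
        obs_meta = adata.obs.drop(columns=["batch"], errors="ignore").reset_index(
            drop=True
        )
        return cls(
            counts=X,
            obs_names=pd.Index(adata.obs_names),
            var_names=pd.Index(adata.var_names),
            batch=batch,
            modality=str(adata.uns.get("modality", "rna")),
            coords=np.asarray(adata.obsm["spatial"])
            if "spatial" in adata.obsm
            else None,
            layer_state=str(adata.uns.get("layer_state", "counts")),
            obs_meta=obs_meta,
            var_meta=adata.var.reset_index(drop=True),
        )


# ======================================================================
# Readers / writers
# ======================================================================

def _read_names(path: str) -> pd.Index:
    tab = pd.read_csv(path, sep="\t", header=None)
    return pd.Index(tab.iloc[:, 0].astype(str))


def _read_mtx_dir(path: str) -> OmicsDataset:
    mtx_path = None
    for cand in ("matrix.mtx", "matrix.mtx.gz"):
        p = os.path.join(path, cand)
        if os.path.exists(p):
            mtx_path = p
            break
    if mtx_path is None:
        raise FormatError(f"no matrix.mtx found under {path}")
    feat_path = None
    for cand in ("features.tsv", "genes.tsv"):
        p = os.path.join(path, cand)
        if os.path.exists(p):
            feat_path = p
            break
    if feat_path is None:
        raise FormatError(f"no features.tsv/genes.tsv under {path}")
    bc_path = os.path.join(path, "barcodes.tsv")
    if not os.path.exists(bc_path):
        raise FormatError(f"no barcodes.tsv under {path}")

    M = scipy.io.mmread(mtx_path)
    M = np.asarray(sp.coo_matrix(M).todense(), dtype=np.float64)
    var_names = _read_names(feat_path)
    obs_names = _read_names(bc_path)
    # triplets are stored features x cells; flip to cells-as-rows
    if M.shape != (len(var_names), len(obs_names)):
        raise FormatError(
            f"matrix shape {M.shape} does not match {len(var_names)} features "
            f"x {len(obs_names)} barcodes"
        )
    return OmicsDataset(counts=M.T, obs_names=obs_names, var_names=var_names)


def _read_csv(path: str, sep: str = ",") -> OmicsDataset:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return OmicsDataset(
        counts=df.to_numpy(dtype=np.float64),
        obs_names=pd.Index(df.index.astype(str)),
        var_names=pd.Index(df.columns.astype(str)),
    )


def _read_tenx_h5(path: str) -> OmicsDataset:
    with h5py.File(path, "r") as f:
        group = None
        for key in f.keys():
            g = f[key]
            if isinstance(g, h5py.Group) and "data" in g and "indptr" in g:
                group = g
                break
        if group is None:
            raise FormatError(f"no CSC matrix group found in {path}")
        data = group["data"][:]
        indices = group["indices"][:]
        indptr = group["indptr"][:]
        shape = tuple(group["shape"][:])
        barcodes = [b.decode() if isinstance(b, bytes) else str(b)
                    for b in group["barcodes"][:]]
        if "features" in group:
            raw = group["features"]["name"][:]
        else:
            raw = group["gene_names"][:]
        features = [b.decode() if isinstance(b, bytes) else str(b) for b in raw]
    M = sp.csc_matrix((data, indices, indptr), shape=shape)
    M = np.asarray(M.todense(), dtype=np.float64)
    if M.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix shape {M.shape} does not match {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    return OmicsDataset(
        counts=M.T,
        obs_names=pd.Index(barcodes),
        var_names=pd.Index(features),
    )


def read_dataset(path: str, format: str) -> OmicsDataset:
    """Read a dataset from disk into an :class:`OmicsDataset` (cells as rows).

    ``format`` is one of ``mtx_dir | csv | tsv | tenx_h5 | h5ad``.
    """
    if not os.path.exists(path):
        raise FormatError(f"path does not exist: {path}")
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "csv":
        return _read_csv(path, sep=",")
    if format == "tsv":
        return _read_csv(path, sep="\t")
    if format == "tenx_h5":
        return _read_tenx_h5(path)
    if format == "h5ad":
        return OmicsDataset.from_anndata(ad.read_h5ad(path))
    raise ParameterError(f"unknown format {format!r}")


def write_h5ad(ds: OmicsDataset, path: str) -> None:
    """Write the dataset in the annotated-matrix HDF5 dialect (lossless)."""
    ds.to_anndata().write_h5ad(path)


def write_csv(ds: OmicsDataset, path: str) -> None:
    """Write the matrix as dense CSV (cells x features, 17 significant digits)."""
    df = pd.DataFrame(ds.counts, index=ds.obs_names, columns=ds.var_names)
    df.to_csv(path, float_format="%.17g")


# ======================================================================
# Preprocessing operations
# ======================================================================

def filter_features(ds: OmicsDataset, min_total_counts: float) -> OmicsDataset:
    """Keep features whose column total is >= ``min_total_counts``."""
    if min_total_counts < 0:
        raise ParameterError("min_total_counts must be non-negative")
    if ds.layer_state != "counts":
        raise ValidationError("filter_features requires the counts layer")
    keep = ds.counts.sum(axis=0) >= min_total_counts
    if not keep.any():
        raise EmptyResultError(
            f"no features with total counts >= {min_total_counts}"
        )
    return ds.subset_vars(keep)


def filter_observations(ds: OmicsDataset, min_total_counts: float) -> OmicsDataset:
    """Keep cells/spots whose row total is >= ``min_total_counts``; coords follow."""
    if min_total_counts < 0:
        raise ParameterError("min_total_counts must be non-negative")
    if ds.layer_state != "counts":
        raise ValidationError("filter_observations requires the counts layer")
    keep = ds.counts.sum(axis=1) >= min_total_counts
    if not keep.any():
        raise EmptyResultError(
            f"no cells with total counts >= {min_total_counts}"
        )
    return ds.subset_obs(keep)


def normalize_log(ds: OmicsDataset, target_sum: float = 1e4) -> OmicsDataset:
    """Library-size normalize each cell to ``target_sum`` total, then log(1+x).

    All-zero cells pass through unchanged (no division by zero).  Marks the
    result ``layer_state="lognorm"``.
    """
    if target_sum <= 0:
        raise ParameterError("target_sum must be positive")
    if ds.layer_state != "counts":
        raise ValidationError("normalize_log requires the counts layer")
    totals = ds.counts.sum(axis=1)
    scale = np.where(totals > 0, target_sum / np.where(totals > 0, totals, 1.0), 0.0)
    X = np.log1p(ds.counts * scale[:, None])
    out = OmicsDataset(
        counts=X,
        obs_names=ds.obs_names,
        var_names=ds.var_names,
        batch=ds.batch,
        modality=ds.modality,
        coords=ds.coords,
        layer_state="lognorm",
        obs_meta=ds.obs_meta.copy(),
        var_meta=ds.var_meta.copy(),
    )
    return out


def select_hvg(ds: OmicsDataset, n_top: int) -> OmicsDataset:
    """Keep the ``n_top`` features with highest variance-to-mean dispersion.

    Dispersion is computed on log-normalized values (computed on the fly when
    the input still holds raw counts).  Ties break toward earlier columns;
    surviving features keep their original relative order.
    """
    if n_top <= 0:
        raise ParameterError("n_top must be positive")
    if n_top > ds.n_vars:
        raise ParameterError(
            f"n_top={n_top} exceeds feature count {ds.n_vars}"
        )
    X = ds.counts if ds.layer_state == "lognorm" else normalize_log(ds).counts
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.argsort(-disp, kind="stable")[:n_top]
    keep = np.zeros(ds.n_vars, dtype=bool)
    keep[order] = True
    return ds.subset_vars(keep)


def concatenate(
    ds_list: Sequence[OmicsDataset], batch_key: str = "batch"
) -> OmicsDataset:
    """Row-stack datasets over the intersection of their feature names.

    The intersection keeps the first dataset's feature order.  The ``batch``
    column of the result is each dataset's position (``"0"``, ``"1"``, ...)
    unless the inputs already carry distinct batch labels, and is mirrored in
    ``obs_meta[batch_key]``.
    """
    if len(ds_list) < 2:
        raise ParameterError("concatenate needs at least 2 datasets")
    states = {d.layer_state for d in ds_list}
    if len(states) > 1:
        raise ValidationError(f"mixed layer states {states}")
    shared = ds_list[0].var_names
    for d in ds_list[1:]:
        shared = shared[shared.isin(d.var_names)]
    if len(shared) == 0:
        raise EmptyResultError(
            "feature intersection across datasets is empty; integration impossible"
        )
    blocks, names, labels = [], [], []
    own = [set(np.unique(d.batch)) for d in ds_list]
    distinct = all(len(s) >= 1 for s in own) and len(set().union(*own)) == sum(
        len(s) for s in own
    )
    for i, d in enumerate(ds_list):
        idx = d.var_names.get_indexer(shared)
        blocks.append(d.counts[:, idx])
        names.append(d.obs_names)
        labels.append(d.batch if distinct else np.repeat(str(i), d.n_obs))
    obs_names = pd.Index(np.concatenate([n.to_numpy() for n in names]))
    if obs_names.has_duplicates:
        raise ValidationError(
            "cell names collide across datasets; rename before concatenating"
        )
    batch = np.concatenate(labels)
    out = OmicsDataset(
        counts=np.vstack(blocks),
        obs_names=obs_names,
        var_names=shared,
        batch=batch,
        modality=ds_list[0].modality,
        layer_state=ds_list[0].layer_state,
        obs_meta=pd.DataFrame({batch_key: batch}),
    )
    return out
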