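"""Synthetic single-cell and spatial data with planted ground truth.

Every generator returns, alongside the dataset(s), a :class:`SimTruth`
carrying the planted structure (cell types, per-gene batch offsets, the
spatially-variable-gene mask), so integration and spatial-test quality can
be measured without external downloads.

Generative model for expression (unpaired and paired simulators):
per-gene base log-means are standard normal; each cell type perturbs a
random 20% of genes with Gaussian effects; each batch adds a Gaussian
per-gene offset; library sizes are log-normal (sigma = 0.3); counts are
negative binomial around exp(base + type + batch) * libsize with
inverse-dispersion 2 — typical scRNA-seq overdispersion.

Spatial simulator: spots form an integer lattice; spatially variable genes
receive one of three pattern functions on the log scale (a linear gradient,
a Gaussian hotspot, or a sinusoid along one axis), added to iid Gaussian
noise, exponentiated and Poisson-sampled; null genes get the noise only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_data import OmicsDataset
from .errors import ParameterError

NB_DISPERSION = 2.0
LIBSIZE_SIGMA = 0.3
TYPE_GENE_FRACTION = 0.2


@dataclass
class SimTruth:
    """Planted ground truth attached to a synthetic dataset."""

    cell_types: Optional[pd.Series] = None  # indexed by cell name
    batch_offsets: Optional[np.ndarray] = None  # batches x genes
    sv_mask: Optional[np.ndarray] = None  # per-gene bool, spatial sims only
    pattern_kind: Optional[Dict[str, str]] = None  # SV gene -> pattern name
    seed: int = 0

    def to_json(self) -> str:
        payload = {"seed": self.seed}
        if self.cell_types is not None:
            payload["cell_types"] = {
                str(k): str(v) for k, v in self.cell_types.items()
            }
        if self.batch_offsets is not None:
            payload["batch_offsets"] = self.batch_offsets.tolist()
        if self.sv_mask is not None:
            payload["sv_mask"] = [bool(b) for b in self.sv_mask]
        if self.pattern_kind is not None:
            payload["pattern_kind"] = self.pattern_kind
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            cell_types=pd.Series(d["cell_types"]) if "cell_types" in d else None,
            batch_offsets=np.asarray(d["batch_offsets"])
            if "batch_offsets" in d
            else None,
            sv_mask=np.asarray(d["sv_mask"], dtype=bool)
            if "sv_mask" in d
            else None,
            pattern_kind=d.get("pattern_kind"),
            seed=int(d.get("seed", 0)),
        )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
    """Negative binomial with fixed inverse-dispersion; Var = m + m^2/theta."""
    theta = NB_DISPERSION
    return rng.negative_binomial(theta, theta / (theta + mean)).astype(np.float64)


def _type_effects(
    rng: np.random.Generator,
    n_types: int,
    n_genes: int,
    sd: float,
    fraction: float = TYPE_GENE_FRACTION,
) -> np.ndarray:
    """Per-type gene effects: Gaussian on a random fraction of genes per type."""
    eff = np.zeros((n_types, n_genes))
    n_hit = max(1, int(round(fraction * n_genes)))
    for t in range(n_types):
        hit = rng.choice(n_genes, size=n_hit, replace=False)
        eff[t, hit] = rng.normal(0.0, sd, size=n_hit)
    return eff


def _assign_types(
    rng: np.random.Generator, n_cells: int, n_types: int
) -> np.ndarray:
    """Balanced type assignment, order shuffled."""
    types = np.arange(n_cells) % n_types
    rng.shuffle(types)
    return types


def simulate_batches(
    n_cells_per_batch: Sequence[int] = (500, 500),
    n_genes: int = 200,
    n_types: int = 3,
    batch_effect_sd: float = 0.5,
    type_effect_sd: float = 1.0,
    seed: int = 0,
) -> Tuple[List[OmicsDataset], SimTruth]:
    """Unpaired multi-batch counts sharing one latent cell population.

    Defaults emulate two technologies measuring the same tissue: a strong
    cell-type signal (effect sd 1.0 on 20% of genes per type) distorted by a
    moderate per-gene batch offset (sd 0.5).  Cell-type proportions are
    identical across batches.
    """
    if n_types < 2:
        raise ParameterError("need at least 2 cell types")
    if type_effect_sd <= 0:
        raise ParameterError("type_effect_sd must be positive")
    if batch_effect_sd < 0:
        raise ParameterError("batch_effect_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_batches = len(n_cells_per_batch)
    base = rng.normal(0.0, 1.0, n_genes)
    type_eff = _type_effects(rng, n_types, n_genes, type_effect_sd)
    batch_off = rng.normal(0.0, batch_effect_sd, (n_batches, n_genes))
    datasets: List[OmicsDataset] = []
    all_types, all_names = [], []
    for b, n_cells in enumerate(n_cells_per_batch):
        types = _assign_types(rng, n_cells, n_types)
        lib = rng.lognormal(0.0, LIBSIZE_SIGMA, n_cells)
        logmean = base[None, :] + type_eff[types] + batch_off[b][None, :]
        counts = _nb_sample(rng, np.exp(logmean) * lib[:, None])
        names = pd.Index([f"b{b}_c{i}" for i in range(n_cells)])
        datasets.append(
            OmicsDataset(
                counts=counts,
                obs_names=names,
                var_names=pd.Index([f"g{j}" for j in range(n_genes)]),
                batch=np.repeat(str(b), n_cells),
                modality="rna",
            )
        )
        all_types.append(types)
        all_names.append(names)
    truth = SimTruth(
        cell_types=pd.Series(
            np.concatenate([t.astype(str) for t in all_types]),
            index=pd.Index(np.concatenate([n.to_numpy() for n in all_names])),
        ),
        batch_offsets=batch_off,
        seed=seed,
    )
    return datasets, truth


def simulate_paired(
    n_cells: int = 500,
    n_genes_x: int = 200,
    n_genes_y: int = 60,
    n_types: int = 3,
    seed: int = 0,
) -> Tuple[OmicsDataset, OmicsDataset, SimTruth]:
    """Two paired views of the same cells driven by one latent type.

    Emulates a paired multi-modal assay: a transcriptome-wide view in which a
    random 20% of genes per type carry signal, and a smaller curated second
    view (an antibody/accessibility panel) in which half the features are
    type-discriminative — panels are selected to separate populations, so
    each view is individually informative about the latent type.
    """
    if n_types < 2:
        raise ParameterError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    types = _assign_types(rng, n_cells, n_types)
    names = pd.Index([f"c{i}" for i in range(n_cells)])
    views = []
    for n_genes, modality, tag, frac in (
        (n_genes_x, "rna", "x", TYPE_GENE_FRACTION),
        (n_genes_y, "atac", "y", 0.5),
    ):
        base = rng.normal(0.0, 1.0, n_genes)
        eff = _type_effects(rng, n_types, n_genes, 1.0, fraction=frac)
        lib = rng.lognormal(0.0, LIBSIZE_SIGMA, n_cells)
        counts = _nb_sample(
            rng, np.exp(base[None, :] + eff[types]) * lib[:, None]
        )
        views.append(
            OmicsDataset(
                counts=counts,
                obs_names=names,
                var_names=pd.Index([f"{tag}{j}" for j in range(n_genes)]),
                batch=np.repeat("0", n_cells),
                modality=modality,
            )
        )
    truth = SimTruth(
        cell_types=pd.Series(types.astype(str), index=names), seed=seed
    )
    return views[0], views[1], truth


_PATTERNS = ("gradient", "hotspot", "periodic")


def simulate_spatial(
    grid_side: int = 10,
    n_genes: int = 200,
    n_sv: int = 20,
    noise_sd: float = 1.0,
    amplitude: float = 2.0,
    seed: int = 0,
) -> Tuple[OmicsDataset, SimTruth]:
    """Lattice spatial counts with planted spatially-variable genes.

    Pattern functions (on the log scale, coordinates scaled to the unit
    square so the amplitude means the same thing at every grid size):
    gradient ``a*u1``, hotspot ``a*exp(-||s-c||^2 / (2 r^2))`` with r a
    quarter of the grid, periodic ``a*sin(4*pi*u1)`` (two full periods).
    """
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be positive")
    if n_sv > n_genes:
        raise ParameterError("n_sv cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    side = np.arange(grid_side, dtype=np.float64)
    xx, yy = np.meshgrid(side, side, indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    n_spots = coords.shape[0]
    u = coords / max(grid_side - 1, 1)
    center = np.full(2, (grid_side - 1) / 2.0)
    r = grid_side / 4.0

    log_expr = rng.normal(0.0, noise_sd, (n_spots, n_genes))
    sv_mask = np.zeros(n_genes, dtype=bool)
    pattern_kind: Dict[str, str] = {}
    sv_genes = rng.choice(n_genes, size=n_sv, replace=False) if n_sv else []
    for i, j in enumerate(sv_genes):
        kind = _PATTERNS[i % len(_PATTERNS)]
        if kind == "gradient":
            pat = amplitude * u[:, 0]
        elif kind == "hotspot":
            d2 = np.sum((coords - center) ** 2, axis=1)
            pat = amplitude * np.exp(-d2 / (2.0 * r**2))
        else:
            pat = amplitude * np.sin(4.0 * np.pi * u[:, 0])
        log_expr[:, j] += pat
        sv_mask[j] = True
        pattern_kind[f"g{j}"] = kind
    counts = rng.poisson(np.exp(log_expr)).astype(np.float64)
    ds = OmicsDataset(
        counts=counts,
        obs_names=pd.Index([f"s{i}" for i in range(n_spots)]),
        var_names=pd.Index([f"g{j}" for j in range(n_genes)]),
        batch=np.repeat("0", n_spots),
        modality="spatial",
        coords=coords,
    )
    truth = SimTruth(sv_mask=sv_mask, pattern_kind=pattern_kind, seed=seed)
    return ds, truth
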