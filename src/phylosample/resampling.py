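"""Column resampling of the supermatrix and the convergence experiment.

The experiment asks how much of a genome-scale supermatrix is needed before
the inferred topology stops changing: at each sampling effort (a fraction of
alignment columns) a fixed number of replicate matrices is drawn without
replacement, a tree is inferred from each with the configured engine, and
its normalized RF distance to the reference topology (the tree from the
complete supermatrix, inferred with the same engine) is recorded.  Columns
are drawn from the raw supermatrix, ignoring partition boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_io import GeneAlignment, SupermatrixBundle
from .synthetic_data import derive_seed
from .tree import PhyloTree
from .tree_compare import rf_distance
from .tree_infer import infer_tree


@dataclass
class ResamplingDesign:
    """Efforts (fractions of columns), replicate count, seed and engine."""

    efforts: Sequence[float] = (0.001, 0.01, 0.10, 0.20, 0.30)
    replicates: int = 30
    master_seed: int = 0
    engine: str = "nj"

    def __post_init__(self):
        efforts = list(self.efforts)
        if any(not 0 < e <= 1 for e in efforts):
            raise ValueError("efforts must lie in (0, 1]")
        if sorted(efforts) != efforts or len(set(efforts)) != len(efforts):
            raise ValueError("efforts must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.efforts = efforts


@dataclass
class ResampleRecord:
    effort: float
    replicate: int
    column_indices: np.ndarray
    tree: PhyloTree | None
    rf_to_reference: float | None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def _draw_indices(L: int, effort: float, rng_seed: int) -> np.ndarray:
    if not 0 < effort <= 1:
        raise ValueError("effort must be in (0, 1]")
    if L < 1:
        raise ValueError("empty supermatrix")
    n_cols = math.ceil(effort * L)
    rng = np.random.default_rng(rng_seed)
    return np.sort(rng.choice(L, size=n_cols, replace=False))


def resample_columns(
    bundle: SupermatrixBundle, effort: float, rng_seed: int
) -> GeneAlignment:
    """Draw ceil(effort·L) distinct columns uniformly without replacement.

    Columns are returned in original (sorted-index) order; deterministic for
    a given seed.
    """
    idx = _draw_indices(bundle.length, effort, rng_seed)
    return bundle.matrix.take_columns(idx, gene_id=f"resample_{effort:g}")


def run_convergence_experiment(
    bundle: SupermatrixBundle,
    reference: PhyloTree,
    design: ResamplingDesign,
) -> list[ResampleRecord]:
    """Subsample → infer → compare, for every (effort, replicate) cell.

    Per-replicate seeds derive deterministically from the design's master
    seed and the (effort index, replicate) pair.  An engine failure on one
    replicate flags that record and the experiment continues.
    """
    if not reference.leaf_set() <= set(bundle.taxa):
        raise ValueError("reference tree has taxa outside the supermatrix")
    records: list[ResampleRecord] = []
    for ei, effort in enumerate(design.efforts):
        for rep in range(design.replicates):
            seed = derive_seed(design.master_seed, ei, rep)
            idx = _draw_indices(bundle.length, effort, seed)
            sub = bundle.matrix.take_columns(idx, gene_id=f"resample_{effort:g}")
            try:
                tree = infer_tree(sub, engine=design.engine)
                _rf, nrf = rf_distance(tree, reference)
                records.append(ResampleRecord(effort, rep, idx, tree, nrf))
            except ValueError as exc:
                records.append(ResampleRecord(effort, rep, idx, None, None, error=str(exc)))
    return records


def records_to_frame(records: Sequence[ResampleRecord]) -> pd.DataFrame:
    """Tidy table of the experiment: one row per (effort, replicate)."""
    return pd.DataFrame(
        {
            "effort": [r.effort for r in records],
            "replicate": [r.replicate for r in records],
            "n_columns": [len(r.column_indices) for r in records],
            "rf_to_reference": [r.rf_to_reference for r in records],
            "failed": [r.failed for r in records],
            "error": [r.error for r in records],
        }
    )


def rf_groups(records: Sequence[ResampleRecord]) -> dict[float, list[float]]:
    """Per-effort lists of normalized RF distances (failed replicates dropped)."""
    groups: dict[float, list[float]] = {}
    for r in records:
        if not r.failed:
            groups.setdefault(r.effort, []).append(r.rf_to_reference)
    return groups
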