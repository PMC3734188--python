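"""Spectral count weight (SCW) normalization.

The SCW of a protein in one MS analysis is its spectral count divided by the
total spectral count of that analysis — a per-run relative abundance on the
simplex.  It corrects for unequal sampling depth between runs (e.g. one
group's runs averaging ~16k spectra against the other's ~19k) so that
abundances are comparable across runs and groups.  A protein not identified
in a run keeps SCW = 0 there (zero imputation over the union protein set).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RunInfo, SpectralCountMatrix


class DegenerateRunError(ValueError):
    """A run with zero total spectral count cannot be normalized."""


@dataclass
class SCWMatrix:
    """Protein-by-run SCW values; every column sums to 1."""

    protein_ids: list[str]
    runs: list[RunInfo]
    scw: np.ndarray  # (n_proteins, n_runs) float64

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.runs) if r.group == group])

    def protein_index(self, protein_id: str) -> int:
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"unknown protein {protein_id!r}") from None


def compute_scw(matrix: SpectralCountMatrix) -> SCWMatrix:
    """Divide each count column by its run total.

    Zero cells map to zero by construction, so SCW is zero exactly where the
    protein was not identified.
    """
    totals = matrix.column_totals()
    for j, t in enumerate(totals):
        if t <= 0:
            raise DegenerateRunError(
                f"run {matrix.runs[j].run_id!r} has zero total spectral count"
            )
    scw = matrix.counts.astype(np.float64) / totals[np.newaxis, :]
    return SCWMatrix(protein_ids=list(matrix.protein_ids), runs=list(matrix.runs), scw=scw)


def group_scw_vectors(
    scw: SCWMatrix, protein_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """A protein's SCW values split (model, control), replicate order kept."""
    i = scw.protein_index(protein_id)
    return (
        scw.scw[i, scw.group_columns("model")],
        scw.scw[i, scw.group_columns("control")],
    )


def write_scw_table(scw: SCWMatrix, path: str | Path) -> None:
    """Export protein_id + one column per run, 6 significant digits."""
    df = pd.DataFrame(scw.scw, index=scw.protein_ids, columns=scw.run_ids)
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", float_format="%.6e")


def read_scw_table(path: str | Path, runs: list[RunInfo]) -> SCWMatrix:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    order = [r.run_id for r in runs]
    if set(order) != set(df.columns):
        raise ValueError("SCW table columns do not match the run list")
    return SCWMatrix(
        protein_ids=[str(p) for p in df.index],
        runs=list(runs),
        scw=df[order].to_numpy(dtype=np.float64),
    )
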