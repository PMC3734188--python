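"""Tabular data model for per-run protein identification tables.

A shotgun-proteomics search pipeline (SEQUEST + PeptideProphet/ProteinProphet
or similar) exports, per MS run, one row per identified protein carrying the
identification probability, the number of distinct supporting peptides and
the spectral count.  This module defines the in-memory types for those rows,
reads/writes the TSV dialect, applies the identification-probability filter,
and assembles the union protein-by-run count matrix on which all downstream
quantification operates.

The TSV dialect (UTF-8, tab-separated, header required)::

    run_id  group  protein_id  probability  peptide_count  spectral_count

with an optional ``peptides`` column holding semicolon-joined peptide
sequences.  An optional runs sidecar (``run_id  group  replicate_index``)
may replace the embedded ``group`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("model", "control")

QUANT_COLUMNS = [
    "run_id",
    "group",
    "protein_id",
    "probability",
    "peptide_count",
    "spectral_count",
]


class QuantFormatError(ValueError):
    """Structural problem with a quantification table (e.g. missing column)."""


class QuantValidationError(ValueError):
    """A row violates a field constraint; the message cites the line number."""


class ConsistencyError(ValueError):
    """Cross-table inconsistency (unknown run, mismatched accessions...)."""


@dataclass(frozen=True)
class RunInfo:
    """One MS analysis: identity, experimental group and replicate number."""

    run_id: str
    group: str
    replicate_index: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


@dataclass(frozen=True)
class IdentificationRecord:
    """One protein observed in one MS run.

    ``peptide_count`` is the number of distinct peptide sequences supporting
    the protein in this run; ``spectral_count`` the number of MS/MS spectra
    assigned to it.  Both are strictly positive: a protein not identified in
    a run has no record (absence is represented by a zero matrix cell, not by
    a zero-count row).
    """

    run_id: str
    protein_id: str
    probability: float
    peptide_count: int
    spectral_count: int
    peptides: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if self.peptide_count < 1 or self.spectral_count < 1:
            raise ValueError("peptide_count and spectral_count must be >= 1")


@dataclass
class SpectralCountMatrix:
    """Protein-by-run integer count matrix over the union protein set.

    ``counts[p, r]`` is zero exactly when protein ``p`` was not identified in
    run ``r``.  ``peptide_support[p]`` aggregates distinct-peptide evidence
    across all runs in which ``p`` appears (union of sequences when they are
    listed, otherwise the maximum per-run ``peptide_count``).
    """

    protein_ids: list[str]
    runs: list[RunInfo]
    counts: np.ndarray  # (n_proteins, n_runs) int64
    peptide_support: np.ndarray  # (n_proteins,) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.peptide_support = np.asarray(self.peptide_support, dtype=np.int64)
        if self.counts.shape != (len(self.protein_ids), len(self.runs)):
            raise ValueError("counts shape does not match protein/run lists")

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices belonging to ``group``, replicate order preserved."""
        return np.array([i for i, r in enumerate(self.runs) if r.group == group])

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def protein_index(self, protein_id: str) -> int:
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"unknown protein {protein_id!r}") from None


def _parse_runs(df: pd.DataFrame) -> list[RunInfo]:
    runs: list[RunInfo] = []
    seen: dict[str, str] = {}
    per_group: dict[str, int] = {g: 0 for g in GROUPS}
    for rid, grp in df[["run_id", "group"]].drop_duplicates().itertuples(index=False):
        if rid in seen:
            raise ConsistencyError(f"run {rid!r} assigned to both {seen[rid]!r} and {grp!r}")
        seen[rid] = grp
        per_group[grp] += 1
        runs.append(RunInfo(run_id=str(rid), group=str(grp), replicate_index=per_group[grp]))
    return runs


def read_runs_table(path: str | Path) -> list[RunInfo]:
    """Read a runs sidecar TSV: run_id, group, replicate_index."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("run_id", "group", "replicate_index"):
        if col not in df.columns:
            raise QuantFormatError(f"runs table is missing required column {col!r}")
    runs = [
        RunInfo(run_id=row.run_id, group=row.group, replicate_index=int(row.replicate_index))
        for row in df.itertuples(index=False)
    ]
    if len({r.run_id for r in runs}) != len(runs):
        raise ConsistencyError("duplicate run_id in runs table")
    return runs


def write_runs_table(runs: Sequence[RunInfo], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.run_id, r.group, r.replicate_index) for r in runs],
        columns=["run_id", "group", "replicate_index"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_quant_table(
    path: str | Path, runs_path: str | Path | None = None
) -> tuple[list[IdentificationRecord], list[RunInfo]]:
    """Parse a quantification TSV into records plus run metadata.

    Run metadata comes from the ``runs_path`` sidecar when given, otherwise it
    is derived from the embedded ``group`` column (replicates numbered in
    order of first appearance).  Field constraints are enforced row by row;
    violations raise :class:`QuantValidationError` citing the 1-based file
    line (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c in QUANT_COLUMNS if c != "group" or runs_path is None]
    for col in required:
        if col not in df.columns:
            raise QuantFormatError(f"quant table is missing required column {col!r}")

    if runs_path is not None:
        runs = read_runs_table(runs_path)
    else:
        runs = _parse_runs(df)
    group_of = {r.run_id: r.group for r in runs}

    has_peptides = "peptides" in df.columns
    records: list[IdentificationRecord] = []
    seen_keys: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        rid, pid = str(row.run_id), str(row.protein_id)
        if rid not in group_of:
            raise ConsistencyError(f"line {line}: unknown run_id {rid!r}")
        try:
            prob = float(row.probability)
            pep = int(row.peptide_count)
            spec = int(row.spectral_count)
        except ValueError as exc:
            raise QuantValidationError(f"line {line}: {exc}") from None
        if not 0.0 <= prob <= 1.0:
            raise QuantValidationError(
                f"line {line}: probability {prob} outside [0, 1]"
            )
        if pep < 1 or spec < 1:
            raise QuantValidationError(
                f"line {line}: peptide_count and spectral_count must be >= 1"
            )
        if (rid, pid) in seen_keys:
            raise QuantValidationError(
                f"line {line}: duplicate (run_id, protein_id) = ({rid}, {pid})"
            )
        seen_keys.add((rid, pid))
        peptides: tuple[str, ...] = ()
        if has_peptides and row.peptides:
            peptides = tuple(str(row.peptides).split(";"))
        records.append(
            IdentificationRecord(
                run_id=rid,
                protein_id=pid,
                probability=prob,
                peptide_count=pep,
                spectral_count=spec,
                peptides=peptides,
            )
        )
    return records, runs


def write_quant_table(
    records: Iterable[IdentificationRecord],
    runs: Sequence[RunInfo],
    path: str | Path,
) -> None:
    """Write records to the quant TSV dialect, sorted by (run_id, protein_id)."""
    group_of = {r.run_id: r.group for r in runs}
    rows = sorted(records, key=lambda r: (r.run_id, r.protein_id))
    any_peptides = any(r.peptides for r in rows)
    data = []
    for r in rows:
        row = {
            "run_id": r.run_id,
            "group": group_of[r.run_id],
            "protein_id": r.protein_id,
            "probability": repr(r.probability),
            "peptide_count": r.peptide_count,
            "spectral_count": r.spectral_count,
        }
        if any_peptides:
            row["peptides"] = ";".join(r.peptides)
        data.append(row)
    cols = QUANT_COLUMNS + (["peptides"] if any_peptides else [])
    pd.DataFrame(data, columns=cols).to_csv(path, sep="\t", index=False)


def filter_by_probability(
    records: Sequence[IdentificationRecord], threshold: float = 0.9
) -> list[IdentificationRecord]:
    """Keep identifications with probability strictly above ``threshold``.

    The strict inequality matters at the boundary: a record at exactly the
    threshold is removed.  Order is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return [r for r in records if r.probability > threshold]


def assemble_count_matrix(
    records: Sequence[IdentificationRecord], runs: Sequence[RunInfo]
) -> SpectralCountMatrix:
    """Build the union protein-by-run count matrix with zero-fill.

    The protein set is the union over all runs, ordered lexicographically by
    accession (a deterministic canonical order).  Cells for (protein, run)
    pairs with no identification record are zero — this is the zero
    imputation that lets every protein be compared across all runs.
    """
    run_index = {r.run_id: j for j, r in enumerate(runs)}
    for rec in records:
        if rec.run_id not in run_index:
            raise ConsistencyError(f"record references unknown run_id {rec.run_id!r}")

    protein_ids = sorted({r.protein_id for r in records})
    p_index = {p: i for i, p in enumerate(protein_ids)}
    counts = np.zeros((len(protein_ids), len(runs)), dtype=np.int64)
    max_pep: dict[str, int] = {}
    union_seqs: dict[str, set[str]] = {}
    any_seqs = False
    for rec in records:
        counts[p_index[rec.protein_id], run_index[rec.run_id]] = rec.spectral_count
        max_pep[rec.protein_id] = max(max_pep.get(rec.protein_id, 0), rec.peptide_count)
        if rec.peptides:
            any_seqs = True
            union_seqs.setdefault(rec.protein_id, set()).update(rec.peptides)

    # Distinct-peptide support across the union of runs; when sequences are
    # not listed the max per-run count is the documented fallback.
    if any_seqs:
        support = np.array(
            [len(union_seqs.get(p, set())) or max_pep[p] for p in protein_ids],
            dtype=np.int64,
        )
    else:
        support = np.array([max_pep[p] for p in protein_ids], dtype=np.int64)
    return SpectralCountMatrix(
        protein_ids=protein_ids, runs=list(runs), counts=counts, peptide_support=support
    )


def run_summary(matrix: SpectralCountMatrix) -> pd.DataFrame:
    """Per-run identification/depth summary plus per-group means.

    Returns a DataFrame indexed by run_id with columns ``group``,
    ``proteins_identified`` (nonzero cells) and ``total_spectra`` (column
    sum), followed by one ``<group>/mean`` row per group.
    """
    n_ident = (matrix.counts > 0).sum(axis=0)
    totals = matrix.column_totals()
    rows = {
        r.run_id: (r.group, int(n_ident[j]), int(totals[j]))
        for j, r in enumerate(matrix.runs)
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["group", "proteins_identified", "total_spectra"]
    )
    df.index.name = "run_id"
    for g in GROUPS:
        cols = matrix.group_columns(g)
        if cols.size:
            df.loc[f"{g}/mean"] = (
                g,
                float(np.mean(n_ident[cols])),
                float(np.mean(totals[cols])),
            )
    return df
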