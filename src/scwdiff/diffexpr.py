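"""Per-protein differential testing and the three-criteria selection cascade.

Each protein's two groups of SCW values (5 model vs 5 control replicates by
default) are compared with a two-sided pooled-variance Student's t-test.
Candidate differential proteins must then clear three credibility criteria:

1. at least two distinct supporting peptides across all runs (single-peptide
   identifications are excluded regardless of spectral count);
2. identification in *every* run of the group in which the protein is
   elevated (so an "increase" cannot rest on sporadic detection);
3. fold change strictly greater than 2.5 between group mean SCWs.

Together with the raw p < 0.01 cut-off these form a conjunction; all four
flags are reported per protein for auditability.  No multiple-testing
correction is applied — the expected number of false positives at the tested
protein count is noted in the report instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SpectralCountMatrix
from .scw import SCWMatrix

INCREASED = "increased"
DECREASED = "decreased"
NONE = "none"


class InsufficientReplicatesError(ValueError):
    """Fewer than two replicates in a group; the t-test is undefined."""


@dataclass(frozen=True)
class PipelineParameters:
    """Thresholds of the selection cascade (defaults = the standard cascade)."""

    p_cutoff: float = 0.01
    fc_cutoff: float = 2.5
    min_peptides: int = 2
    probability_cutoff: float = 0.9


@dataclass(frozen=True)
class DifferentialCall:
    """Test result, fold change, direction and criteria flags for one protein."""

    protein_id: str
    mean_model: float
    mean_control: float
    p_value: float
    fold_change: float  # >= 1, or +inf when exactly one mean is zero
    direction: str
    peptide_support: int
    present_all_elevated_runs: bool
    passes_p: bool
    passes_peptide: bool
    passes_presence: bool
    passes_fc: bool
    selected: bool


def two_sample_t(model: Sequence[float], control: Sequence[float]) -> float:
    """Two-sided pooled-variance Student's t-test p-value.

    Degenerate zero-variance inputs are resolved by continuity: when both
    groups are constant, p is 1 for equal means and 0 for unequal means.
    """
    x = np.asarray(model, dtype=np.float64)
    y = np.asarray(control, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError("each group needs >= 2 replicates")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    diff = x.mean() - y.mean()
    if pooled_var == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    t = diff / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    return 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)


def pooled_t_statistic(model: Sequence[float], control: Sequence[float]) -> float:
    """The pooled t statistic itself (model minus control); nan if degenerate."""
    x = np.asarray(model, dtype=np.float64)
    y = np.asarray(control, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError("each group needs >= 2 replicates")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        return math.nan
    return (x.mean() - y.mean()) / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))


def fold_change_and_direction(
    mean_model: float, mean_control: float
) -> tuple[float, str]:
    """Fold change as the larger group mean over the smaller, plus direction.

    The magnitude convention makes a 3.5-fold increase and a 3.5-fold
    decrease the same number with opposite directions.  One zero mean gives
    +inf (any threshold is exceeded; the presence criterion still gates such
    contrasts); two zero means give (1, none).
    """
    if mean_model < 0 or mean_control < 0:
        raise ValueError("group means must be >= 0")
    if mean_model == mean_control:
        return 1.0, NONE
    direction = INCREASED if mean_model > mean_control else DECREASED
    lo = min(mean_model, mean_control)
    if lo == 0.0:
        return math.inf, direction
    return max(mean_model, mean_control) / lo, direction


def apply_selection_criteria(
    call: DifferentialCall,
    counts: SpectralCountMatrix,
    params: PipelineParameters = PipelineParameters(),
) -> DifferentialCall:
    """Fill the four pass flags and the selected conjunction on a call.

    The presence criterion is direction-dependent: the protein must have a
    nonzero count in every run of the group in which it is elevated.  A
    protein with no direction (equal means) cannot satisfy it.
    """
    i = counts.protein_index(call.protein_id)
    if call.direction == NONE:
        present = False
    else:
        group = "model" if call.direction == INCREASED else "control"
        present = bool(np.all(counts.counts[i, counts.group_columns(group)] > 0))
    passes_p = call.p_value < params.p_cutoff
    passes_peptide = call.peptide_support >= params.min_peptides
    passes_fc = call.fold_change > params.fc_cutoff
    return replace(
        call,
        present_all_elevated_runs=present,
        passes_p=passes_p,
        passes_peptide=passes_peptide,
        passes_presence=present,
        passes_fc=passes_fc,
        selected=passes_p and passes_peptide and present and passes_fc,
    )


def run_differential_analysis(
    scw: SCWMatrix,
    counts: SpectralCountMatrix,
    params: PipelineParameters = PipelineParameters(),
) -> list[DifferentialCall]:
    """One DifferentialCall per protein in the union set, in matrix order."""
    if scw.protein_ids != counts.protein_ids or scw.run_ids != counts.run_ids:
        raise ValueError("SCW and count matrices must share protein/run indexing")
    model_cols = scw.group_columns("model")
    control_cols = scw.group_columns("control")
    calls: list[DifferentialCall] = []
    for i, pid in enumerate(scw.protein_ids):
        x = scw.scw[i, model_cols]
        y = scw.scw[i, control_cols]
        p = two_sample_t(x, y)
        fc, direction = fold_change_and_direction(float(x.mean()), float(y.mean()))
        call = DifferentialCall(
            protein_id=pid,
            mean_model=float(x.mean()),
            mean_control=float(y.mean()),
            p_value=p,
            fold_change=fc,
            direction=direction,
            peptide_support=int(counts.peptide_support[i]),
            present_all_elevated_runs=False,
            passes_p=False,
            passes_peptide=False,
            passes_presence=False,
            passes_fc=False,
            selected=False,
        )
        calls.append(apply_selection_criteria(call, counts, params))
    return calls


def expected_false_positives(n_tested: int, p_cutoff: float = 0.01) -> float:
    """Expected false-positive count at the raw p cut-off (no correction)."""
    return n_tested * p_cutoff


_TABLE_COLUMNS = [
    "protein_id",
    "mean_model",
    "mean_control",
    "fold_change",
    "direction",
    "p_value",
    "peptide_support",
    "passes_p",
    "passes_peptide",
    "passes_presence",
    "passes_fc",
    "selected",
]


def calls_to_frame(calls: Sequence[DifferentialCall]) -> pd.DataFrame:
    """Differential table sorted by descending fold change, then accession."""
    rows = [
        {
            "protein_id": c.protein_id,
            "mean_model": c.mean_model,
            "mean_control": c.mean_control,
            "fold_change": c.fold_change,
            "direction": c.direction,
            "p_value": c.p_value,
            "peptide_support": c.peptide_support,
            "passes_p": c.passes_p,
            "passes_peptide": c.passes_peptide,
            "passes_presence": c.passes_presence,
            "passes_fc": c.passes_fc,
            "selected": c.selected,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return df.sort_values(
        ["fold_change", "protein_id"], ascending=[False, True]
    ).reset_index(drop=True)


def write_differential_table(calls: Sequence[DifferentialCall], path: str | Path) -> None:
    df = calls_to_frame(calls)
    df["fold_change"] = df["fold_change"].map(
        lambda v: "Inf" if math.isinf(v) else repr(float(v))
    )
    df.to_csv(path, sep="\t", index=False)


def read_differential_table(path: str | Path) -> list[DifferentialCall]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    calls = []
    for row in df.itertuples(index=False):
        fc = math.inf if str(row.fold_change) in ("Inf", "inf") else float(row.fold_change)
        calls.append(
            DifferentialCall(
                protein_id=row.protein_id,
                mean_model=float(row.mean_model),
                mean_control=float(row.mean_control),
                p_value=float(row.p_value),
                fold_change=fc,
                direction=row.direction,
                peptide_support=int(row.peptide_support),
                present_all_elevated_runs=bool(row.passes_presence),
                passes_p=bool(row.passes_p),
                passes_peptide=bool(row.passes_peptide),
                passes_presence=bool(row.passes_presence),
                passes_fc=bool(row.passes_fc),
                selected=bool(row.selected),
            )
        )
    return calls
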