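"""Secreted / non-secretory partition of differential proteins.

Classically secreted proteins carry an N-terminal signal peptide.  Signal
peptides are predicted here by two independent algorithms (a neural network
and a hidden Markov model, as in SignalP); a protein counts as secreted only
when both predictors are positive.  The partition crossed with the change
direction (increased/decreased in the disease-model group) yields a 2x2
table whose percentages summarize whether the secreted compartment moves
with or against the intracellular/membrane compartment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .diffexpr import DifferentialCall, INCREASED, DECREASED, NONE


@dataclass(frozen=True)
class SecretionAnnotation:
    protein_id: str
    nn_positive: bool
    hmm_positive: bool


@dataclass(frozen=True)
class PartitionSummary:
    """Secretion-by-direction cross-tabulation of a differential protein list.

    Percentages are computed from the integer cells and rounded half-up to
    one decimal place (the usual reporting precision).
    """

    n_total: int
    n_secreted: int
    n_nonsecreted: int
    secreted_increased: int
    secreted_decreased: int
    nonsecreted_increased: int
    nonsecreted_decreased: int
    pct_secreted: float
    pct_nonsecreted: float
    pct_secreted_decreased: float
    pct_nonsecreted_increased: float


def round1(value: float) -> float:
    """Round half-up to 1 decimal (3.75 -> 3.8), like printed percentages."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_secreted(annotation: SecretionAnnotation | None) -> bool:
    """Secreted iff both predictors are positive; unannotated -> non-secretory."""
    if annotation is None:
        return False
    return annotation.nn_positive and annotation.hmm_positive


def partition_summary(
    calls: Sequence[DifferentialCall],
    annotations: Sequence[SecretionAnnotation] | Mapping[str, SecretionAnnotation],
) -> PartitionSummary:
    """Cross-tabulate secretion class against change direction.

    ``calls`` is the *selected* differential list; every call must carry a
    direction.  Proteins lacking an annotation row default to non-secretory
    (with a warning naming them), so the split is always exhaustive.
    """
    if isinstance(annotations, Mapping):
        ann_by_id = dict(annotations)
    else:
        ann_by_id = {a.protein_id: a for a in annotations}
    cells = {
        (True, INCREASED): 0,
        (True, DECREASED): 0,
        (False, INCREASED): 0,
        (False, DECREASED): 0,
    }
    missing = []
    for call in calls:
        if call.direction == NONE:
            raise ValueError(
                f"protein {call.protein_id!r} has no direction; partition requires "
                "a differential (selected) call list"
            )
        ann = ann_by_id.get(call.protein_id)
        if ann is None:
            missing.append(call.protein_id)
        cells[(classify_secreted(ann), call.direction)] += 1
    if missing:
        warnings.warn(
            f"{len(missing)} proteins lack a secretion annotation and default "
            f"to non-secretory: {', '.join(sorted(missing)[:10])}"
            + ("..." if len(missing) > 10 else ""),
            stacklevel=2,
        )

    n_total = len(calls)
    n_sec = cells[(True, INCREASED)] + cells[(True, DECREASED)]
    n_non = n_total - n_sec
    pct = lambda num, den: round1(100.0 * num / den) if den else 0.0
    return PartitionSummary(
        n_total=n_total,
        n_secreted=n_sec,
        n_nonsecreted=n_non,
        secreted_increased=cells[(True, INCREASED)],
        secreted_decreased=cells[(True, DECREASED)],
        nonsecreted_increased=cells[(False, INCREASED)],
        nonsecreted_decreased=cells[(False, DECREASED)],
        pct_secreted=pct(n_sec, n_total),
        pct_nonsecreted=pct(n_non, n_total),
        pct_secreted_decreased=pct(cells[(True, DECREASED)], n_sec),
        pct_nonsecreted_increased=pct(cells[(False, INCREASED)], n_non),
    )


def read_annotation_table(path: str | Path) -> list[SecretionAnnotation]:
    """Annotation TSV: protein_id, nn_positive (0/1), hmm_positive (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for col in ("protein_id", "nn_positive", "hmm_positive"):
        if col not in df.columns:
            raise ValueError(f"annotation table is missing column {col!r}")
    if df["protein_id"].duplicated().any():
        dup = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise ValueError(f"duplicate annotation for protein {dup!r}")
    return [
        SecretionAnnotation(
            protein_id=row.protein_id,
            nn_positive=bool(int(row.nn_positive)),
            hmm_positive=bool(int(row.hmm_positive)),
        )
        for row in df.itertuples(index=False)
    ]


def write_annotation_table(
    annotations: Sequence[SecretionAnnotation], path: str | Path
) -> None:
    rows = sorted(annotations, key=lambda a: a.protein_id)
    pd.DataFrame(
        [(a.protein_id, int(a.nn_positive), int(a.hmm_positive)) for a in rows],
        columns=["protein_id", "nn_positive", "hmm_positive"],
    ).to_csv(path, sep="\t", index=False)


def write_summary_json(
    summary: PartitionSummary, path: str | Path, parameters: dict | None = None
) -> None:
    payload = {"partition": asdict(summary), "parameters": parameters or {}}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
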