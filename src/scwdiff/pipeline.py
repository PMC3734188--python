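"""End-to-end orchestration and recovery evaluation.

``run_pipeline`` drives the whole analysis from one config mapping (usually
a YAML file): simulate or load a quant table, apply the probability filter,
assemble counts, normalize to SCW, test and select differential proteins,
partition them by secretion, and — when ground truth is available — score
how well the truth was recovered.  The report bundle is deterministic for a
given config and seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import io as qio
from .diffexpr import (
    DifferentialCall,
    PipelineParameters,
    calls_to_frame,
    expected_false_positives,
    run_differential_analysis,
    write_differential_table,
)
from .io import ConsistencyError, SpectralCountMatrix
from .scw import compute_scw, write_scw_table
from .secretome import (
    partition_summary,
    read_annotation_table,
    write_summary_json,
)
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_dataset,
    write_config_json,
    write_truth_table,
)

logger = logging.getLogger("scwdiff")

CRITERIA = ("p", "peptide", "presence", "fc")


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the selected set recovers the simulator's truth.

    ``sensitivity`` is over all truly differential proteins (detected or
    not); ``empirical_fdr`` over the selected set; both are None when their
    denominator is zero.  ``fold_change_log2_rmse`` is computed over selected
    true positives with finite estimated fold.  Attrition counts how many
    cascade-entering proteins failed each criterion (a protein can fail
    several; ``any`` counts each unselected protein once).
    """

    sensitivity: float | None
    empirical_fdr: float | None
    fold_change_log2_rmse: float | None
    n_selected: int
    n_true_differential: int
    attrition: dict[str, int]


def evaluate_recovery(
    calls: Sequence[DifferentialCall], truth: GroundTruth
) -> RecoveryMetrics:
    truth_ids = set(truth.protein_ids)
    for c in calls:
        if c.protein_id not in truth_ids:
            raise ConsistencyError(
                f"call accession {c.protein_id!r} absent from ground truth"
            )
    is_diff = dict(zip(truth.protein_ids, truth.is_differential))
    fold_of = dict(zip(truth.protein_ids, truth.true_fold))

    selected = [c for c in calls if c.selected]
    n_true = int(sum(is_diff.values()))
    tp = [c for c in selected if is_diff[c.protein_id]]
    sensitivity = len(tp) / n_true if n_true else None
    fdr = (len(selected) - len(tp)) / len(selected) if selected else None

    sq = [
        (math.log2(c.fold_change) - math.log2(fold_of[c.protein_id])) ** 2
        for c in tp
        if math.isfinite(c.fold_change)
    ]
    rmse = math.sqrt(sum(sq) / len(sq)) if sq else None

    attrition = {k: 0 for k in CRITERIA}
    attrition["any"] = 0
    for c in calls:
        if c.selected:
            continue
        attrition["any"] += 1
        if not c.passes_p:
            attrition["p"] += 1
        if not c.passes_peptide:
            attrition["peptide"] += 1
        if not c.passes_presence:
            attrition["presence"] += 1
        if not c.passes_fc:
            attrition["fc"] += 1
    return RecoveryMetrics(
        sensitivity=sensitivity,
        empirical_fdr=fdr,
        fold_change_log2_rmse=rmse,
        n_selected=len(selected),
        n_true_differential=n_true,
        attrition=attrition,
    )


def stratified_sensitivity(
    calls: Sequence[DifferentialCall],
    truth: GroundTruth,
    counts: SpectralCountMatrix,
    fold_min: float = 1.0,
    fold_max: float = math.inf,
    require_all_runs: bool = False,
) -> float | None:
    """Sensitivity restricted to spike-ins in a true-fold window.

    With ``require_all_runs`` the stratum keeps only spike-ins detected in
    every run (power for such proteins reflects the test, not dropout).
    Returns None when the stratum is empty.
    """
    sel = {c.protein_id for c in calls if c.selected}
    idx = {p: i for i, p in enumerate(counts.protein_ids)}
    denom = hits = 0
    for i, pid in enumerate(truth.protein_ids):
        if not truth.is_differential[i]:
            continue
        f = truth.true_fold[i]
        if not fold_min <= f <= fold_max:
            continue
        if require_all_runs:
            j = idx.get(pid)
            if j is None or not np.all(counts.counts[j] > 0):
                continue
        denom += 1
        hits += pid in sel
    return hits / denom if denom else None


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _params_from_config(cfg: dict[str, Any]) -> PipelineParameters:
    p = cfg.get("parameters", {}) or {}
    return PipelineParameters(
        p_cutoff=float(p.get("p_cutoff", 0.01)),
        fc_cutoff=float(p.get("fc_cutoff", 2.5)),
        min_peptides=int(p.get("min_peptides", 2)),
        probability_cutoff=float(p.get("probability_cutoff", 0.9)),
    )


def run_pipeline(
    config: dict[str, Any] | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Any]:
    """Execute the full analysis described by ``config`` into ``out_dir``.

    The config either names input TSVs under ``inputs`` (``quant``, optional
    ``runs`` sidecar, optional ``annotations``) or carries a ``simulation``
    block of :class:`SimulationConfig` fields.  ``seed`` overrides the
    config's seed.  Returns a report dict; all tables and JSON reports are
    also written under ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    params = _params_from_config(config)
    sim_block = config.get("simulation")
    inputs = config.get("inputs", {}) or {}
    if sim_block is None and "quant" not in inputs:
        raise ValueError("config must provide a simulation block or inputs.quant")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "thresholds: p<%g, fold>%g, peptides>=%d, probability>%g",
        params.p_cutoff, params.fc_cutoff, params.min_peptides,
        params.probability_cutoff,
    )

    truth: GroundTruth | None = None
    if sim_block is not None:
        sim_kwargs = dict(sim_block)
        if seed is not None:
            sim_kwargs["seed"] = seed
        for key in ("depth_range", "log2_fc_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_config = SimulationConfig(**sim_kwargs)
        logger.info("simulating dataset (seed=%d)", sim_config.seed)
        records, runs, truth = simulate_dataset(sim_config)
        qio.write_quant_table(records, runs, out / "quant.tsv")
        qio.write_runs_table(runs, out / "runs.tsv")
        write_truth_table(truth, out / "truth.tsv")
        write_config_json(sim_config, out / "simulation_config.json")
    else:
        records, runs = qio.read_quant_table(inputs["quant"], inputs.get("runs"))

    filtered = qio.filter_by_probability(records, params.probability_cutoff)
    logger.info(
        "%d of %d identifications pass probability > %g",
        len(filtered), len(records), params.probability_cutoff,
    )
    counts = qio.assemble_count_matrix(filtered, runs)
    summary = qio.run_summary(counts)
    summary.to_csv(out / "run_summary.tsv", sep="\t")

    scw = compute_scw(counts)
    write_scw_table(scw, out / "scw.tsv")

    calls = run_differential_analysis(scw, counts, params)
    write_differential_table(calls, out / "differential.tsv")
    selected = [c for c in calls if c.selected]
    n_inc = sum(c.direction == "increased" for c in selected)
    n_dec = sum(c.direction == "decreased" for c in selected)
    logger.info(
        "%d proteins selected (%d increased, %d decreased) of %d tested; "
        "~%.1f false positives expected at raw p<%g",
        len(selected), n_inc, n_dec, len(calls),
        expected_false_positives(len(calls), params.p_cutoff), params.p_cutoff,
    )

    report: dict[str, Any] = {
        "parameters": asdict(params),
        "n_tested": len(calls),
        "n_selected": len(selected),
        "n_increased": n_inc,
        "n_decreased": n_dec,
        "expected_false_positives": expected_false_positives(
            len(calls), params.p_cutoff
        ),
    }
    if sim_block is not None:
        report["seed"] = sim_config.seed

    if inputs.get("annotations"):
        annotations = read_annotation_table(inputs["annotations"])
        part = partition_summary(selected, annotations)
        write_summary_json(part, out / "partition.json", asdict(params))
        report["partition"] = asdict(part)

    if truth is not None:
        metrics = evaluate_recovery(calls, truth)
        report["recovery"] = asdict(metrics)
        (out / "recovery.json").write_text(
            json.dumps(asdict(metrics), indent=2, sort_keys=True) + "\n"
        )
        if metrics.n_true_differential == 0 and metrics.n_selected <= max(
            1, 0.01 * len(calls)
        ):
            logger.info(
                "null calibration: no true effects simulated and %d selected",
                metrics.n_selected,
            )

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
    )
    return report
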