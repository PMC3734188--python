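"""Synthetic spectral-count datasets with known ground truth.

The generator emulates the data-generating setting the pipeline targets: two
pooled samples (disease model vs control), each measured by five technical
replicate MS runs, ~650-800 proteins identified per run and ~16,000-19,500
MS/MS spectra per run.  Baseline relative abundances are log-normal and
highly skewed, a configurable subset of proteins carries true fold changes,
and detection is abundance-dependent: a protein is identified in a run iff
at least one spectrum was sampled for it, which reproduces the missing-value
pattern (zero imputation) of real spectral counting.

Counts are negative-binomial (gamma-Poisson) in each protein, conditioned on
the run's total spectral depth: per-protein gamma weights with the configured
overdispersion are drawn around the condition's abundance simplex and the
run's depth is allocated multinomially across them.  This keeps each run's
realized total exactly at its sampled depth while giving individual proteins
negative-binomial-like replicate variability; dispersion 0 degenerates to a
plain multinomial (the conditioned Poisson).

Also provided is a constant worked-example fixture: an 86-protein selected
differential list whose direction (59 increased / 27 decreased) and
secretion (27 secreted / 59 non-secretory) marginals, and the derived 2x2
cells, reproduce a published perfusate-proteome partition exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import DifferentialCall, INCREASED, DECREASED
from .io import IdentificationRecord, RunInfo
from .secretome import SecretionAnnotation


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study-scale conditions.

    ``dispersion`` is the negative-binomial overdispersion of technical
    replicates (variance = mu + dispersion * mu^2); the default is small
    because replicates re-measure one pooled sample.  ``peptide_rate`` sets
    expected distinct peptides per log10 unit of expected spectral count.
    """

    n_proteins: int = 800
    runs_per_group: int = 5
    depth_range: tuple[int, int] = (16_000, 19_500)
    abundance_sigma: float = 1.5
    frac_differential: float = 0.10
    log2_fc_range: tuple[float, float] = (1.4, 3.0)
    direction_prob_increased: float = 59.0 / 86.0
    dispersion: float = 0.1
    peptide_rate: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ConfigurationError("frac_differential must be in [0, 1]")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] <= 0:
            raise ConfigurationError("depth_range must satisfy 0 < low <= high")
        if self.log2_fc_range[0] > self.log2_fc_range[1] or self.log2_fc_range[0] <= 0:
            raise ConfigurationError("log2_fc_range must satisfy 0 < low <= high")
        if self.n_proteins < 1 or self.runs_per_group < 2:
            raise ConfigurationError("need >= 1 protein and >= 2 runs per group")
        if self.dispersion < 0 or self.abundance_sigma <= 0 or self.peptide_rate <= 0:
            raise ConfigurationError("rates must be positive, dispersion >= 0")
        if not 0.0 <= self.direction_prob_increased <= 1.0:
            raise ConfigurationError("direction_prob_increased must be in [0, 1]")


@dataclass
class GroundTruth:
    """The simulator's true state, for recovery evaluation."""

    protein_ids: list[str]
    baseline: np.ndarray  # relative-abundance simplex
    is_differential: np.ndarray  # bool
    true_fold: np.ndarray  # 1.0 for nulls
    true_direction: list[str]  # "increased"/"decreased"/"none"
    run_depths: dict[str, int]
    # Realized per-condition expected-abundance simplices.  Because spiked
    # mass is renormalized within each condition, the expected SCW ratio of a
    # spike-in is true_fold scaled by the normalizer ratio, not true_fold
    # itself (compositional deflation); these vectors carry that expectation.
    model_abund: np.ndarray | None = None
    control_abund: np.ndarray | None = None

    def expected_scw_ratio(self, i: int) -> float:
        """Expected elevated-over-other SCW ratio for protein ``i``."""
        if self.model_abund is None or self.control_abund is None:
            raise ValueError("per-condition abundances not available")
        m, c = self.model_abund[i], self.control_abund[i]
        return m / c if m >= c else c / m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "baseline": self.baseline,
                "is_differential": self.is_differential.astype(int),
                "true_fold": self.true_fold,
                "true_direction": self.true_direction,
            }
        )


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"SYNP{i:0{width}d}" for i in range(1, n + 1)]


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[IdentificationRecord], list[RunInfo], GroundTruth]:
    """Draw one dataset: quant records, run metadata and ground truth.

    Random draws are consumed in a fixed order (baseline abundances;
    differential subset; log2 folds; directions; then per run in
    model-before-control, replicate order: gamma weights, multinomial
    counts, peptide counts, probabilities) from a single
    ``numpy.random.default_rng(seed)`` PCG64 stream, so a given (config,
    seed) pair is fully reproducible.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = _protein_ids(n)

    baseline = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    baseline /= baseline.sum()

    n_diff = int(round(config.frac_differential * n))
    diff_idx = np.sort(rng.choice(n, size=n_diff, replace=False))
    is_diff = np.zeros(n, dtype=bool)
    is_diff[diff_idx] = True
    log2_fc = rng.uniform(*config.log2_fc_range, size=n_diff)
    increased = rng.random(n_diff) < config.direction_prob_increased

    true_fold = np.ones(n)
    true_fold[diff_idx] = 2.0 ** log2_fc
    direction = ["none"] * n
    for k, i in enumerate(diff_idx):
        direction[i] = INCREASED if increased[k] else DECREASED

    # Expected relative abundance per condition: spike folds applied to the
    # model group, then renormalized within the condition (compositionality:
    # spike-ins slightly deflate every other protein's share).
    model_abund = baseline.copy()
    model_abund[diff_idx] *= np.where(increased, true_fold[diff_idx], 1.0 / true_fold[diff_idx])
    model_abund /= model_abund.sum()
    control_abund = baseline

    runs = [
        RunInfo(run_id=f"{g}_{k}", group=g, replicate_index=k)
        for g in ("model", "control")
        for k in range(1, config.runs_per_group + 1)
    ]
    lo, hi = config.depth_range
    records: list[IdentificationRecord] = []
    run_depths: dict[str, int] = {}
    for run in runs:
        abund = model_abund if run.group == "model" else control_abund
        depth = int(rng.integers(lo, hi + 1))
        run_depths[run.run_id] = depth
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            weights = rng.gamma(shape=shape, scale=abund / shape)
            total = weights.sum()
            if total == 0.0:  # pathological tiny configs
                weights = abund.copy()
                total = weights.sum()
            probs = weights / total
        else:
            probs = abund
        counts = rng.multinomial(depth, probs)
        identified = np.flatnonzero(counts > 0)
        mu = depth * abund[identified]
        pep = np.maximum(
            1, rng.poisson(config.peptide_rate * np.log10(mu + 1.0))
        )
        prob = 1.0 - 0.1 * rng.random(identified.size)  # in (0.9, 1.0]
        for j, i in enumerate(identified):
            records.append(
                IdentificationRecord(
                    run_id=run.run_id,
                    protein_id=ids[i],
                    probability=float(prob[j]),
                    peptide_count=int(pep[j]),
                    spectral_count=int(counts[i]),
                )
            )

    truth = GroundTruth(
        protein_ids=ids,
        baseline=baseline,
        is_differential=is_diff,
        true_fold=true_fold,
        true_direction=direction,
        run_depths=run_depths,
        model_abund=model_abund,
        control_abund=control_abund,
    )
    return records, runs, truth


def write_truth_table(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return GroundTruth(
        protein_ids=list(df["protein_id"]),
        baseline=df["baseline"].to_numpy(),
        is_differential=df["is_differential"].to_numpy().astype(bool),
        true_fold=df["true_fold"].to_numpy(),
        true_direction=list(df["true_direction"]),
        run_depths={},
    )


def write_config_json(config: SimulationConfig, path: str | Path) -> None:
    """Reproducibility block: config plus the generator algorithm name."""
    payload = asdict(config)
    payload["rng"] = "numpy.random.default_rng (PCG64), fixed draw order"
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Worked-example fixture reproducing the published partition marginals.
# ---------------------------------------------------------------------------

MARGINALS = {
    "n_total": 86,
    "n_increased": 59,
    "n_decreased": 27,
    "n_secreted": 27,
    "n_nonsecreted": 59,
    "frac_secreted_decreased": 0.704,
    "frac_nonsecreted_increased": 0.864,
}


def derive_partition_cells(marginals: dict = MARGINALS) -> dict[str, int]:
    """Solve the 2x2 cell counts from the printed marginals.

    Two cells follow from the printed within-class percentages
    (secreted-decreased, non-secreted-increased); the other two by
    subtraction.  Consistency with both the direction and the secretion
    marginals is asserted — the four printed numbers overdetermine the table,
    so agreement is a genuine check, not a tautology.
    """
    sec_dec = round(marginals["frac_secreted_decreased"] * marginals["n_secreted"])
    non_inc = round(marginals["frac_nonsecreted_increased"] * marginals["n_nonsecreted"])
    sec_inc = marginals["n_secreted"] - sec_dec
    non_dec = marginals["n_nonsecreted"] - non_inc
    cells = {
        "secreted_increased": sec_inc,
        "secreted_decreased": sec_dec,
        "nonsecreted_increased": non_inc,
        "nonsecreted_decreased": non_dec,
    }
    assert sec_inc + non_inc == marginals["n_increased"]
    assert sec_dec + non_dec == marginals["n_decreased"]
    assert sum(cells.values()) == marginals["n_total"]
    assert all(v >= 0 for v in cells.values())
    return cells


def _fixture_call(pid: str, direction: str, fold: float) -> DifferentialCall:
    # Plausible SCW means consistent with the direction and fold.
    base = 1e-3
    mm, mc = (base * fold, base) if direction == INCREASED else (base, base * fold)
    return DifferentialCall(
        protein_id=pid,
        mean_model=mm,
        mean_control=mc,
        p_value=0.001,
        fold_change=fold,
        direction=direction,
        peptide_support=3,
        present_all_elevated_runs=True,
        passes_p=True,
        passes_peptide=True,
        passes_presence=True,
        passes_fc=True,
        selected=True,
    )


def make_paper_marginal_fixture() -> tuple[list[DifferentialCall], list[SecretionAnnotation]]:
    """The constant 86-protein selected list plus secretion annotations.

    Calls are synthetic stand-ins (the underlying protein list is not
    public): accessions, means and folds are fabricated, but the direction
    and secretion structure reproduces the published marginals exactly.
    """
    cells = derive_partition_cells()
    calls: list[DifferentialCall] = []
    annotations: list[SecretionAnnotation] = []
    spec_blocks = [
        ("secreted_increased", True, INCREASED),
        ("secreted_decreased", True, DECREASED),
        ("nonsecreted_increased", False, INCREASED),
        ("nonsecreted_decreased", False, DECREASED),
    ]
    k = 0
    for cell, secreted, direction in spec_blocks:
        for _ in range(cells[cell]):
            k += 1
            pid = f"FIXT{k:04d}"
            fold = 2.6 + 0.05 * (k % 40)  # varied folds, all > 2.5
            calls.append(_fixture_call(pid, direction, fold))
            if secreted:
                annotations.append(SecretionAnnotation(pid, True, True))
            else:
                # Non-secretory proteins include single-positive and
                # double-negative predictions; one predictor alone never
                # suffices for the secreted class.
                nn = k % 3 == 0
                hmm = k % 5 == 0 and not nn
                annotations.append(SecretionAnnotation(pid, nn, hmm))
    return calls, annotations
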