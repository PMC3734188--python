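import numpy as np
import pytest

from scwdiff.io import IdentificationRecord, RunInfo, SpectralCountMatrix


def make_runs(n_per_group: int = 5) -> list[RunInfo]:
    return [
        RunInfo(run_id=f"{g}_{k}", group=g, replicate_index=k)
        for g in ("model", "control")
        for k in range(1, n_per_group + 1)
    ]


def make_matrix(
    counts_by_protein: dict[str, list[int]],
    peptide_support: dict[str, int] | None = None,
    n_per_group: int = 5,
) -> SpectralCountMatrix:
    """Hand-build a count matrix; rows given per protein across all runs."""
    runs = make_runs(n_per_group)
    protein_ids = sorted(counts_by_protein)
    counts = np.array([counts_by_protein[p] for p in protein_ids], dtype=np.int64)
    support = np.array(
        [(peptide_support or {}).get(p, 3) for p in protein_ids], dtype=np.int64
    )
    return SpectralCountMatrix(
        protein_ids=protein_ids, runs=runs, counts=counts, peptide_support=support
    )


@pytest.fixture
def runs5():
    return make_runs(5)


@pytest.fixture
def toy_records(runs5):
    """Three proteins scattered over the ten runs, with peptide sequences."""
    recs = []
    for rid in [r.run_id for r in runs5][:3]:
        recs.append(
            IdentificationRecord(
                run_id=rid, protein_id="A", probability=0.99,
                peptide_count=2, spectral_count=5, peptides=("PEPA", "PEPB"),
            )
        )
    recs.append(
        IdentificationRecord(
            run_id="control_1", protein_id="B", probability=0.95,
            peptide_count=1, spectral_count=3, peptides=("PEPC",),
        )
    )
    recs.append(
        IdentificationRecord(
            run_id="model_1", protein_id="C", probability=0.92,
            peptide_count=4, spectral_count=12,
        )
    )
    return recs
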