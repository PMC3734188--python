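import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from scwdiff.diffexpr import (
    DECREASED,
    INCREASED,
    NONE,
    DifferentialCall,
    InsufficientReplicatesError,
    PipelineParameters,
    apply_selection_criteria,
    calls_to_frame,
    fold_change_and_direction,
    pooled_t_statistic,
    read_differential_table,
    run_differential_analysis,
    two_sample_t,
    write_differential_table,
)
from scwdiff.io import RunInfo, SpectralCountMatrix
from scwdiff.scw import compute_scw
from conftest import make_matrix, make_runs

HAND_MODEL = [0.10, 0.12, 0.11, 0.13, 0.09]
HAND_CONTROL = [0.20, 0.22, 0.21, 0.23, 0.19]


def t_cdf_via_incomplete_beta(t: float, df: int) -> float:
    """Two-sided p through the regularized incomplete beta function —
    an algebraic route independent of scipy.stats.t."""
    return special.betainc(df / 2.0, 0.5, df / (df + t * t))


class TestTwoSampleT:
    def test_identical_groups_give_p_one(self):
        assert two_sample_t([0.1] * 5, [0.1] * 5) == 1.0

    def test_hand_computable_pair_has_t_exactly_minus_ten(self):
        # group sds 0.0158..., pooled se exactly 0.01, mean difference -0.10
        t = pooled_t_statistic(HAND_MODEL, HAND_CONTROL)
        assert t == pytest.approx(-10.0, abs=1e-12)
        p = two_sample_t(HAND_MODEL, HAND_CONTROL)
        assert p < 0.01
        assert p == pytest.approx(t_cdf_via_incomplete_beta(10.0, 8), abs=1e-12)

    def test_swapping_groups_leaves_p_unchanged(self):
        assert two_sample_t(HAND_MODEL, HAND_CONTROL) == pytest.approx(
            two_sample_t(HAND_CONTROL, HAND_MODEL), abs=1e-15
        )

    def test_matches_scipy_pooled_ttest_on_nondegenerate_input(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x, y = rng.normal(size=5), rng.normal(size=5)
            expected = stats.ttest_ind(x, y, equal_var=True).pvalue
            assert two_sample_t(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_but_unequal_groups_give_p_zero(self):
        assert two_sample_t([0.2] * 5, [0.1] * 5) == 0.0

    @pytest.mark.parametrize("model, control", [([0.1], [0.1, 0.2]), ([], [0.1, 0.2])])
    def test_fewer_than_two_replicates_is_an_error(self, model, control):
        with pytest.raises(InsufficientReplicatesError):
            two_sample_t(model, control)


class TestFoldChangeAndDirection:
    @pytest.mark.parametrize(
        "mm, mc, fold, direction",
        [
            (0.0035, 0.0010, 3.5, INCREASED),
            (0.0010, 0.0035, 3.5, DECREASED),
            (0.002, 0.0, math.inf, INCREASED),
            (0.0, 0.002, math.inf, DECREASED),
            (0.01, 0.01, 1.0, NONE),
            (0.0, 0.0, 1.0, NONE),
        ],
    )
    def test_ratio_and_direction(self, mm, mc, fold, direction):
        f, d = fold_change_and_direction(mm, mc)
        assert d == direction
        assert f == fold or f == pytest.approx(fold)

    def test_negative_means_rejected(self):
        with pytest.raises(ValueError):
            fold_change_and_direction(-0.1, 0.2)


def _call(pid="P", p=0.001, fold=3.0, direction=INCREASED, support=5):
    base = 0.001
    mm, mc = (base * fold, base) if direction == INCREASED else (base, base * fold)
    return DifferentialCall(
        protein_id=pid, mean_model=mm, mean_control=mc, p_value=p,
        fold_change=fold, direction=direction, peptide_support=support,
        present_all_elevated_runs=False, passes_p=False, passes_peptide=False,
        passes_presence=False, passes_fc=False, selected=False,
    )


class TestSelectionCriteria:
    @pytest.fixture
    def present_matrix(self):
        return make_matrix({"P": [3] * 10}, peptide_support={"P": 5})

    def test_single_peptide_spikein_is_never_selected(self, present_matrix):
        out = apply_selection_criteria(_call(support=1), present_matrix)
        assert out.passes_p and out.passes_presence and out.passes_fc
        assert not out.passes_peptide and not out.selected

    def test_p_cutoff_is_strict_at_0_01(self, present_matrix):
        out = apply_selection_criteria(_call(p=0.02, fold=4.0), present_matrix)
        assert not out.passes_p and not out.selected
        boundary = apply_selection_criteria(_call(p=0.01), present_matrix)
        assert not boundary.passes_p

    def test_fold_exactly_2_5_fails_the_strict_threshold(self, present_matrix):
        out = apply_selection_criteria(_call(fold=2.5), present_matrix)
        assert out.passes_p and out.passes_peptide and out.passes_presence
        assert not out.passes_fc and not out.selected

    def test_infinite_fold_passes_fold_criterion(self, present_matrix):
        out = apply_selection_criteria(_call(fold=math.inf), present_matrix)
        assert out.passes_fc

    def test_presence_checked_in_the_elevated_group_only(self):
        m = make_matrix({"P": [0, 3, 3, 3, 3] + [1] * 5}, peptide_support={"P": 5})
        up = apply_selection_criteria(_call(direction=INCREASED), m)
        assert not up.passes_presence and not up.selected
        down = apply_selection_criteria(_call(direction=DECREASED), m)
        assert down.passes_presence  # all five control runs are nonzero

    def test_no_direction_cannot_satisfy_presence(self, present_matrix):
        out = apply_selection_criteria(_call(fold=1.0, direction=NONE), present_matrix)
        assert not out.passes_presence and not out.selected


def build_toy_matrix() -> SpectralCountMatrix:
    """Twelve proteins, hand-enumerable: 3 clear spike-ins, 1 single-peptide
    spike-in, 1 spike-in absent from one elevated-group run, 7 nulls (one is
    a filler equalizing every run total to 1000)."""
    rows = {
        "UP1": [50, 52, 48, 51, 49, 5, 5, 6, 4, 5],
        "UP2": [30, 31, 29, 30, 30, 8, 8, 7, 9, 8],
        "DOWN1": [6, 5, 6, 5, 6, 40, 42, 38, 41, 39],
        "SINGLEPEP": [60, 61, 59, 60, 60, 10, 10, 10, 10, 10],
        "MISSING": [0, 45, 46, 44, 45, 5, 5, 5, 5, 5],
        "NULL1": [20, 21, 19, 20, 20, 20, 21, 19, 20, 20],
        "NULL2": [100, 99, 101, 100, 100, 100, 99, 101, 100, 100],
        "NULL3": [15, 15, 15, 15, 15, 15, 15, 15, 15, 15],
        "NULL4": [8, 9, 8, 9, 8, 9, 8, 9, 8, 9],
        "NULL5": [33, 32, 34, 33, 33, 33, 32, 34, 33, 33],
        "NULL6": [12, 12, 12, 12, 12, 12, 12, 12, 12, 12],
    }
    col_sums = [sum(rows[p][j] for p in rows) for j in range(10)]
    rows["FILLER"] = [1000 - s for s in col_sums]
    support = {p: 4 for p in rows}
    support["SINGLEPEP"] = 1
    return make_matrix(rows, peptide_support=support)


class TestRunDifferentialAnalysis:
    def test_toy_matrix_selects_exactly_the_three_clear_spikeins(self):
        m = build_toy_matrix()
        calls = run_differential_analysis(compute_scw(m), m)
        selected = {c.protein_id for c in calls if c.selected}
        assert selected == {"UP1", "UP2", "DOWN1"}
        by_id = {c.protein_id: c for c in calls}
        assert not by_id["SINGLEPEP"].passes_peptide
        assert not by_id["MISSING"].passes_presence
        assert by_id["DOWN1"].direction == DECREASED

    def test_raising_fold_cutoff_shrinks_the_selected_set(self):
        m = build_toy_matrix()
        scw = compute_scw(m)
        base = {c.protein_id for c in run_differential_analysis(scw, m) if c.selected}
        strict = {
            c.protein_id
            for c in run_differential_analysis(
                scw, m, PipelineParameters(fc_cutoff=5.0)
            )
            if c.selected
        }
        assert strict < base

    @pytest.mark.parametrize(
        "params",
        [
            PipelineParameters(p_cutoff=0.001),
            PipelineParameters(min_peptides=5),
            PipelineParameters(fc_cutoff=4.0),
        ],
    )
    def test_tightening_any_threshold_is_monotone(self, params):
        m = build_toy_matrix()
        scw = compute_scw(m)
        base = {c.protein_id for c in run_differential_analysis(scw, m) if c.selected}
        tight = {
            c.protein_id for c in run_differential_analysis(scw, m, params) if c.selected
        }
        assert tight <= base

    def test_group_swap_maps_increased_to_decreased(self):
        m = build_toy_matrix()
        swapped_runs = [
            RunInfo(
                run_id=r.run_id,
                group="control" if r.group == "model" else "model",
                replicate_index=r.replicate_index,
            )
            for r in m.runs
        ]
        m2 = SpectralCountMatrix(
            protein_ids=list(m.protein_ids),
            runs=swapped_runs,
            counts=m.counts.copy(),
            peptide_support=m.peptide_support.copy(),
        )
        ref = {c.protein_id: c for c in run_differential_analysis(compute_scw(m), m)}
        swp = {c.protein_id: c for c in run_differential_analysis(compute_scw(m2), m2)}
        flip = {INCREASED: DECREASED, DECREASED: INCREASED, NONE: NONE}
        for pid, c in ref.items():
            assert swp[pid].direction == flip[c.direction]
            assert swp[pid].p_value == pytest.approx(c.p_value, abs=1e-15)
            assert swp[pid].fold_change == pytest.approx(c.fold_change)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_explicit_bruteforce_implementation(self, seed):
        rng = np.random.default_rng(seed)
        n_p = int(rng.integers(2, 11))
        counts = rng.integers(0, 25, size=(n_p, 10))
        counts[0, :] += 1
        m = SpectralCountMatrix(
            protein_ids=[f"P{i:02d}" for i in range(n_p)],
            runs=make_runs(5),
            counts=counts,
            peptide_support=rng.integers(1, 6, size=n_p),
        )
        calls = {c.protein_id: c for c in run_differential_analysis(compute_scw(m), m)}

        totals = [sum(int(counts[i, j]) for i in range(n_p)) for j in range(10)]
        for i, pid in enumerate(m.protein_ids):
            scw_row = [counts[i, j] / totals[j] for j in range(10)]
            x, y = scw_row[:5], scw_row[5:]
            mx, my = sum(x) / 5, sum(y) / 5
            vx = sum((v - mx) ** 2 for v in x) / 4
            vy = sum((v - my) ** 2 for v in y) / 4
            sp2 = (4 * vx + 4 * vy) / 8
            if sp2 == 0:
                p_ref = 1.0 if mx == my else 0.0
            else:
                t = (mx - my) / math.sqrt(sp2 * 0.4)
                p_ref = t_cdf_via_incomplete_beta(t, 8)
            c = calls[pid]
            assert c.p_value == pytest.approx(p_ref, abs=1e-10)
            if mx == my:
                fc_ref, dir_ref = 1.0, NONE
            else:
                dir_ref = INCREASED if mx > my else DECREASED
                lo = min(mx, my)
                fc_ref = math.inf if lo == 0 else max(mx, my) / lo
            assert c.direction == dir_ref
            assert c.fold_change == pytest.approx(fc_ref)
            sel_ref = (
                p_ref < 0.01
                and m.peptide_support[i] >= 2
                and fc_ref > 2.5
                and dir_ref != NONE
                and all(
                    counts[i, j] > 0
                    for j in (range(5) if dir_ref == INCREASED else range(5, 10))
                )
            )
            assert c.selected == sel_ref


def test_differential_table_round_trip(tmp_path):
    m = build_toy_matrix()
    calls = run_differential_analysis(compute_scw(m), m)
    path = tmp_path / "diff.tsv"
    write_differential_table(calls, path)
    back = read_differential_table(path)
    ref = {c.protein_id: c for c in calls}
    assert len(back) == len(calls)
    for c in back:
        r = ref[c.protein_id]
        assert c.selected == r.selected and c.direction == r.direction
        assert c.p_value == pytest.approx(r.p_value, rel=1e-12)
    df = calls_to_frame(calls)
    assert list(df["fold_change"]) == sorted(df["fold_change"], reverse=True)
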