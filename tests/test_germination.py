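"""Germination phytotoxicity indices and group-level summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecotoxscreen.errors import (
    EmptyGroupError,
    InvalidControlError,
    InvalidInputError,
    UndefinedMeasureError,
)
from ecotoxscreen.germination import (
    GerminationReplicate,
    aerial_influence_index,
    compute_group_indices,
    exclude_sparse_groups,
    germination_energy,
    germination_index,
    germination_rate,
    mean_length,
    relative_root_growth,
    relative_seed_germination,
    vigor_index,
)


def _dish(n_final, n_seeds=10, roots=(), shoots=(), n_energy=0, cond="g", rid="r1", conc=500.0):
    return GerminationReplicate(
        condition=cond,
        concentration=conc,
        replicate_id=rid,
        n_seeds=n_seeds,
        n_germ_energy=min(n_energy, n_final),
        n_germ_final=n_final,
        root_lengths=tuple(roots),
        shoot_lengths=tuple(shoots),
    )


class TestElementaryIndices:
    @pytest.mark.parametrize(
        "n_seeds,n_energy,expected", [(10, 0, 0.0), (50, 24, 48.0), (10, 10, 100.0)]
    )
    def test_germination_energy(self, n_seeds, n_energy, expected):
        rep = _dish(n_seeds, n_seeds=n_seeds, n_energy=n_energy)
        assert germination_energy(rep) == pytest.approx(expected)

    def test_energy_undefined_without_reading(self):
        rep = GerminationReplicate("parsley", None, "r1", 10, None, 5)
        with pytest.raises(UndefinedMeasureError):
            germination_energy(rep)

    @pytest.mark.parametrize(
        "n_seeds,n_final,expected", [(10, 0, 0.0), (50, 43, 86.0), (10, 10, 100.0)]
    )
    def test_germination_rate(self, n_seeds, n_final, expected):
        assert germination_rate(_dish(n_final, n_seeds=n_seeds)) == pytest.approx(expected)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            GerminationReplicate("g", 0.0, "r", 0, 0, 0)
        with pytest.raises(InvalidInputError):
            GerminationReplicate("g", 0.0, "r", 10, 6, 5)  # energy > final
        with pytest.raises(InvalidInputError):
            GerminationReplicate("g", 0.0, "r", 10, 0, 11)

    @pytest.mark.parametrize(
        "values,expected", [([3.0], 3.0), ([2.0, 4.0], 3.0), ([1.0, 2.0, 6.0], 3.0)]
    )
    def test_mean_length(self, values, expected):
        assert mean_length(values) == pytest.approx(expected)

    def test_mean_length_empty_is_undefined_not_zero(self):
        with pytest.raises(UndefinedMeasureError):
            mean_length([])

    @pytest.mark.parametrize(
        "sample,control,expected", [(5.0, 5.0, 100.0), (2.5, 5.0, 50.0), (1.12, 3.72, 30.11)]
    )
    def test_relative_root_growth(self, sample, control, expected):
        assert relative_root_growth(sample, control) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "sample,control,expected", [(36, 36, 100.0), (18, 36, 50.0), (43, 36, 119.44)]
    )
    def test_relative_seed_germination(self, sample, control, expected):
        assert relative_seed_germination(sample, control) == pytest.approx(expected, abs=0.005)

    def test_zero_controls_rejected(self):
        with pytest.raises(InvalidControlError):
            relative_root_growth(1.0, 0.0)
        with pytest.raises(InvalidControlError):
            relative_seed_germination(5, 0)

    @pytest.mark.parametrize(
        "g,rrg,expected", [(72.0, 100.0, 72.0), (0.0, 50.0, 0.0), (86.0, 121.0, 104.06)]
    )
    def test_germination_index(self, g, rrg, expected):
        assert germination_index(g, rrg) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "g,rl,sl,expected", [(0, 3.0, 2.0, 0.0), (100, 1.0, 1.0, 200.0), (92, 3.72, 2.29, 552.92)]
    )
    def test_vigor_index(self, g, rl, sl, expected):
        assert vigor_index(g, rl, sl) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "gs,sls,gc,slc,expected",
        [
            (56, 0.90, 56, 0.90, 100.0),
            (50, 0.85, 56, 0.90, 84.33),
            (100, 2.0, 50, 2.0, 200.0),
        ],
    )
    def test_aerial_influence_index(self, gs, sls, gc, slc, expected):
        assert aerial_influence_index(gs, sls, gc, slc) == pytest.approx(expected, abs=0.005)

    def test_aerial_index_zero_control_product_rejected(self):
        with pytest.raises(InvalidControlError):
            aerial_influence_index(50, 1.0, 0, 1.0)

    @given(
        st.floats(0, 100), st.floats(0, 100), st.floats(0.1, 100), st.floats(0.1, 100)
    )
    def test_gi_monotone_in_both_arguments(self, g, rrg, dg, drrg):
        base = germination_index(g, rrg)
        assert germination_index(g + dg, rrg) >= base
        assert germination_index(g, rrg + drrg) >= base


class TestExclusion:
    def test_below_threshold_removed_and_logged(self):
        reps = [_dish(5, rid="a"), _dish(2, rid="b"), _dish(7, rid="c")]
        retained, excluded = exclude_sparse_groups(reps)
        assert [r.n_germ_final for r in retained] == [5, 7]
        assert len(excluded) == 1 and "b" in excluded[0][1]

    def test_boundary_inclusive(self):
        retained, excluded = exclude_sparse_groups([_dish(3)])
        assert len(retained) == 1 and not excluded

    def test_all_excluded_raises(self):
        with pytest.raises(EmptyGroupError):
            exclude_sparse_groups([_dish(0), _dish(0)])

    def test_order_preserved(self):
        reps = [_dish(9, rid="x"), _dish(4, rid="y"), _dish(6, rid="z")]
        retained, _ = exclude_sparse_groups(reps)
        assert [r.replicate_id for r in retained] == ["x", "y", "z"]


class TestGroupIndices:
    def test_control_vs_itself_reference_values(self, wheat_like_replicates):
        control, _ = wheat_like_replicates
        for mode in ("per_replicate", "pooled"):
            idx = compute_group_indices(control, control, mode=mode)
            assert idx["RRG"].mean == 100.0
            assert idx["RSG"].mean == 100.0
            assert idx["PI"].mean == 100.0
            assert idx["GI"].mean == pytest.approx(idx["G"].mean)
            if mode == "per_replicate":
                assert idx["RRG"].sd == 0.0
                assert idx["GI"].sd == pytest.approx(idx["G"].sd)

    def test_identical_replicates_have_zero_sd(self, wheat_like_replicates):
        control, treated = wheat_like_replicates
        idx = compute_group_indices(treated, control)
        for name in ("Eg", "G", "RL", "SL", "RRG", "RSG", "GI", "VI", "PI"):
            assert idx[name].sd == pytest.approx(0.0, abs=1e-10)

    def test_per_replicate_matches_hand_oracle(self, wheat_like_replicates):
        control, treated = wheat_like_replicates
        idx = compute_group_indices(treated, control)
        # hand-computed: control means RL=6, SL=8, germ=7, G=70
        assert idx["G"].mean == pytest.approx(50.0)
        assert idx["RRG"].mean == pytest.approx(100 * 3.0 / 6.0)
        assert idx["RSG"].mean == pytest.approx(100 * 5 / 7)
        assert idx["GI"].mean == pytest.approx(50 * 50 / 100)
        assert idx["VI"].mean == pytest.approx(50 * (3.0 + 7.0))
        assert idx["PI"].mean == pytest.approx(100 * (50 * 7.0) / (70 * 8.0))

    def test_pooled_equals_per_replicate_for_identical_dishes(self, wheat_like_replicates):
        control, treated = wheat_like_replicates
        per = compute_group_indices(treated, control, mode="per_replicate")
        pooled = compute_group_indices(treated, control, mode="pooled")
        for name in ("G", "RL", "SL", "RRG", "RSG", "GI", "VI", "PI"):
            assert per[name].mean == pytest.approx(pooled[name].mean)

    def test_heterogeneous_group_mean_sd_against_numpy_oracle(self):
        control = [_dish(7, roots=[6.0] * 7, shoots=[8.0] * 7, cond="c", rid=f"c{i}", conc=None) for i in range(3)]
        treated = [
            _dish(5, roots=[2.0] * 5, shoots=[6.0] * 5, rid="t1"),
            _dish(6, roots=[4.0] * 6, shoots=[7.0] * 6, rid="t2"),
        ]
        idx = compute_group_indices(treated, control)
        rrg_vals = [100 * 2.0 / 6.0, 100 * 4.0 / 6.0]
        assert idx["RRG"].mean == pytest.approx(np.mean(rrg_vals))
        assert idx["RRG"].sd == pytest.approx(np.std(rrg_vals, ddof=1))
        gi_vals = [50 * rrg_vals[0] / 100, 60 * rrg_vals[1] / 100]
        assert idx["GI"].mean == pytest.approx(np.mean(gi_vals))

    def test_empty_group_rejected(self, wheat_like_replicates):
        control, _ = wheat_like_replicates
        with pytest.raises(EmptyGroupError):
            compute_group_indices([], control)

    def test_zero_germination_dish_skipped_for_lengths(self, wheat_like_replicates):
        control, treated = wheat_like_replicates
        group = treated + [_dish(0, rid="t9")]
        idx = compute_group_indices(group, control)
        assert idx["G"].n == 6          # counts include the empty dish
        assert idx["RL"].n == 5         # lengths skip it
        assert idx["G"].mean == pytest.approx((5 * 50 + 0) / 6)

    def test_to_frame_round_trip(self, wheat_like_replicates):
        control, treated = wheat_like_replicates
        frame = compute_group_indices(treated, control).to_frame()
        assert set(frame["index"]) == {"Eg", "G", "RL", "SL", "RRG", "RSG", "GI", "VI", "PI"}
        assert (frame["condition"] == "1000 ug/mL").all()
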