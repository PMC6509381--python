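import numpy as np
import pytest
from hypothesis import given, strategies as st

import coastniche as cn
from coastniche.venn import GAIN_LABELS, LOSS_LABELS, LABELS, NODATA_CODE

from conftest import binary_map
from oracles import venn_oracle_codes


def all_16_maps():
    """One 4x4 grid whose 16 cells realise every (CUR,CLC,SLR,CCS) membership."""
    bits = np.array([[(i >> b) & 1 for i in range(16)] for b in range(4)])
    shape = (4, 4)
    cur, clc, slr, ccs = (bits[b].reshape(shape) for b in range(4))
    return cur, clc, slr, ccs


def habitats(cur, clc, slr, ccs):
    return cn.ScenarioHabitats(
        HCUR=binary_map(cur), HCLC=binary_map(clc),
        HSLR=binary_map(slr), HCCS=binary_map(ccs))


def random_quadruple(seed, shape=(8, 8)):
    rng = np.random.default_rng(seed)
    return [rng.integers(0, 2, shape) for _ in range(4)]


class TestBinarize:
    def test_threshold_zero_all_suitable(self):
        grid = cn.GridSpec(2, 2)
        m = cn.binarize(np.array([[0.1, 0.4], [0.0, 0.9]]), 0.0, grid)
        assert m.values.sum() == 4

    def test_threshold_above_one_none_suitable(self):
        grid = cn.GridSpec(2, 2)
        m = cn.binarize(np.full((2, 2), 0.99), 1.0, grid)
        assert m.values.sum() == 0

    def test_boundary_inclusive(self):
        grid = cn.GridSpec(1, 3)
        m = cn.binarize(np.array([[0.2, 0.5, 0.7]]), 0.5, grid)
        assert m.values.tolist() == [[0, 1, 1]]

    def test_nan_becomes_nodata(self):
        grid = cn.GridSpec(1, 2)
        m = cn.binarize(np.array([[np.nan, 0.8]]), 0.5, grid)
        assert m.nodata.tolist() == [[True, False]]
        assert m.as_set().tolist() == [[False, True]]


class TestChangedSets:
    def test_identical_maps_no_change(self):
        cur = np.ones((3, 3), dtype=int)
        sh = habitats(cur, cur, cur, cur)
        unchanged, gain, loss = cn.changed_sets(sh)
        assert unchanged.all() and not gain.any() and not loss.any()

    def test_empty_current_all_gain(self):
        z = np.zeros((3, 3), dtype=int)
        ccs = np.ones((3, 3), dtype=int)
        sh = habitats(z, z, z, ccs)
        unchanged, gain, loss = cn.changed_sets(sh)
        assert gain.all() and not loss.any() and not unchanged.any()

    @pytest.mark.parametrize("seed", range(10))
    def test_set_identities_on_random_maps(self, seed):
        cur, clc, slr, ccs = random_quadruple(seed)
        sh = habitats(cur, clc, slr, ccs)
        unchanged, gain, loss = cn.changed_sets(sh)
        cur_b, ccs_b = cur.astype(bool), ccs.astype(bool)
        # brute-force cell enumeration
        for idx in np.ndindex(cur.shape):
            assert unchanged[idx] == (cur_b[idx] and ccs_b[idx])
            assert gain[idx] == (ccs_b[idx] and not cur_b[idx])
            assert loss[idx] == (cur_b[idx] and not ccs_b[idx])
        assert not (unchanged & gain).any()
        assert not (unchanged & loss).any()
        assert not (gain & loss).any()
        np.testing.assert_array_equal(unchanged | gain | loss, cur_b | ccs_b)

    def test_grid_mismatch_rejected(self):
        a = binary_map(np.zeros((2, 2)))
        b = binary_map(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cn.ScenarioHabitats(a, a, a, b)


class TestAttribution:
    def test_all_16_membership_combinations_as_printed(self):
        cur, clc, slr, ccs = all_16_maps()
        decomp = cn.decompose(habitats(cur, clc, slr, ccs), "as_printed")
        expected = venn_oracle_codes(cur, clc, slr, ccs, "as_printed")
        np.testing.assert_array_equal(decomp.codes, expected)

    def test_all_16_membership_combinations_symmetric(self):
        cur, clc, slr, ccs = all_16_maps()
        decomp = cn.decompose(habitats(cur, clc, slr, ccs), "symmetric")
        expected = venn_oracle_codes(cur, clc, slr, ccs, "symmetric")
        np.testing.assert_array_equal(decomp.codes, expected)

    def test_coupling_gain_when_single_scenarios_unchanged(self):
        cur = np.zeros((2, 2), dtype=int)
        ccs = np.ones((2, 2), dtype=int)
        sh = habitats(cur, cur, cur, ccs)
        labels = cn.attribute_gain(sh)
        assert labels["c_ics_gain"].all()
        for k in ("p_clc_gain", "p_slr_gain", "s_ics_gain"):
            assert not labels[k].any()

    def test_degenerate_loss_case_both_conventions(self):
        cur = np.ones((2, 2), dtype=int)
        z = np.zeros((2, 2), dtype=int)
        sh = habitats(cur, z, z, z)
        printed = cn.attribute_loss(sh, "as_printed")
        assert printed["c_ics_loss"].all()
        symmetric = cn.attribute_loss(sh, "symmetric")
        assert symmetric["s_ics_loss"].all()

    def test_retained_under_both_is_printed_shared_loss(self):
        cur = np.array([[1]])
        sh = habitats(cur, cur, cur, np.array([[0]]))
        printed = cn.attribute_loss(sh, "as_printed")
        assert printed["s_ics_loss"].all()

    def test_unknown_convention_rejected(self):
        cur, clc, slr, ccs = all_16_maps()
        with pytest.raises(ValueError, match="convention"):
            cn.attribute_loss(habitats(cur, clc, slr, ccs), "other")

    @pytest.mark.parametrize("seed", range(10))
    def test_conventions_are_a_label_permutation(self, seed):
        cur, clc, slr, ccs = random_quadruple(seed)
        sh = habitats(cur, clc, slr, ccs)
        printed = cn.attribute_loss(sh, "as_printed")
        symmetric = cn.attribute_loss(sh, "symmetric")
        perm = {"s_ics_loss": "c_ics_loss", "c_ics_loss": "s_ics_loss",
                "p_clc_loss": "p_slr_loss", "p_slr_loss": "p_clc_loss"}
        for a, b in perm.items():
            np.testing.assert_array_equal(printed[a], symmetric[b])
        # gains are convention-invariant by construction
        np.testing.assert_array_equal(
            cn.decompose(sh, "as_printed").codes >= LABELS["p_clc_loss"],
            cn.decompose(sh, "symmetric").codes >= LABELS["p_clc_loss"])


class TestDecompose:
    def test_no_change_only_absent_and_unchanged(self):
        cur = np.array([[1, 0], [0, 1]])
        sh = habitats(cur, cur, cur, cur)
        decomp = cn.decompose(sh)
        assert set(np.unique(decomp.codes)) <= {LABELS["absent"], LABELS["unchanged"]}

    @given(st.integers(0, 10_000))
    def test_labels_partition_every_valid_cell(self, seed):
        cur, clc, slr, ccs = random_quadruple(seed)
        decomp = cn.decompose(habitats(cur, clc, slr, ccs))
        counts = decomp.label_counts()
        assert sum(counts.values()) == 64  # no nodata here
        gain = (np.asarray(ccs, bool) & ~np.asarray(cur, bool)).sum()
        loss = (np.asarray(cur, bool) & ~np.asarray(ccs, bool)).sum()
        assert sum(counts[l] for l in GAIN_LABELS) == gain
        assert sum(counts[l] for l in LOSS_LABELS) == loss

    def test_worked_4x4_fixture(self):
        # hand-built maps and hand-enumerated expected label grid
        cur = np.array([[1, 1, 0, 0],
                        [1, 1, 0, 0],
                        [0, 0, 0, 0],
                        [1, 1, 1, 1]])
        clc = np.array([[1, 0, 1, 0],
                        [1, 1, 0, 0],
                        [0, 0, 1, 1],
                        [1, 0, 0, 1]])
        slr = np.array([[1, 0, 0, 1],
                        [1, 1, 0, 0],
                        [0, 0, 1, 0],
                        [0, 1, 0, 1]])
        ccs = np.array([[1, 0, 1, 1],
                        [0, 1, 0, 0],
                        [1, 1, 1, 1],
                        [0, 0, 0, 1]])
        L = LABELS
        expected = np.array([
            # row 0: kept; lost-retained-nowhere; gained via clc only;
            #        gained via slr only
            [L["unchanged"], L["c_ics_loss"], L["p_clc_gain"], L["p_slr_gain"]],
            # row 1: lost but retained under both; kept; absent; absent
            [L["s_ics_loss"], L["unchanged"], L["absent"], L["absent"]],
            # row 2: gained only combined; gained only combined;
            #        gained under both singles; gained via clc only
            [L["c_ics_gain"], L["c_ics_gain"], L["s_ics_gain"], L["p_clc_gain"]],
            # row 3: lost, retained under clc; lost, retained under slr;
            #        lost, retained nowhere; kept
            [L["p_clc_loss"], L["p_slr_loss"], L["c_ics_loss"], L["unchanged"]],
        ])
        decomp = cn.decompose(habitats(cur, clc, slr, ccs), "as_printed")
        np.testing.assert_array_equal(decomp.codes, expected)

    def test_common_nodata_only_when_masked_everywhere(self):
        cur = np.ones((2, 2), dtype=int)
        nodata_all = np.array([[True, False], [False, False]])
        nodata_one = np.array([[True, True], [False, False]])
        sh = cn.ScenarioHabitats(
            HCUR=binary_map(cur, nodata_all), HCLC=binary_map(cur, nodata_one),
            HSLR=binary_map(cur, nodata_all), HCCS=binary_map(cur, nodata_all))
        decomp = cn.decompose(sh)
        assert (decomp.codes == NODATA_CODE).sum() == 1
        # cell masked only under one scenario is still labelled
        assert decomp.codes[0, 1] != NODATA_CODE


class TestAreaTable:
    def _decomp_from_counts(self, gain_counts, loss_counts):
        codes = []
        for lab, n in zip(GAIN_LABELS, gain_counts):
            codes += [LABELS[lab]] * n
        for lab, n in zip(LOSS_LABELS, loss_counts):
            codes += [LABELS[lab]] * n
        side = max(int(np.ceil(np.sqrt(len(codes)))), 1)
        arr = np.full(side * side, LABELS["absent"], dtype=np.int16)
        arr[: len(codes)] = codes
        grid = cn.GridSpec(side, side)
        return cn.DecompositionMap(grid, arr.reshape(side, side), "as_printed")

    def test_single_class_is_hundred_percent(self):
        decomp = self._decomp_from_counts([5, 0, 0, 0], [0, 0, 0, 0])
        table = cn.area_table(decomp).table.set_index("direction")
        assert table.loc["gain", "H_p_clc_pct"] == 100.0
        assert table.loc["gain", "H_changed"] == 5.0

    def test_zero_change_flagged(self):
        decomp = self._decomp_from_counts([0] * 4, [0] * 4)
        at = cn.area_table(decomp)
        assert set(at.zero_total_flags) == {"gain", "loss"}
        assert (at.table.filter(like="_pct") == 0).all().all()

    def test_cell_size_scales_area_quadratically(self):
        decomp = self._decomp_from_counts([3, 1, 0, 0], [0, 0, 0, 0])
        at = cn.area_table(decomp, cell_size=2.0).table.set_index("direction")
        assert at.loc["gain", "H_p_clc"] == 12.0
        assert at.loc["gain", "H_changed"] == 16.0

    def test_percentages_sum_to_hundred(self):
        decomp = self._decomp_from_counts([17, 5, 3, 11], [2, 9, 4, 1])
        table = cn.area_table(decomp).table
        for _, row in table.iterrows():
            pct = sum(row[f"H_{c}_pct"] for c in ("p_clc", "p_slr", "s_ics", "c_ics"))
            assert pct == pytest.approx(100.0, abs=0.01)
            comp = sum(row[f"H_{c}"] for c in ("p_clc", "p_slr", "s_ics", "c_ics"))
            assert comp == row["H_changed"]


class TestExportMap:
    def test_roundtrip_and_legend(self, tmp_path):
        cur, clc, slr, ccs = all_16_maps()
        decomp = cn.decompose(habitats(cur, clc, slr, ccs))
        decomp.codes[0, 0] = NODATA_CODE
        raster = tmp_path / "decomp.asc"
        legend = tmp_path / "legend.csv"
        cn.export_map(decomp, raster, legend)
        from coastniche.venn import import_map
        back = import_map(raster)
        np.testing.assert_array_equal(back.codes, decomp.codes)
        import pandas as pd
        leg = pd.read_csv(legend)
        present = np.unique(decomp.codes[decomp.codes != NODATA_CODE])
        assert len(leg) == len(present)
        assert (back.codes == NODATA_CODE).sum() == 1
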