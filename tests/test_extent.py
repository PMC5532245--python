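"""Change matrices and extent accounts: worked examples, oracle equivalence,
and the SEEA account identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilcap import (
    ChangeMatrix,
    LandCoverGrid,
    area_by_class,
    build_extent_account,
    change_matrix,
    extent_account_from_net_changes,
    net_change_summary,
)
from conftest import random_seea_pair
from oracles import brute_change_matrix, brute_patch_sizes, hand_extent_ledger


def make_grid(codes, cell_area=1.0, epoch=""):
    return LandCoverGrid(np.asarray(codes), cell_area, epoch=epoch)


class TestChangeMatrix:
    def test_identical_epochs_give_diagonal_matrix(self):
        g = make_grid([[2, 2, 6], [6, 13, 0]], cell_area=0.25)
        cm = change_matrix(g, g)
        areas = area_by_class(g)
        off_diag = cm.flows.to_numpy() - np.diag(np.diag(cm.flows.to_numpy()))
        assert not off_diag.any()
        for c, a in areas.items():
            assert cm.flows.at[c, c] == pytest.approx(a)

    def test_two_cell_flow(self):
        g0 = make_grid([[1, 2]])
        g1 = make_grid([[1, 1]])
        cm = change_matrix(g0, g1)
        assert cm.flows.at[2, 1] == 1.0
        assert cm.flows.at[2, 2] == 0.0
        assert cm.flows.at[1, 1] == 1.0

    def test_small_patch_folded_into_diagonal(self):
        # one isolated changed cell of 0.01 km² is below a 0.05 km² mmu
        codes0 = np.full((5, 5), 2)
        codes1 = codes0.copy()
        codes1[2, 2] = 1
        g0 = make_grid(codes0, cell_area=0.01)
        g1 = make_grid(codes1, cell_area=0.01)
        cm = change_matrix(g0, g1, min_mapping_unit=0.05)
        ident = change_matrix(g0, g0)
        pd.testing.assert_frame_equal(cm.flows, ident.flows)

    def test_mmu_respects_patch_labelling_oracle(self, rng):
        for _ in range(20):
            g0, g1 = random_seea_pair(rng, max_side=20, nodata_frac=0.0)
            mmu = 3.5 * g0.cell_area  # patches of < 4 cells fold back
            changed = g0.codes != g1.codes
            sizes = brute_patch_sizes(changed)
            expected_c1 = np.where((sizes > 0) & (sizes * g0.cell_area < mmu), g0.codes, g1.codes)
            cm = change_matrix(g0, g1, min_mapping_unit=mmu)
            expected = brute_change_matrix(g0.codes, expected_c1, g0.cell_area)
            np.testing.assert_allclose(cm.flows.to_numpy(), expected)

    def test_equals_brute_force_on_random_grids(self, rng):
        for _ in range(50):
            g0, g1 = random_seea_pair(rng)
            cm = change_matrix(g0, g1)
            np.testing.assert_allclose(
                cm.flows.to_numpy(), brute_change_matrix(g0.codes, g1.codes, g0.cell_area)
            )

    def test_marginals_reproduce_area_by_class(self, rng):
        for _ in range(20):
            g0, g1 = random_seea_pair(rng)
            cm = change_matrix(g0, g1)
            a0, a1 = area_by_class(g0), area_by_class(g1)
            for c in range(1, 15):
                assert cm.opening_areas[c] == pytest.approx(a0[c])
                assert cm.closing_areas[c] == pytest.approx(a1[c])
            assert cm.total_area == pytest.approx(sum(a0.values()))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            change_matrix(make_grid([[1]]), make_grid([[1, 2]]))

    def test_discordant_nodata_rejected_with_count(self):
        g0 = make_grid([[1, 0, 0]])
        g1 = make_grid([[1, 2, 0]])
        with pytest.raises(ValueError, match="1 cells"):
            change_matrix(g0, g1)

    def test_negative_flows_rejected(self):
        flows = pd.DataFrame(0.0, index=range(1, 15), columns=range(1, 15))
        flows.at[2, 1] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            ChangeMatrix(flows)


class TestExtentAccount:
    def toy_matrix(self):
        flows = pd.DataFrame(0.0, index=range(1, 15), columns=range(1, 15))
        flows.at[1, 2] = 5.0
        flows.at[3, 2] = 2.0
        return ChangeMatrix(flows)

    def test_three_class_hand_ledger(self):
        acct = build_extent_account(self.toy_matrix(), mode="net", managed_classes={1, 2})
        t = acct.table
        assert t.at["total_additions", 2] == 7.0
        assert t.at["managed_regression", 1] == -5.0
        assert t.at["natural_regression", 3] == -2.0
        assert t.at["closing", 2] == 7.0
        assert t.at["closing", 1] == 0.0

    def test_net_mode_one_sided_per_class(self, rng):
        for _ in range(20):
            g0, g1 = random_seea_pair(rng)
            acct = build_extent_account(change_matrix(g0, g1), mode="net")
            t = acct.table.fillna(0.0)
            assert ((t.loc["total_additions"] == 0) | (t.loc["total_reductions"] == 0)).all()

    def test_identity_matrix_keeps_opening(self):
        g = make_grid([[2, 6], [6, 2]])
        acct = build_extent_account(change_matrix(g, g))
        t = acct.table
        assert (t.loc["total_additions"].fillna(0) == 0).all()
        assert (t.loc["total_reductions"].fillna(0) == 0).all()
        assert t.at["closing", 2] == t.at["opening", 2] == 2.0

    def test_matches_hand_ledger_on_random_grids(self, rng):
        managed = {1, 2, 3, 4}
        for _ in range(20):
            g0, g1 = random_seea_pair(rng)
            cm = change_matrix(g0, g1)
            acct = build_extent_account(cm, managed_classes=managed)
            ledger = hand_extent_ledger(cm.flows.to_numpy(), managed)
            t = acct.table.fillna(0.0)
            for c in range(1, 15):
                assert t.at["total_additions", c] == pytest.approx(ledger["expansion"][c])
                assert t.at["total_reductions", c] == pytest.approx(ledger["regression"][c])
                assert t.at["closing", c] == pytest.approx(ledger["closing"][c])
                exp_row = "managed_expansion" if ledger["managed"][c] else "natural_expansion"
                assert t.at[exp_row, c] == pytest.approx(ledger["expansion"][c])

    def test_gross_mode_records_both_directions(self):
        # 2 -> 1 on one cell and 1 -> 2 on another net to zero but are real flows
        g0 = make_grid([[1, 2]])
        g1 = make_grid([[2, 1]])
        net = build_extent_account(change_matrix(g0, g1), mode="net").table
        gross = build_extent_account(change_matrix(g0, g1), mode="gross").table
        assert net.at["total_additions", 1] == 0.0
        assert gross.at["total_additions", 1] == 1.0
        assert gross.at["total_reductions", 1] == -1.0
        assert gross.at["closing", 1] == 1.0

    def test_account_identity_holds(self, rng):
        for mode in ("net", "gross"):
            g0, g1 = random_seea_pair(rng)
            acct = build_extent_account(change_matrix(g0, g1), mode=mode)
            acct.check_identity()

    def test_inconsistent_opening_areas_rejected_with_residuals(self):
        cm = self.toy_matrix()
        opening = {c: 0.0 for c in range(1, 15)}
        opening[1] = 999.0
        with pytest.raises(ValueError, match="residuals"):
            build_extent_account(cm, opening_areas=opening)

    def test_absent_class_serialized_as_na_not_zero(self):
        acct = build_extent_account(self.toy_matrix())
        assert np.isnan(acct.table.at["closing", 7])  # no mangrove in territory

    def test_net_changes_sum_to_zero_over_classes(self, rng):
        g0, g1 = random_seea_pair(rng, nodata_frac=0.0)
        acct = build_extent_account(change_matrix(g0, g1))
        net = (acct.table.loc["closing"] - acct.table.loc["opening"]).fillna(0.0)
        assert net.sum() == pytest.approx(0.0, abs=1e-9)


class TestFromNetChanges:
    def test_published_style_inputs(self):
        acct = extent_account_from_net_changes(
            {1: 99128.0, 2: 941477.0}, {1: 8354.0, 2: -8676.0}
        )
        assert acct.table.at["managed_expansion", 1] == 8354.0
        assert acct.table.at["closing", 1] == 107482.0
        assert acct.table.at["managed_regression", 2] == -8676.0
        assert acct.table.at["closing", 2] == 932801.0

    def test_nan_opening_marks_class_absent(self):
        acct = extent_account_from_net_changes({1: 10.0, 7: np.nan}, {1: 1.0})
        assert np.isnan(acct.table.at["closing", 7])
        assert acct.table.at["closing", 1] == 11.0


class TestNetChangeSummary:
    def test_percent_of_total(self):
        acct = extent_account_from_net_changes({1: 99128.0}, {1: 8354.0})
        summary = net_change_summary(acct, total_area=3_500_000.0)
        assert summary.at[1, "net_km2"] == pytest.approx(8354.0)
        assert summary.at[1, "net_pct"] == pytest.approx(100 * 8354 / 3_500_000)

    def test_zero_net_class(self):
        acct = extent_account_from_net_changes({5: 100.0}, {})
        summary = net_change_summary(acct, total_area=100.0)
        assert summary.at[5, "net_km2"] == 0.0
        assert summary.at[5, "net_pct"] == 0.0

    def test_total_area_must_be_positive(self):
        acct = extent_account_from_net_changes({5: 100.0}, {})
        with pytest.raises(ValueError):
            net_change_summary(acct, total_area=0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_change_matrix_conserves_total_area(seed):
    g0, g1 = random_seea_pair(np.random.default_rng(seed), max_side=15)
    cm = change_matrix(g0, g1)
    classified = int((g0.codes != 0).sum())
    assert cm.total_area == pytest.approx(classified * g0.cell_area)
    assert cm.opening_areas.sum() == pytest.approx(cm.closing_areas.sum())
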