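"""Quantification layer: assignment, efficiency formulas, filters, datasets."""

import numpy as np
import pandas as pd
import pytest

import bescreen as bs
from bescreen.screen_proc import (
    POS_COLS,
    TargetCounts,
    assign_reads,
    dichotomize,
    efficiency_table,
    filter_loci,
    per_base_efficiency,
    overall_efficiency,
    position_profile,
    pool_replicates,
    trinuc_proportions,
)
from bescreen.seqcore import ABE, LibraryMember, ProtospacerRecord


@pytest.fixture
def toy_member():
    rec = ProtospacerRecord("t0", "GGGGAAGGGGGGGGGGGGGG", "AGG", flank5="T", flank3="C")
    return LibraryMember(record=rec, barcode5="AAAAAA", barcode3="CCCCCC")


def make_counts(rec, outcome_counts, rep="rep1"):
    return TargetCounts(rec.id, rec, rep, outcome_counts)


class TestEfficiencyFormulas:
    def test_per_base_formula(self, toy_member):
        rec = toy_member.record
        edited5 = rec.sequence[:4] + "G" + rec.sequence[5:]
        tc = make_counts(rec, {rec.sequence: 75, edited5: 25})
        eff = per_base_efficiency(tc, ABE)
        assert eff[5] == 25.0 and eff[6] == 0.0

    def test_all_wild_type_is_zero_everywhere(self, toy_member):
        rec = toy_member.record
        eff = per_base_efficiency(make_counts(rec, {rec.sequence: 50}), ABE)
        assert set(eff.values()) == {0.0}

    def test_overall_formula_and_complement(self, toy_member):
        rec = toy_member.record
        edited = rec.sequence[:4] + "GG" + rec.sequence[6:]
        tc = make_counts(rec, {rec.sequence: 370, edited: 30})
        assert overall_efficiency(tc) == pytest.approx(7.5)
        wt_pct = 100.0 * 370 / 400
        assert overall_efficiency(tc) == pytest.approx(100.0 - wt_pct)

    def test_multi_outcome_matches_read_level_tally(self, toy_member):
        """Brute-force per-read counting oracle over a 3-outcome fixture."""
        rec = toy_member.record
        o56 = rec.sequence[:4] + "GG" + rec.sequence[6:]
        o5 = rec.sequence[:4] + "G" + rec.sequence[5:]
        tc = make_counts(rec, {rec.sequence: 60, o5: 30, o56: 10})
        reads = [rec.sequence] * 60 + [o5] * 30 + [o56] * 10
        eff = per_base_efficiency(tc, ABE)
        for p in (5, 6):
            oracle = 100.0 * sum(1 for r in reads if r[p - 1] == "G") / len(reads)
            assert eff[p] == pytest.approx(oracle)
        assert overall_efficiency(tc) == pytest.approx(
            100.0 * sum(1 for r in reads if r != rec.sequence) / len(reads)
        )

    def test_zero_reads_is_an_error(self, toy_member):
        with pytest.raises(ValueError):
            per_base_efficiency(make_counts(toy_member.record, {}), ABE)

    def test_per_position_never_exceeds_overall(self, abemax_screen):
        counts = pool_replicates(bs.counts_from_screen(abemax_screen))
        table = efficiency_table(counts, ABE)
        pos_max = table[POS_COLS].max(axis=1, skipna=True).fillna(0.0)
        assert (pos_max <= table["overall_pct"] + 1e-9).all()


class TestAssignReads:
    def test_hand_tally_fixture(self, toy_member):
        """20 hand-written reads, 3 of them non-canonical, vs a hand tally."""
        rec = toy_member.record
        wt = rec.sequence
        e5 = wt[:4] + "G" + wt[5:]
        e56 = wt[:4] + "GG" + wt[6:]
        noncanon = "T" + wt[1:]          # G->T is not an ABE transition... position1 is G
        noncanon2 = wt[:4] + "C" + wt[5:]  # A->C
        mk = lambda core: toy_member.barcode5 + core + rec.pam + toy_member.barcode3
        reads = ([mk(wt)] * 10 + [mk(e5)] * 4 + [mk(e56)] * 3
                 + [mk(noncanon)] * 2 + [mk(noncanon2)])
        res = assign_reads(reads, [toy_member], ABE)
        assert res.n_assigned == 17 and res.n_dropped_noncanonical == 3
        (tc,) = res.counts
        assert tc.outcome_counts == {wt: 10, e5: 4, e56: 3}

    def test_wrong_geometry_and_unknown_barcodes_dropped(self, toy_member):
        rec = toy_member.record
        good = toy_member.barcode5 + rec.sequence + rec.pam + toy_member.barcode3
        res = assign_reads([good, good[:-1], "T" * 35], [toy_member], ABE)
        assert res.n_assigned == 1
        assert res.n_dropped_geometry == 1
        assert res.n_dropped_unassigned == 1

    def test_duplicate_barcode_pair_rejected(self, toy_member):
        rec2 = ProtospacerRecord("t1", "C" * 20, "TGG")
        dup = LibraryMember(record=rec2, barcode5=toy_member.barcode5,
                            barcode3=toy_member.barcode3)
        with pytest.raises(ValueError, match="duplicate barcode"):
            assign_reads([], [toy_member, dup], ABE)

    def test_roundtrip_from_simulated_screen(self, abemax_screen):
        """simulate -> flatten to reads -> assign reproduces the count maps."""
        from bescreen.screen_sim import screen_reads

        reads = screen_reads(abemax_screen, replicate=0, shuffle_seed=1)
        res = assign_reads(reads, abemax_screen.library, ABE)
        assert res.n_dropped_noncanonical == 0 and res.n_dropped_unassigned == 0
        expected = abemax_screen.counts[0]
        got = {tc.target_id: tc.outcome_counts for tc in res.counts}
        assert got == {k: v for k, v in expected.items() if v}


class TestFilters:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["target_id", "depth", "overall_pct", *POS_COLS])
        return df

    def test_depth_boundary_at_100(self):
        t = self._table([("a", 99, 5.0) + (np.nan,) * 20,
                         ("b", 100, 5.0) + (np.nan,) * 20])
        out = filter_loci(t, min_depth=100, above_mean=False)
        assert list(out["target_id"]) == ["b"]

    def test_above_mean_arithmetic(self):
        rows = [(f"t{i}", 200, e) + (np.nan,) * 20 for i, e in enumerate([1, 2, 3, 4, 10])]
        out = filter_loci(self._table(rows), above_mean=True)
        assert list(out["overall_pct"]) == [10]
        assert out.attrs["mean_overall_pct"] == pytest.approx(4.0)

    def test_above_mean_flag_off_is_depth_only(self):
        rows = [(f"t{i}", d, e) + (np.nan,) * 20
                for i, (d, e) in enumerate([(50, 1), (150, 1), (150, 9)])]
        out = filter_loci(self._table(rows), above_mean=False)
        assert len(out) == 2

    def test_depth_filter_idempotent(self):
        rows = [(f"t{i}", d, 1.0) + (np.nan,) * 20 for i, d in enumerate([80, 120, 300])]
        once = filter_loci(self._table(rows), above_mean=False)
        twice = filter_loci(once, above_mean=False)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_empty_result_warns_not_raises(self):
        rows = [("a", 10, 1.0) + (np.nan,) * 20]
        with pytest.warns(UserWarning):
            out = filter_loci(self._table(rows), above_mean=False)
        assert out.empty


class TestDichotomize:
    def _table(self):
        row = {"target_id": "a", "depth": 1000, "overall_pct": 6.0}
        row.update({c: np.nan for c in POS_COLS})
        row["pos5"], row["pos6"], row["pos7"] = 4.26, 4.30, 0.0
        return pd.DataFrame([row])

    def test_tie_goes_to_edited_and_zero_is_not(self):
        labelled = dichotomize(self._table(), mean_efficiency=4.26)
        lab = dict(zip(labelled["position"], labelled["label"]))
        assert lab[5] == 1      # exactly at the mean -> edited
        assert lab[6] == 1      # 4.30 above the 4.26 mean -> edited
        assert lab[7] == 0


class TestAssembleDataset:
    def test_ratio_splits_and_determinism(self, context_dataset):
        _, _, dataset = context_dataset
        per_target = dataset.examples.groupby("target_id")["label"].max()
        n_edited = int((per_target == 1).sum())
        n_unedited = int((per_target == 0).sum())
        assert n_unedited == round(0.25 * n_edited)
        for run in range(dataset.n_runs):
            col = dataset.splits.iloc[:, run]
            n = len(col)
            n_train = (col == "train").sum()
            n_test = (col == "test").sum()
            n_val = (col == "validation").sum()
            assert abs(n_train - 0.8 * n) <= 2
            assert abs(n_test - n_val) <= 2  # 1:1 within rounding per stratum
            assert n_train + n_test + n_val == n

    def test_exact_80_10_10_on_100_targets(self):
        labelled = pd.DataFrame({
            "target_id": [f"t{i}" for i in range(200)],
            "position": [5] * 200,
            "efficiency_pct": [9.0] * 100 + [0.0] * 100,
            "label": [1] * 100 + [0] * 100,
        })
        records = {f"t{i}": ProtospacerRecord(f"t{i}", "A" * 20, "AGG")
                   for i in range(200)}
        ds = bs.assemble_dataset(labelled, records, unedited_ratio=0.0,
                                 train_frac=0.8, n_runs=1, seed=3)
        col = ds.splits.iloc[:, 0]
        assert ((col == "train").sum(), (col == "test").sum(),
                (col == "validation").sum()) == (80, 10, 10)

    def test_same_seed_reproduces_splits(self, context_dataset):
        _, counts, dataset = context_dataset
        table = efficiency_table(counts, ABE)
        mean_pct = bs.library_mean_efficiency(table)
        labelled = dichotomize(filter_loci(table, above_mean=False), mean_pct)
        # same seed -> same chosen targets, all covered by dataset.records
        ds2 = bs.assemble_dataset(labelled, dataset.records, n_runs=2, seed=7)
        pd.testing.assert_frame_equal(ds2.splits, dataset.splits)

    def test_insufficient_unedited_pool_raises(self):
        labelled = pd.DataFrame({
            "target_id": ["a", "b"], "position": [5, 5],
            "efficiency_pct": [9.0, 8.0], "label": [1, 1],
        })
        records = {k: ProtospacerRecord(k, "A" * 20, "AGG") for k in "ab"}
        with pytest.raises(ValueError, match="pool too small"):
            bs.assemble_dataset(labelled, records, unedited_ratio=0.5, n_runs=1)


class TestProfilesAndMotifs:
    def test_position_profile_argmax_abemax(self, abemax_screen):
        counts = pool_replicates(bs.counts_from_screen(abemax_screen))
        filtered = filter_loci(efficiency_table(counts, ABE))
        _, argmax = position_profile(filtered)
        assert argmax == 6

    def test_flat_truth_window_gives_flat_profile(self):
        from bescreen.screen_sim import EditorTruthModel, ScreenConfig

        lib = bs.generate_library(300, seed=11)
        truth = EditorTruthModel("flat", ABE, window={p: 0.05 for p in range(1, 21)})
        cfg = ScreenConfig(n_targets=300, depth_mean=2000, replicate_noise_sd=0.0,
                           n_replicates=1, seed=11)
        counts = bs.counts_from_screen(bs.simulate_reads(lib, truth, cfg))
        table = efficiency_table(counts, ABE)
        prof, _ = position_profile(filter_loci(table, above_mean=False))
        assert np.nanmax(prof) - np.nanmin(prof) < 0.75  # percent points

    def test_trinuc_proportions_sum_to_one_and_tc_preference(self, context_dataset):
        screen, counts, dataset = context_dataset
        table = efficiency_table(counts, ABE)
        mean_pct = bs.library_mean_efficiency(table)
        filtered = filter_loci(table)
        labelled = dichotomize(filtered, mean_pct)
        records = {m.record.id: m.record for m in screen.library}
        props = trinuc_proportions(labelled, records)
        assert props.sum() == pytest.approx(1.0)
        # preceding-T preference of the simulated deaminase dominates
        by_prev = props.groupby(lambda m: m[0]).sum()
        assert by_prev.idxmax() == "T"
        assert by_prev["T"] > by_prev.get("A", 0.0)

    def test_single_motif_library_is_degenerate(self):
        rec = ProtospacerRecord("x", "GT" + "A" + "C" + "G" * 16, "AGG", "T", "C")
        labelled = pd.DataFrame({
            "target_id": ["x"], "position": [3],
            "efficiency_pct": [9.0], "label": [1],
        })
        props = trinuc_proportions(labelled, {"x": rec})
        assert props.to_dict() == {"TAC": 1.0}
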