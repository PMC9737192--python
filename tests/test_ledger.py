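"""Ledger accumulation, persistence tables and duration statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactprof.interactions import InteractionRecord
from contactprof.ledger import (InteractionLedger, accumulate, bond_durations,
                                per_atom_type_profile, per_pair_persistence,
                                per_type_persistence, record_key, residue_label)


def _rec(itype="hbond", lig=("O1",), res=("A", "TYR", 426), rec=("OH",)):
    return InteractionRecord(
        itype=itype, frame_index=0, ligand_atoms=(0,), ligand_atom_names=lig,
        receptor_residue=res, receptor_atoms=(1,), receptor_atom_names=rec,
        geometry={"distance": 3.0})


def _ledger(total, **key_frames):
    return InteractionLedger(total_frames=total,
                             occupancy={k: sorted(v)
                                        for k, v in key_frames.items()})


def test_residue_labels_match_table_conventions():
    assert residue_label(("A", "TYR", 426)) == "Tyr426"
    assert residue_label(("A", "ARG", 364)) == "Arg364"
    assert residue_label(("B", "DA", 113)) == "DA113"
    assert residue_label(("B", "DT", 9)) == "DT9"


def test_record_key_formats():
    assert record_key(_rec()) == "hbond|O1|Tyr426|OH"
    assert record_key(_rec(itype="hydrophobic", lig=("C13",),
                           res=("B", "DT", 9), rec=("C7",))) == \
        "hydrophobic|C13|DT9|*"


class TestAccumulate:
    def test_occupancy_lists(self):
        recs = [[_rec()], [], [_rec()], [], [_rec()]]
        led = accumulate(recs)
        assert led.total_frames == 5
        assert led.occupancy == {"hbond|O1|Tyr426|OH": [0, 2, 4]}

    def test_duplicates_collapse(self):
        led = accumulate([[_rec(), _rec()]])
        assert led.occupancy["hbond|O1|Tyr426|OH"] == [0]

    def test_empty_input_preserves_total(self):
        led = accumulate([], total_frames=7)
        assert led.total_frames == 7 and led.occupancy == {}

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            accumulate([[_rec()], [_rec()]], total_frames=1)


class TestPerType:
    def test_always_present_is_100(self):
        df = per_type_persistence(_ledger(10, **{"hbond|O1|Tyr426|OH": range(10)}))
        assert df.set_index("itype").loc["hbond", "percent"] == 100.0

    def test_778_of_1000_is_77_8(self):
        df = per_type_persistence(_ledger(
            1000, **{"pistacking|C1R|DA113|*": range(778)}))
        assert df.set_index("itype").loc["pistacking", "percent"] == 77.8

    def test_absent_type_is_0(self):
        df = per_type_persistence(_ledger(10, **{"hbond|O1|Tyr426|OH": [0]}))
        assert df.set_index("itype").loc["saltbridge", "percent"] == 0.0

    def test_union_across_keys_of_a_type(self):
        df = per_type_persistence(_ledger(
            10, **{"hbond|O1|Tyr426|OH": [0, 1], "hbond|O6|Arg364|NH1": [1, 2]}))
        assert df.set_index("itype").loc["hbond", "percent"] == 30.0

    def test_zero_frames_is_error(self):
        with pytest.raises(ValueError):
            per_type_persistence(_ledger(0))


class TestPerPair:
    def test_98_of_100(self):
        df = per_pair_persistence(_ledger(
            100, **{"hbond|O1|Tyr426|OH": range(98)}))
        assert df.iloc[0].tolist()[:3] == ["O1", "Tyr426", 98]

    def test_below_threshold_omitted(self):
        led = _ledger(1000, **{"hbond|O1|Tyr426|OH": range(96)})  # 9.6 %
        assert per_pair_persistence(led, min_percent=10).empty
        assert not per_pair_persistence(led, min_percent=5).empty

    def test_full_occupancy_is_100(self):
        df = per_pair_persistence(_ledger(50, **{"hbond|O1|Tyr426|OH": range(50)}))
        assert df.iloc[0]["percent"] == 100

    def test_multi_atom_groups_expand_per_atom(self):
        df = per_pair_persistence(_ledger(
            10, **{"saltbridge|C9+O91+O92|Lys425|*": range(10)}))
        assert df["ligand_atom"].tolist() == ["C9", "O91", "O92"]
        assert set(df["percent"]) == {100}

    def test_union_across_itypes_per_pair(self):
        df = per_pair_persistence(_ledger(
            10, **{"hbond|O1|Tyr426|OH": [0, 1, 2],
                   "hydrophobic|O1|Tyr426|*": [2, 3, 4]}))
        assert df.iloc[0]["percent"] == 50


class TestPerAtomProfile:
    def test_single_type_row(self):
        df = per_atom_type_profile(_ledger(
            10, **{"hbond|O1|Tyr426|OH": range(5)}))
        row = df.set_index("ligand_atom").loc["O1"]
        assert row["hbond"] == 50.0
        assert row["hydrophobic"] == 0.0

    def test_empty_ledger_empty_matrix(self):
        assert per_atom_type_profile(_ledger(10)).empty

    def test_row_value_bounds_pair_rows(self):
        # union inequality: a type's percent for an atom >= the percent of
        # any single (atom, residue) pair restricted to that type
        led = _ledger(20, **{"hbond|O1|Tyr426|OH": [0, 1, 2, 3],
                             "hbond|O1|Arg364|NH1": [3, 4, 5]})
        prof = per_atom_type_profile(led).set_index("ligand_atom")
        assert prof.loc["O1", "hbond"] == 30.0  # union of 6 frames / 20
        for key in led.occupancy:
            assert prof.loc["O1", "hbond"] >= 100.0 * len(led.occupancy[key]) / 20


class TestDurations:
    def test_runs_decomposition(self):
        d = bond_durations(_ledger(10, k=[0, 1, 2, 5, 6]))["k"]
        assert d.runs == [3, 2] and d.longest_run == 3 and d.frames_present == 5

    def test_single_frame(self):
        d = bond_durations(_ledger(10, k=[4]))["k"]
        assert d.longest_run == 1

    @given(st.sets(st.integers(min_value=0, max_value=199), max_size=80))
    @settings(max_examples=50, deadline=None)
    def test_runs_match_linear_scan_oracle(self, frames):
        occ = sorted(frames)
        d = bond_durations(_ledger(200, k=occ))["k"]
        if not occ:
            assert d.frames_present == 0 and d.runs == []
            return
        # direct scan oracle
        runs, cur = [], 0
        for t in range(200):
            if t in frames:
                cur += 1
            elif cur:
                runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        assert d.runs == runs
        assert sum(d.runs) == d.frames_present == len(occ)
        assert d.longest_run == max(runs)


@given(st.dictionaries(
    st.sampled_from(["hbond|O1|Tyr426|OH", "hbond|O6|Arg364|NH1",
                     "hydrophobic|C13|DT9|*", "waterbridge|O2|Asp533|OD1"]),
    st.sets(st.integers(min_value=0, max_value=49), max_size=50),
))
@settings(max_examples=50, deadline=None)
def test_percent_bounds_and_conservation(occupancy):
    led = InteractionLedger(total_frames=50,
                            occupancy={k: sorted(v)
                                       for k, v in occupancy.items() if v})
    df = per_type_persistence(led)
    assert ((df["percent"] >= 0) & (df["percent"] <= 100)).all()
    dfp = per_pair_persistence(led, min_percent=0)
    assert ((dfp["percent"] >= 0) & (dfp["percent"] <= 100)).all() or dfp.empty
    assert sum(len(v) for v in led.occupancy.values()) == \
        sum(d.frames_present for d in bond_durations(led).values())


def test_monotonicity_adding_records_never_decreases_percent():
    base = _ledger(10, **{"hbond|O1|Tyr426|OH": [0, 1]})
    more = _ledger(10, **{"hbond|O1|Tyr426|OH": [0, 1, 5],
                          "hydrophobic|C13|DT9|*": [2]})
    p1 = per_type_persistence(base).set_index("itype")["percent"]
    p2 = per_type_persistence(more).set_index("itype")["percent"]
    assert (p2 >= p1).all()
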