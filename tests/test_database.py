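import itertools

import pytest

from pamrm.chem import ADDUCTS, AcylChain, LipidClass
from pamrm.database import (
    ChainSpace,
    MRMTransition,
    TransitionOverflowError,
    build_ms1_table,
    build_msms_table,
    build_transition_list,
    decompose_sum_composition,
    transitions_to_frame,
)


def brute_force_pairs(m, n, space):
    """Independent oracle: double loop over every chain pair in the space."""
    chains = list(space.chains())
    found = set()
    for c1, c2 in itertools.product(chains, repeat=2):
        if c1.carbons + c2.carbons == m and c1.double_bonds + c2.double_bonds == n:
            found.add(tuple(sorted((c1, c2), key=lambda c: c.sort_key)))
    return found


class TestChainSpace:
    def test_grid_membership(self):
        space = ChainSpace(min_carbons=14, max_carbons=20,
                           allow_odd_carbons=False, max_db_per_chain=2)
        assert AcylChain(16, 2) in space
        assert AcylChain(15, 0) not in space
        assert AcylChain(16, 3) not in space
        assert AcylChain(12, 0) not in space

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            ChainSpace(min_carbons=20, max_carbons=12)

    def test_default_panel_is_curated(self):
        space = ChainSpace.default_panel()
        assert AcylChain(18, 1) in space
        assert AcylChain(20, 2) not in space  # not a curated chain


class TestDecompose:
    def test_34_2_default_panel_reproduces_published_candidates(self):
        pairs = decompose_sum_composition(34, 2, ChainSpace.default_panel())
        as_text = {(str(a), str(b)) for a, b in pairs}
        assert as_text == {
            ("14:2", "20:0"),
            ("16:0", "18:2"),
            ("16:1", "18:1"),
            ("16:2", "18:0"),
        }

    def test_symmetric_self_pair(self):
        space = ChainSpace(min_carbons=12, max_carbons=12, max_db_per_chain=0)
        pairs = decompose_sum_composition(24, 0, space)
        assert pairs == [(AcylChain(12, 0), AcylChain(12, 0))]

    def test_empty_set_allowed(self):
        assert decompose_sum_composition(10, 6) == []

    @pytest.mark.parametrize("m,n", [(28, 0), (34, 2), (36, 4), (31, 1), (40, 7)])
    def test_matches_brute_force_oracle(self, m, n):
        for space in (ChainSpace(), ChainSpace.default_panel(),
                      ChainSpace(min_carbons=14, max_carbons=18,
                                 allow_odd_carbons=False, max_db_per_chain=3)):
            assert set(decompose_sum_composition(m, n, space)) == \
                brute_force_pairs(m, n, space)

    def test_deterministic_order(self):
        pairs = decompose_sum_composition(36, 3)
        keys = [p[0].sort_key + p[1].sort_key for p in pairs]
        assert keys == sorted(keys)


class TestMs1Table:
    def test_single_species_row(self):
        table = build_ms1_table("PA", (34, 34), (2, 2))
        assert len(table) == 1
        row = table.iloc[0]
        assert row["[M-H]- (2dp)"] == "671.46"
        assert row["formula"] == "C37H69O8P"
        adduct_columns = [c for c in table.columns if c in ADDUCTS]
        assert len(adduct_columns) == 9

    def test_grid_cardinality(self):
        table = build_ms1_table("PA", (30, 40), (0, 6))
        assert len(table) == 11 * 7

    def test_undecomposable_row_flagged(self):
        table = build_ms1_table("PA", (10, 10), (6, 6))
        assert not table.iloc[0]["valid"]
        assert table.iloc[0]["n_chain_pairs"] == 0

    def test_empty_range_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_ms1_table("PA", (34, 30), (0, 2))


class TestMsmsTable:
    def test_acyl_anion_row_18_1(self):
        table = build_msms_table(AcylChain(18, 1))
        anion = table[table["fragment_type"] == "acyl_anion"]
        assert anion.iloc[0]["mz"] == pytest.approx(281.2486, abs=5e-4)

    def test_lyso_row_16_0(self):
        table = build_msms_table(AcylChain(16, 0))
        lyso = table[table["fragment_type"] == "lyso_[M-H]-"]
        assert lyso.iloc[0]["mz"] == pytest.approx(409.2361, abs=5e-4)

    def test_precursor_rows_cover_space(self):
        space = ChainSpace.default_panel()
        table = build_msms_table(AcylChain(16, 0), space=space)
        precursors = table[table["fragment_type"] == "precursor_[M-H]-"]
        assert len(precursors) == len(list(space.chains()))

    def test_invalid_chain_errors(self):
        with pytest.raises(ValueError):
            build_msms_table(AcylChain(0, 0))


class TestTransitionList:
    def test_34_2_yields_eight_transitions(self):
        transitions = build_transition_list([(34, 2)])
        assert len(transitions) == 8
        q3_2dp = {t.q3_mz for t in transitions}
        assert len(q3_2dp) == 8
        assert all(t.q1_mz > t.q3_mz > 0 for t in transitions)
        assert all(t.dwell_ms == 30.0 and t.collision_energy_eV == 39.0
                   for t in transitions)

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_transition_list([])

    def test_duplicate_species_errors(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_transition_list([(34, 2), (34, 2)])

    def test_overflow_reports_count(self):
        panel = [(m, n) for m in range(28, 40) for n in range(0, 3)]
        with pytest.raises(TransitionOverflowError) as excinfo:
            build_transition_list(panel, max_transitions=75)
        assert excinfo.value.count > 75
        assert "75" in str(excinfo.value)

    def test_priority_truncates_in_order(self):
        panel = [(m, n) for m in range(28, 40) for n in range(0, 3)]
        priority = sorted(panel, key=lambda s: (s[1], s[0]))
        transitions = build_transition_list(panel, max_transitions=40,
                                            priority=priority)
        assert 0 < len(transitions) <= 40
        # the top-priority species survives
        assert any(t.sum_composition == tuple(priority[0]) for t in transitions)

    def test_sharing_impossible_within_one_sum_composition(self):
        # if two pairs of the same (m, n) shared a chain, their partners
        # would have identical carbons and double bonds, i.e. be the same
        # pair; so shared_fragment is always False for grid decompositions
        for m, n in [(32, 2), (34, 2), (36, 3)]:
            for t in build_transition_list([(m, n)], space=ChainSpace()):
                assert t.shared_fragment is False

    def test_q3_ordering_deterministic(self):
        a = build_transition_list([(34, 2), (36, 2)])
        b = build_transition_list([(34, 2), (36, 2)])
        assert [t.name for t in a] == [t.name for t in b]

    def test_transition_invariants(self):
        with pytest.raises(ValueError, match="q1 > q3"):
            MRMTransition(q1_mz=100.0, q3_mz=200.0, sum_composition=(34, 2),
                          diagnostic_chain=AcylChain(16, 0))
        with pytest.raises(ValueError, match="fit inside"):
            MRMTransition(q1_mz=671.46, q3_mz=281.24, sum_composition=(16, 2),
                          diagnostic_chain=AcylChain(18, 1))

    def test_frame_layout(self):
        df = transitions_to_frame(build_transition_list([(34, 2)]))
        assert list(df["q1 (2dp)"].unique()) == ["671.46"]
        assert "223.17" in set(df["q3 (2dp)"])
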