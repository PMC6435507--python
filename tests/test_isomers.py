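import numpy as np
import pytest

from pamrm.chem import AcylChain, LipidClass, LipidSpecies
from pamrm.database import ChainSpace, decompose_sum_composition
from pamrm.isomers import (
    Confidence,
    assign_sn_positions,
    confirm_by_coelution,
    identify_species,
    match_fragments,
    resolve_pairs,
)
from pamrm.spectra import EPISpectrum

from conftest import gaussian_chromatogram

CANDIDATES_34_2 = decompose_sum_composition(34, 2, ChainSpace.default_panel())


class TestMatchFragments:
    def test_worked_example_presence(self, worked_epi_spectrum):
        matches = match_fragments(worked_epi_spectrum, CANDIDATES_34_2,
                                  mz_tol=0.3)
        present = {str(c) for c, m in matches.items() if m.present}
        assert present == {"16:0", "16:1", "18:1", "18:2"}
        absent = {str(c) for c, m in matches.items() if not m.present}
        assert {"14:2", "20:0"} <= absent

    def test_empty_candidates_empty_map(self, worked_epi_spectrum):
        assert match_fragments(worked_epi_spectrum, []) == {}

    def test_empty_spectrum_errors(self):
        empty = EPISpectrum(671.46, 9.4, np.array([]), np.array([]))
        with pytest.raises(ValueError, match="empty spectrum"):
            match_fragments(empty, CANDIDATES_34_2)

    def test_boundary_peak_matched(self):
        # peak exactly mz_tol away: closed interval, still matched
        chain = AcylChain(18, 1)
        from pamrm.chem import acyl_anion_mz

        theory = acyl_anion_mz(chain)
        spec = EPISpectrum(671.46, 9.4, np.array([theory + 0.3]),
                           np.array([100.0]))
        matches = match_fragments(spec, [(chain, AcylChain(16, 1))], mz_tol=0.3)
        assert matches[chain].present

    def test_subthreshold_peak_absent(self):
        from pamrm.chem import acyl_anion_mz

        chain = AcylChain(18, 1)
        spec = EPISpectrum(
            671.46, 9.4,
            np.array([acyl_anion_mz(chain), 500.0]),
            np.array([0.5, 100.0]),  # 0.5% of base peak < 1% threshold
        )
        matches = match_fragments(spec, [(chain, AcylChain(16, 1))])
        assert not matches[chain].present


class TestResolvePairs:
    def test_worked_example_two_pairs(self, worked_epi_spectrum):
        matches = match_fragments(worked_epi_spectrum, CANDIDATES_34_2)
        assignments = resolve_pairs(matches, CANDIDATES_34_2)
        names = {frozenset(str(c) for c in a.chains) for a in assignments}
        assert names == {frozenset({"16:1", "18:1"}),
                         frozenset({"16:0", "18:2"})}
        assert all(a.confidence is Confidence.RESOLVED for a in assignments)

    def test_unpaired_fragment_rejected(self):
        from pamrm.chem import acyl_anion_mz

        spec = EPISpectrum(671.46, 9.4,
                           np.array([acyl_anion_mz(AcylChain(16, 0))]),
                           np.array([100.0]))
        matches = match_fragments(spec, CANDIDATES_34_2)
        assert resolve_pairs(matches, CANDIDATES_34_2) == []

    def test_self_pair_single_fragment_suffices(self):
        from pamrm.chem import acyl_anion_mz

        candidates = decompose_sum_composition(36, 2)
        spec = EPISpectrum(699.49, 9.4,
                           np.array([acyl_anion_mz(AcylChain(18, 1))]),
                           np.array([100.0]))
        matches = match_fragments(spec, candidates)
        assignments = resolve_pairs(matches, candidates)
        assert len(assignments) == 1
        assert assignments[0].species.name == "PA(18:1/18:1)"

    def test_shared_fragment_flags_pair_ambiguous(self):
        # candidate pairs spanning different sum compositions can share a
        # chain; both accepted pairs must then be flagged
        from pamrm.chem import acyl_anion_mz

        pairs = [(AcylChain(16, 0), AcylChain(18, 1)),
                 (AcylChain(16, 0), AcylChain(18, 2))]
        mz = [acyl_anion_mz(AcylChain(16, 0)), acyl_anion_mz(AcylChain(18, 1)),
              acyl_anion_mz(AcylChain(18, 2))]
        spec = EPISpectrum(671.46, 9.4, np.array(mz),
                           np.array([100.0, 60.0, 40.0]))
        matches = match_fragments(spec, pairs)
        assignments = resolve_pairs(matches, pairs)
        assert len(assignments) == 2
        assert all(a.confidence is Confidence.PAIR_AMBIGUOUS
                   for a in assignments)


class TestAssignSnPositions:
    def _assignment(self, chain_a, chain_b, intensity_a, intensity_b):
        from pamrm.chem import acyl_anion_mz

        pair = (chain_a, chain_b)
        spec = EPISpectrum(
            671.46, 9.4,
            np.array([acyl_anion_mz(chain_a), acyl_anion_mz(chain_b)]),
            np.array([intensity_a, intensity_b]),
        )
        matches = match_fragments(spec, [pair])
        (assignment,) = resolve_pairs(matches, [pair])
        return assign_sn_positions(assignment, matches)

    def test_higher_intensity_goes_to_sn1(self):
        result = self._assignment(AcylChain(16, 1), AcylChain(18, 1), 100, 60)
        assert result.species.name == "PA(16:1/18:1)"
        assert result.confidence is Confidence.RESOLVED

    def test_order_flips_with_intensity(self):
        result = self._assignment(AcylChain(16, 0), AcylChain(18, 2), 30, 60)
        assert result.species.name == "PA(18:2/16:0)"

    def test_near_equal_intensities_ambiguous(self):
        result = self._assignment(AcylChain(16, 0), AcylChain(18, 2), 100, 90)
        assert result.confidence is Confidence.SN_AMBIGUOUS

    def test_identical_chains_trivially_resolved(self):
        from pamrm.chem import acyl_anion_mz

        pair = (AcylChain(18, 1), AcylChain(18, 1))
        spec = EPISpectrum(699.49, 9.4,
                           np.array([acyl_anion_mz(AcylChain(18, 1))]),
                           np.array([100.0]))
        matches = match_fragments(spec, [pair])
        (assignment,) = resolve_pairs(matches, [pair])
        result = assign_sn_positions(assignment, matches)
        assert result.confidence is Confidence.RESOLVED


class TestCoelution:
    def _assignments(self, spectrum):
        matches = match_fragments(spectrum, CANDIDATES_34_2)
        assignments = resolve_pairs(matches, CANDIDATES_34_2)
        return [assign_sn_positions(a, matches) for a in assignments]

    def test_coeluting_pairs_confirmed(self, worked_epi_spectrum):
        xics = [
            gaussian_chromatogram(q3=253.21, apex=9.45),
            gaussian_chromatogram(q3=281.24, apex=9.45),
            gaussian_chromatogram(q3=255.23, apex=9.36),
            gaussian_chromatogram(q3=279.23, apex=9.36),
        ]
        confirmed = confirm_by_coelution(self._assignments(worked_epi_spectrum),
                                         xics, rt_tol_min=0.1)
        assert all(a.rt_confirmed for a in confirmed)
        apex_sets = {a.species.name: a.rt_apexes for a in confirmed}
        assert apex_sets["PA(16:1/18:1)"] == pytest.approx((9.45, 9.45), abs=0.01)
        assert apex_sets["PA(16:0/18:2)"] == pytest.approx((9.36, 9.36), abs=0.01)

    def test_contradictory_apexes_withdraw_confirmation(self, worked_epi_spectrum):
        xics = [
            gaussian_chromatogram(q3=253.21, apex=9.45),
            gaussian_chromatogram(q3=281.24, apex=8.80),
            gaussian_chromatogram(q3=255.23, apex=9.36),
            gaussian_chromatogram(q3=279.23, apex=9.36),
        ]
        confirmed = confirm_by_coelution(self._assignments(worked_epi_spectrum),
                                         xics, rt_tol_min=0.1)
        by_name = {a.species.name: a for a in confirmed}
        assert by_name["PA(16:1/18:1)"].rt_confirmed is False
        assert by_name["PA(16:1/18:1)"].confidence is Confidence.PAIR_AMBIGUOUS
        assert by_name["PA(16:0/18:2)"].rt_confirmed is True

    def test_missing_xics_leave_confidence_unchanged(self, worked_epi_spectrum):
        assignments = self._assignments(worked_epi_spectrum)
        confirmed = confirm_by_coelution(assignments, [], rt_tol_min=0.1)
        for before, after in zip(assignments, confirmed):
            assert after.rt_confirmed is None
            assert after.confidence is before.confidence


class TestIdentifySpecies:
    def test_worked_example_end_to_end(self, worked_epi_spectrum):
        assignments = identify_species(worked_epi_spectrum, (34, 2))
        names = {a.species.name for a in assignments}
        assert names == {"PA(16:1/18:1)", "PA(16:0/18:2)"}
        assert all(a.confidence is Confidence.RESOLVED for a in assignments)
        assert all(a.collision_energy_eV == 39.0 for a in assignments)

    def test_threshold_stability(self, worked_epi_spectrum):
        baseline = identify_species(worked_epi_spectrum, (34, 2))
        # add a fragment below 1% of the base peak at the 14:2 anion mass
        from pamrm.chem import acyl_anion_mz

        mz = np.append(worked_epi_spectrum.mz, acyl_anion_mz(AcylChain(14, 2)))
        intensity = np.append(worked_epi_spectrum.intensities, 0.5)
        perturbed_spec = EPISpectrum(worked_epi_spectrum.precursor_mz,
                                     worked_epi_spectrum.retention_time_min,
                                     mz, intensity)
        perturbed = identify_species(perturbed_spec, (34, 2))
        assert [a.species.name for a in perturbed] == \
            [a.species.name for a in baseline]

    def test_order_independence(self, worked_epi_spectrum):
        rng = np.random.default_rng(5)
        order = rng.permutation(len(worked_epi_spectrum.mz))
        shuffled = EPISpectrum(worked_epi_spectrum.precursor_mz,
                               worked_epi_spectrum.retention_time_min,
                               worked_epi_spectrum.mz[order],
                               worked_epi_spectrum.intensities[order])
        assert [a.species.name for a in identify_species(shuffled, (34, 2))] \
            == [a.species.name for a in
                identify_species(worked_epi_spectrum, (34, 2))]
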