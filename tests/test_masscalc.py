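"""Mass arithmetic: oracles against pyteomics and hand-derived values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pt_mass

from glycomark.constants import PROTON, WATER, ModKind
from glycomark.masscalc import (
    IonSpecies,
    ModifiedPeptide,
    amadori_loss_ladder,
    enumerate_charge_states,
    monoisotopic_mass,
    mz_for_charge,
    parse_mod_spec,
    parse_modified_sequence,
    ppm_error,
    tryptic_digest,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestModifiedPeptide:
    def test_rejects_unknown_residue(self):
        with pytest.raises(ValueError, match="X"):
            ModifiedPeptide("PEPTXDE")

    @pytest.mark.parametrize(
        "seq,mods",
        [
            ("AKA", ((2, ModKind.CARBAMIDOMETHYL),)),  # CAM needs C
            ("ACA", ((2, ModKind.AMADORI),)),  # Amadori needs K
            ("AMA", ((2, ModKind.CARBAMIDOMETHYL),)),
            ("AKA", ((5, ModKind.AMADORI),)),  # out of range
            ("AKKA", ((2, ModKind.AMADORI), (2, ModKind.AMADORI),)),  # duplicate
        ],
    )
    def test_rejects_invalid_modifications(self, seq, mods):
        with pytest.raises(ValueError):
            ModifiedPeptide(seq, mods)

    def test_star_notation_round_trip(self):
        pep = parse_modified_sequence("VTK*C*C*TESLVNR")
        assert pep.sequence == "VTKCCTESLVNR"
        assert pep.modifications == (
            (3, ModKind.AMADORI),
            (4, ModKind.CARBAMIDOMETHYL),
            (5, ModKind.CARBAMIDOMETHYL),
        )
        assert str(pep) == "VTK*C*C*TESLVNR"

    def test_mod_spec_parsing(self):
        pep = parse_mod_spec("FKDLGEENFK", "K2:AMADORI")
        assert pep.amadori_positions == (2,)
        with pytest.raises(ValueError, match="sequence has"):
            parse_mod_spec("FKDLGEENFK", "K3:AMADORI")


class TestMonoisotopicMass:
    def test_single_glycine(self):
        assert monoisotopic_mass("G") == pytest.approx(75.03203, abs=1e-5)

    def test_glycated_decapeptide_hand_sum(self):
        # residue masses + water + one hexose, summed independently
        pep = parse_mod_spec("FKDLGEENFK", "K2:AMADORI")
        assert monoisotopic_mass(pep) == pytest.approx(1387.6507, abs=2e-4)

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet=AA, min_size=1, max_size=30))
    def test_matches_pyteomics_oracle(self, seq):
        ours = monoisotopic_mass(ModifiedPeptide(seq))
        theirs = pt_mass.calculate_mass(sequence=seq, monoisotopic=True)
        assert ours == pytest.approx(theirs, abs=5e-4)

    def test_amadori_delta_is_one_hexose(self):
        plain = monoisotopic_mass("AKA")
        glyc = monoisotopic_mass(ModifiedPeptide("AKA", ((2, ModKind.AMADORI),)))
        assert glyc - plain == pytest.approx(162.052824, abs=1e-9)


class TestMz:
    def test_triply_and_doubly_protonated(self):
        assert mz_for_charge(1387.6507, 3) == pytest.approx(463.5575, abs=2e-4)
        assert mz_for_charge(1387.6507, 2) == pytest.approx(694.8326, abs=2e-4)

    def test_proton_identity(self):
        assert mz_for_charge(PROTON, 1) == pytest.approx(2 * PROTON)

    def test_monotone_in_charge(self):
        mzs = [mz_for_charge(1500.0, z) for z in range(1, 6)]
        assert all(a > b for a, b in zip(mzs, mzs[1:]))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            mz_for_charge(-1.0, 2)
        with pytest.raises(ValueError):
            mz_for_charge(100.0, 0)

    def test_neutral_mass_consistency_across_charges(self):
        pep = parse_modified_sequence("LK*EC*C*EKPLLEK")
        ions = enumerate_charge_states(pep, 2, 4)
        neutral = {round(i.mz * i.charge - i.charge * PROTON, 6) for i in ions}
        assert len(neutral) == 1


class TestPpmError:
    def test_zero_and_sign(self):
        assert ppm_error(463.5581, 463.5581) == 0.0
        assert ppm_error(463.5581, 463.5575) == pytest.approx(1.294, abs=0.01)

    @settings(max_examples=30, deadline=None)
    @given(
        st.floats(min_value=100, max_value=2000),
        st.floats(min_value=100, max_value=2000),
    )
    def test_antisymmetric_up_to_scale(self, a, b):
        # swapping observed and theoretical flips the sign (scale differs by a/b)
        assert np.sign(ppm_error(a, b)) == -np.sign(ppm_error(b, a))


class TestChargeEnumeration:
    def test_annotated_three_state_peptide(self):
        pep = parse_modified_sequence("LK*EC*C*EKPLLEK")
        ions = {i.charge: i.mz for i in enumerate_charge_states(pep, 2, 4)}
        for z, printed in {2: 854.9281, 3: 570.2889, 4: 427.9688}.items():
            assert abs(ppm_error(printed, ions[z])) <= 10

    def test_zmax_from_basic_sites(self):
        # one R, no K/H: N-terminus + R = 2 basic sites, z_max = min(5, 3)
        ions = enumerate_charge_states(ModifiedPeptide("GAVR"), z_min=2)
        assert max(i.charge for i in ions) == 3
        # glycated K does not count as a basic site
        glyc = parse_modified_sequence("K*AVAG")
        assert max(i.charge for i in enumerate_charge_states(glyc, 1)) == 2

    def test_single_state(self):
        ions = enumerate_charge_states(ModifiedPeptide("GAVR"), 2, 2)
        assert len(ions) == 1 and ions[0].charge == 2


class TestTrypticDigest:
    def test_basic_cleavage(self):
        peps = {p.sequence for p in tryptic_digest("AKGR", max_missed=0)}
        assert peps == {"AK", "GR"}

    def test_glycation_suppresses_cleavage(self):
        peps = {
            p.sequence
            for p in tryptic_digest("AKGR", max_missed=0, glycation_sites={2})
        }
        assert peps == {"AKGR"}

    def test_proline_rule(self):
        peps = {p.sequence for p in tryptic_digest("AKPGR", max_missed=0)}
        assert peps == {"AKPGR"}

    def test_missed_cleavage_counting(self):
        peps = tryptic_digest("AKGKGR", max_missed=1)
        by_missed = {}
        for p in peps:
            by_missed.setdefault(p.missed_cleavages, set()).add(p.sequence)
        assert by_missed[0] == {"AK", "GK", "GR"}
        assert by_missed[1] == {"AKGK", "GKGR"}

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet=AA, min_size=1, max_size=60))
    def test_zero_missed_peptides_reconstruct_protein(self, protein):
        zero = [p for p in tryptic_digest(protein, max_missed=0)]
        zero.sort(key=lambda p: p.start)
        assert "".join(p.sequence for p in zero) == protein


class TestAmadoriLossLadder:
    def _ion(self, z):
        pep = parse_mod_spec("FKDLGEENFK", "K2:AMADORI")
        return IonSpecies(pep, z, mz_for_charge(monoisotopic_mass(pep), z))

    def test_singly_charged_ladder(self):
        ion = self._ion(1)
        losses = [ion.mz - mz for _, mz in amadori_loss_ladder(ion)]
        assert losses == pytest.approx([18.0106, 36.0211, 54.0317, 84.0423], abs=1e-3)

    def test_charge_scaled_water_loss(self):
        ion = self._ion(2)
        label, mz = amadori_loss_ladder(ion)[0]
        assert label == "-H2O"
        assert ion.mz - mz == pytest.approx(WATER / 2, abs=1e-6)

    def test_strictly_decreasing(self):
        mzs = [mz for _, mz in amadori_loss_ladder(self._ion(3))]
        assert all(a > b for a, b in zip(mzs, mzs[1:]))
        assert all(mz < self._ion(3).mz for mz in mzs)

    def test_requires_amadori(self):
        pep = ModifiedPeptide("GAVR")
        ion = IonSpecies(pep, 2, mz_for_charge(monoisotopic_mass(pep), 2))
        with pytest.raises(ValueError, match="Amadori"):
            amadori_loss_ladder(ion)
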