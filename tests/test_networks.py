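"""Network builders: conditioning chemistry, KSCN dosimetry, crosslink scheme."""

import numpy as np
import pytest

import radiokin as rk
from radiokin.core import CROSSLINK_SPECIES
from radiokin.networks import AERATED, N2O_SATURATED


class TestWaterNetwork:
    def test_n2o_condition_converts_electrons(self):
        net = rk.build_water_network(N2O_SATURATED)
        eaq_sinks = [r for r in net.reactions
                     if "e_aq" in {s for s, _ in r.reactants}]
        assert len(eaq_sinks) == 1
        assert {s for s, _ in eaq_sinks[0].products} == {"OH", "N2", "OH-"}
        assert "O2" not in net.species
        assert net.species["N2O"].initial_conc == pytest.approx(2.5e-2)

    def test_aerated_condition_scavenges_eaq_and_h(self):
        net = rk.build_water_network(AERATED)
        assert net.species["O2"].initial_conc == pytest.approx(2.5e-4)
        labels = {tuple(sorted(s for s, _ in r.reactants)) for r in net.reactions}
        assert ("H", "O2") in labels and ("O2", "e_aq") in labels

    def test_aerated_with_zero_o2_is_inert(self):
        net = rk.build_water_network(AERATED.with_(dissolved_o2=0.0))
        state = rk.deposit_dose(
            {n: s.initial_conc for n, s in net.species.items()}, 1.0, net.g_yield
        )
        from radiokin.core import assemble_rhs

        rhs, _ = assemble_rhs(net)
        y = np.array([state[n] for n in net.names])
        # no O2: scavenging reactions carry zero flux
        np.testing.assert_allclose(rhs(0.0, y), 0.0, atol=1e-30)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            rk.ConditionSpec("argon_purged")


class TestKscnChemistry:
    def test_printed_rate_constants_and_extinction(self):
        net = rk.add_kscn_chemistry(rk.build_water_network(N2O_SATURATED), 1e-3)
        ks = {r.k for r in net.reactions}
        assert 2.8e10 in ks and 7.0e9 in ks
        assert net.species["SCN-"].initial_conc == pytest.approx(1e-3)
        assert net.species["(SCN)2-"].extinction[472.0] == pytest.approx(7100.0)

    def test_full_conversion_plateau_is_stoichiometric(self, pulse_tc):
        # under N2O with no competing solute, every OH + e_aq ends as (SCN)2-.
        expected = (0.287 + 0.27) * 4.5 * 1e-6  # 2.5065e-6 mol/L
        assert pulse_tc["(SCN)2-"].max() == pytest.approx(expected, rel=1e-4)

    def test_zero_kscn_zero_flux(self):
        net = rk.add_kscn_chemistry(rk.build_water_network(N2O_SATURATED), 0.0)
        tc = rk.integrate(net, rk.IrradiationProtocol.single_pulse(4.5), 1e-6)
        assert tc["(SCN)2-"].max() == 0.0


class TestPeptideScavenger:
    @pytest.mark.parametrize("name,k", [("H5", 4.2e9), ("H9", 2.7e9),
                                        ("H", 5.0e9), ("G", 1.7e7)])
    def test_table_rate_constants(self, name, k):
        net = rk.build_water_network(N2O_SATURATED)
        rk.add_peptide_scavenger(net, rk.PEPTIDE_TABLE[name], 1e-3)
        pep_rx = [r for r in net.reactions
                  if r.label == f"{name} + OH scavenging"]
        assert len(pep_rx) == 1 and pep_rx[0].k == pytest.approx(k)

    def test_single_residue_name_does_not_collide_with_h_atom(self):
        # histidine ("H") must not merge with the hydrogen-atom primary
        net = rk.build_water_network(N2O_SATURATED)
        rk.add_peptide_scavenger(net, rk.PEPTIDE_TABLE["H"], 1e-3)
        assert net.species["H"].initial_conc == 0.0  # the atom, untouched
        assert net.species["H_peptide"].initial_conc == pytest.approx(1e-3)

    def test_his_gly_composition(self):
        h9 = rk.PEPTIDE_TABLE["H9"]
        assert h9.sequence == "HGGGHGGGH"
        assert h9.n_his == 3 and h9.n_gly == 6
        assert h9.n_his + h9.n_gly == len(h9.sequence)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            rk.PeptideSpec("bad", "HG", 0.0)


class TestCrosslinkNetwork:
    def test_default_h5_network_constants(self, h5):
        net = rk.build_crosslink_network(h5)
        k_by_label = {r.label: r.k for r in net.reactions}
        assert k_by_label["H5 + OH -> adduct radical"] == pytest.approx(4.2e9)
        assert k_by_label["R1 + R1 recombination"] == pytest.approx(1e4)
        assert k_by_label["R1 + O2 quenching"] == pytest.approx(2e9)
        assert k_by_label["OH-substituted + OH ring opening"] == pytest.approx(1e9)

    def test_nmax2_closure_matches_hand_enumeration(self, h5):
        net = rk.build_crosslink_network(
            h5, AERATED, rk.CrosslinkRateSet(n_max=2), peptide_conc=1e-3
        )
        # hand enumeration at n_max=2:
        #   water: H+O2, e_aq+O2                                  -> 2
        #   adduct formation: P1+OH, P2+OH                        -> 2
        #   recombination: R1+R1, R1+R2, R2+R2                    -> 3
        #   degradation: P2+OH                                    -> 1
        #   O2 quenching: R1+O2                                   -> 1
        #   ring opening: P-OH + OH                               -> 1
        assert len(net.reactions) == 10
        assert {"P1", "P2", "R1", "R2"} <= set(net.species)

    def test_nmax_below_two_rejected(self):
        with pytest.raises(ValueError):
            rk.CrosslinkRateSet(n_max=1)

    def test_n2o_condition_has_no_o2_channel(self, h5):
        net = rk.build_crosslink_network(h5, N2O_SATURATED, peptide_conc=1e-3)
        assert not any("O2 quenching" in r.label for r in net.reactions)

    def test_unit_conservation_under_gamma(self, gamma_h5):
        tc, _ = gamma_h5
        total = tc.tag_total("peptide_units")
        np.testing.assert_allclose(total, total[0], rtol=1e-6)

    def test_crosslink_counter_non_decreasing(self, gamma_h5):
        tc, _ = gamma_h5
        assert tc.has_crosslink
        assert np.all(np.diff(tc.crosslink_conc) >= -1e-15)


class TestPeptideMass:
    def test_h5_molar_mass_from_sequence(self, h5):
        # HGHGH: 3 His + 2 Gly residues + one water, average masses
        assert rk.peptide_molar_mass(h5) == pytest.approx(543.5, abs=1.0)

    def test_0p1_wt_percent_molarity(self, h5):
        # 1 g/L over the sequence mass
        conc = rk.peptide_molar_conc(h5, 0.1)
        assert conc == pytest.approx(1.0 / 543.5, rel=5e-3)
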