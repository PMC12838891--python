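"""Descriptor battery, drug-likeness filters, solubility, bioavailability,
structural alerts and the liability classifier."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comolead.adme import (
    ALERT_CATALOG,
    DescriptorSet,
    bioavailability_score,
    compute_descriptors,
    esol_logs,
    identify_liabilities,
    profile_molecule,
    rule_filters,
    solubility_class,
    structural_alerts,
)
from comolead.chem import mol_from_smiles

# literature standard atomic weights, independent of the descriptor engine
_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
         "S": 32.06, "Cl": 35.45}

# (SMILES, molecular formula, heavy atoms) hand-derived from the structures
_HAND_CHECK = [
    ("CCO", {"C": 2, "H": 6, "O": 1}, 3),
    ("CCCC", {"C": 4, "H": 10}, 4),
    ("c1ccccc1", {"C": 6, "H": 6}, 6),
    ("CC(=O)O", {"C": 2, "H": 4, "O": 2}, 4),
    ("O", {"H": 2, "O": 1}, 1),
    ("C(F)(F)F", {"C": 1, "H": 1, "F": 3}, 4),
    ("CS", {"C": 1, "H": 4, "S": 1}, 2),
    ("ClCCl", {"C": 1, "H": 2, "Cl": 2}, 3),
    ("c1ccncc1", {"C": 5, "H": 5, "N": 1}, 6),
    ("CC(=O)Nc1ccccc1", {"C": 8, "H": 9, "N": 1, "O": 1}, 10),
]


def _rule(results, name):
    return next(r for r in results if r.rule_name == name)


class TestDescriptors:
    def test_ethanol_counts(self):
        d = compute_descriptors(mol_from_smiles("CCO"))
        assert (d.hbd, d.hba, d.rotatable_bonds, d.heavy_atoms) == (1, 1, 0, 3)

    def test_benzene_polar_surface_and_aromaticity(self):
        d = compute_descriptors(mol_from_smiles("c1ccccc1"))
        assert d.tpsa == 0.0
        assert d.aromatic_proportion == 1.0

    def test_butane_rotatable_bond_and_mass(self):
        d = compute_descriptors(mol_from_smiles("CCCC"))
        assert d.rotatable_bonds == 1
        assert d.mw == pytest.approx(58.12, abs=0.01)

    @pytest.mark.parametrize("smiles,formula,heavy", _HAND_CHECK)
    def test_masses_match_hand_computed_formula_sums(self, smiles, formula, heavy):
        d = compute_descriptors(mol_from_smiles(smiles))
        expected = sum(_MASS[el] * n for el, n in formula.items())
        assert d.mw == pytest.approx(expected, abs=0.02)
        assert d.heavy_atoms == heavy

    def test_amide_bond_not_rotatable(self):
        # acetanilide: the C-N amide bond is excluded; N-phenyl remains
        d = compute_descriptors(mol_from_smiles("CC(=O)Nc1ccccc1"))
        assert d.rotatable_bonds == 1

    @pytest.mark.parametrize(
        "smiles,expected",
        [("CC(=O)[O-]", "anion"), ("C[N+](C)(C)C", "cation"),
         ("C[N+](C)(C)CC(=O)[O-]", "zwitterion"), ("CCO", "neutral")],
    )
    def test_ionization_classes(self, smiles, expected):
        assert compute_descriptors(mol_from_smiles(smiles)).ionization_class == expected


class TestRuleFilters:
    def test_heavy_lipophilic_compound_two_lipinski_violations(self):
        d = DescriptorSet(mw=629.73, logp_consensus=5.23, hbd=1, hba=9)
        lip = _rule(rule_filters(d), "Lipinski")
        assert lip.n_violations == 2
        assert not lip.passed
        assert {v[0] for v in lip.violations} == {"MW", "LogP"}

    def test_ethanol_passes_lipinski_and_veber(self):
        results = rule_filters(compute_descriptors(mol_from_smiles("CCO")))
        assert _rule(results, "Lipinski").n_violations == 0
        assert _rule(results, "Veber").passed

    def test_three_violation_bound_arithmetic(self):
        d = DescriptorSet(mw=510, hbd=6, hba=11, logp_consensus=4)
        assert _rule(rule_filters(d), "Lipinski").n_violations == 3

    @given(
        mw=st.floats(100, 900), logp=st.floats(-3, 9),
        hbd=st.integers(0, 12), hba=st.integers(0, 15),
        bump=st.sampled_from(["mw", "logp_consensus", "hbd", "hba"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_lipinski_monotone_under_worsening(self, mw, logp, hbd, hba, bump):
        d = DescriptorSet(mw=mw, logp_consensus=logp, hbd=hbd, hba=hba)
        worse = dataclasses.replace(d, **{bump: getattr(d, bump) + (100 if bump == "mw" else 3)})
        before = _rule(rule_filters(d), "Lipinski").n_violations
        after = _rule(rule_filters(worse), "Lipinski").n_violations
        assert after >= before


class TestSolubility:
    def test_intercept_only(self):
        d = DescriptorSet(mw=0, logp_consensus=0, rotatable_bonds=0, aromatic_proportion=0)
        assert esol_logs(d) == pytest.approx(0.16)

    def test_hand_arithmetic(self):
        d = DescriptorSet(mw=200, logp_consensus=2.0, rotatable_bonds=2, aromatic_proportion=0.5)
        assert esol_logs(d) == pytest.approx(-2.578)

    def test_large_lipophilic_compound_poorly_soluble_direction(self):
        d = DescriptorSet(mw=629.73, logp_consensus=5.23, rotatable_bonds=8,
                          aromatic_proportion=0.6)
        assert esol_logs(d) < -6

    @pytest.mark.parametrize(
        "log_s,band",
        [(-1.0, "highly_soluble"), (-2.0, "soluble"), (-3.0, "soluble"),
         (-4.0, "moderately_soluble"), (-5.0, "moderately_soluble"),
         (-6.0, "poorly_soluble"), (-8.0, "insoluble"), (-8.5, "insoluble")],
    )
    def test_banding_with_boundaries(self, log_s, band):
        assert solubility_class(log_s) == band

    @given(st.floats(-15, 5, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_every_value_lands_in_exactly_one_band(self, log_s):
        assert solubility_class(log_s) in {b for b, _ in
                                           (("highly_soluble", 0), ("soluble", 0),
                                            ("moderately_soluble", 0), ("poorly_soluble", 0),
                                            ("insoluble", 0))}


class TestBioavailability:
    def test_neutral_rule_of_five_compliant(self):
        d = compute_descriptors(mol_from_smiles("CCO"))
        assert bioavailability_score(d) == 0.55

    def test_zwitterion_rule_of_five_failure(self):
        d = DescriptorSet(mw=629.73, logp_consensus=5.23, hbd=1, hba=9,
                          ionization_class="zwitterion")
        assert bioavailability_score(d) == 0.17

    @pytest.mark.parametrize("tpsa,score", [(60.0, 0.85), (100.0, 0.56), (200.0, 0.11)])
    def test_anion_polar_surface_bands(self, tpsa, score):
        d = DescriptorSet(mw=300, logp_consensus=2, tpsa=tpsa, ionization_class="anion")
        assert bioavailability_score(d) == score

    def test_deterministic(self):
        d = compute_descriptors(mol_from_smiles("CC(=O)Nc1ccccc1"))
        assert bioavailability_score(d) == bioavailability_score(d)


class TestStructuralAlerts:
    @pytest.mark.parametrize(
        "smiles,expected",
        [("C[N+](C)(C)C", ("quaternary_nitrogen",)),
         ("CCO", ()),
         ("c1ccc(/C=C/c2ccccc2)cc1", ("stilbene",)),
         ("C=CC(C)=O", ("michael_acceptor",))],
    )
    def test_catalog_matches(self, smiles, expected):
        assert structural_alerts(mol_from_smiles(smiles)) == expected

    def test_malformed_pattern_rejected_at_match_time(self):
        with pytest.raises(ValueError, match="broken"):
            structural_alerts(mol_from_smiles("CCO"), {"broken": "[[["})

    def test_catalog_is_extensible(self):
        catalog = dict(ALERT_CATALOG, nitro="[NX3](=O)=O")
        hits = structural_alerts(mol_from_smiles("O=[N+]([O-])c1ccccc1"), catalog)
        assert hits == () or "nitro" in hits  # charged form differs from neutral SMARTS


class TestLiabilities:
    def test_pflid_fixture_fires_the_expected_categories(self, profiles):
        rep = identify_liabilities(profiles["PFLID"])
        assert {"lipophilicity", "solubility", "molecular_weight",
                "bioavailability", "structural_alert",
                "druglikeness_failure"} == rep.categories
        by_cat = {l.category: l for l in rep.liabilities}
        assert by_cat["lipophilicity"].triggering_value == 5.23
        assert by_cat["bioavailability"].triggering_value == 0.17
        assert by_cat["molecular_weight"].bound == "MW <= 600.0"

    def test_iclid_fixture_fires_solubility_and_alerts(self, profiles):
        rep = identify_liabilities(profiles["ICLID"])
        assert "solubility" in rep.categories       # -7.80 < -7
        assert "lipophilicity" in rep.categories    # 4.53 > 4.5
        assert "structural_alert" in rep.categories  # three alerts

    def test_fully_compliant_profile_is_clean(self):
        # a mid-sized drug passing every filter with no alerts
        smiles = "CN1c2ccc(Cl)cc2C(=Nc2ccccc2)CC1=O"
        profile = profile_molecule(mol_from_smiles(smiles, "diazepam"),
                                   gi_absorption="high")
        assert len(identify_liabilities(profile)) == 0

    def test_report_ordered_most_severe_first(self, profiles):
        rep = identify_liabilities(profiles["PFLID"])
        ranks = [l.severity_rank for l in rep.liabilities]
        assert ranks == sorted(ranks, reverse=True)

    def test_computed_profile_end_to_end(self):
        profile = profile_molecule(mol_from_smiles("C=CC(C)=O", "mvk"))
        assert profile.alerts == ("michael_acceptor",)
        assert profile.solubility_class == solubility_class(profile.log_s_esol)
        rep = identify_liabilities(profile)
        assert "structural_alert" in rep.categories
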