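"""ADME profiling and liability triage.

Profiles a structure end to end (descriptors, five drug-likeness filters,
ESOL solubility, bioavailability class, structural alerts), then runs the
liability classifier on the literature profiles of the designed hybrids.
"""

from comolead.adme import identify_liabilities, literature_profiles, profile_molecule
from comolead.chem import mol_from_smiles

# computed profile of a public-structure compound
mel = profile_molecule(mol_from_smiles("CC(=O)NCCc1c[nH]c2ccc(OC)cc12", "melatonin"))
d = mel.descriptors
print(f"melatonin: MW {d.mw:.2f}, WLOGP {d.logp_wlogp:.2f}, TPSA {d.tpsa:.1f}, "
      f"HBD {d.hbd}, HBA {d.hba}")
print(f"  LogS(ESOL) {mel.log_s_esol:.2f} -> {mel.solubility_class}; "
      f"bioavailability {mel.bioavailability_score}; alerts {list(mel.alerts)}")
for r in mel.rules:
    print(f"  {r.rule_name}: {'pass' if r.passed else 'FAIL'} ({r.n_violations} violations)")

# liability triage of the fixture profiles (structures unpublished)
for name, profile in literature_profiles().items():
    report = identify_liabilities(profile)
    cats = [f"{l.category}({l.triggering_value})" for l in report.liabilities]
    print(f"{name}: {len(report)} liabilities -> {cats or 'clean'}")
# The second-generation hybrids carry heavy liability loads (lipophilicity,
# solubility, bioavailability, alerts); the optimized third generation is
# clean except PFL's single residual MW > 500.
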