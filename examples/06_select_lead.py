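"""Lead selection: retention bands, improvement checks, composite scoring.

Bands each third-generation variant's binding change against its parent,
checks the ADME-improvement criteria, and ranks the candidates with the
40/40/10/10 weighted composite score.
"""

from comolead.adme import literature_profiles
from comolead.docking import improvement, packaged_table
from comolead.selection import (
    adme_deltas, candidate_subscores, classify_retention, lead_designation,
    rank_candidates, variant_success,
)

table = packaged_table()
profiles = literature_profiles()

subscores = {}
for variant, parent in (("ICL", "ICLID"), ("PFL", "PFLID")):
    deltas = {t: -improvement(table, variant, parent, t).delta
              for t in ("CK1D", "PINK1")}
    bands = {t: classify_retention(d) for t, d in deltas.items()}
    for t, (band, fold) in bands.items():
        print(f"{variant} vs {parent} on {t}: ddG {deltas[t]:+.1f} kcal/mol "
              f"-> {band} (Ki fold {fold:.2f})")
    ad = adme_deltas(profiles[parent], profiles[variant])
    ok, fired = variant_success(ad, profiles[variant])
    print(f"{variant}: ADME success={ok}, criteria fired: {fired}")
    designated = lead_designation(bands["CK1D"][0], bands["PINK1"][0], ad, metric="any")
    print(f"{variant}: lead designation (retained on both + >=30% ADME gain): {designated}")
    subscores[variant] = candidate_subscores(profiles[variant], deltas)

print("\ncomposite 40/40/10/10 ranking:")
for name, score in rank_candidates(subscores):
    s = subscores[name]
    print(f"  {name}: {score:.3f} (adme {s['adme_sub']:.2f}, binding {s['binding_sub']:.2f}, "
          f"synth {s['synth_sub']:.2f}, balance {s['balance_sub']:.2f})")
# PFL wins: it keeps (indeed improves) binding on both kinases while fixing
# the bioavailability crisis, so its binding sub-score saturates at 1.
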