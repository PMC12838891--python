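"""Comparative arithmetic on the packaged docking-score table.

Loads the 20-row compound-vs-kinase Vina-score table and reports the best
binder per target, the improvement of each designed hybrid over its
reference inhibitor, and the balanced dual-target ranking.
"""

from comolead.docking import best_binder, dual_summary, improvement, packaged_table

table = packaged_table()

for target in ("CK1D", "PINK1"):
    nat = best_binder(table, target, subset="natural")
    overall = best_binder(table, target)
    print(f"{target}: best natural {nat.compound} ({nat.vina_score} kcal/mol); "
          f"best overall {overall.compound} ({overall.vina_score} kcal/mol)")

for compound, reference in (("ICLID", "IC261"), ("PFLID", "PF670462")):
    for target in ("CK1D", "PINK1"):
        rep = improvement(table, compound, reference, target)
        print(f"{compound} vs {reference} on {target}: "
              f"{rep.delta_1dp:+.1f} kcal/mol (~{rep.fold_ki_estimate:.0f}-fold Ki)")

print(dual_summary(table).to_string(index=False))
# 'worse_of_two' is each compound's weaker score; the most negative value
# marks the best balanced dual-kinase binder (PFL at -10.8 kcal/mol).
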