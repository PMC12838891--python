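# Methods

This note documents the models and procedures implemented in `comolead`,
the parameters that matter, the synthetic-data design, and the numerical
choices made where conventions diverge.

## Gene-set refinement

Comorbidity panels are pooled as a deduplicated union; the per-panel report
records each panel's raw size and its *unique contribution* (genes found in
no other panel), flagging panels that contribute nothing unique. The
refined set is `(disease ∩ pool) ∪ retained`, where `retained` is an
explicitly supplied subset of the disease-unique genes. It is an argument,
not a computation: which disease-unique genes survive curation is a
judgment call upstream of this package, so the packaged default geometry
supplies the retained subset (8 genes) directly. Symbols are upper-cased
and whitespace-stripped at ingestion, since mixed-case symbol collisions
are the dominant practical failure when merging curated lists. Every
refined gene carries provenance (`comorbidity_overlap` or `osa_unique`),
and the two classes partition the set by construction.

## Network analytics

**Statistics.** Average degree is 2E/N exactly; the reported value rounds
to two decimals. Mean local clustering averages the per-node clustering
coefficient over *all* nodes, with degree-<2 nodes contributing 0 — the
convention behind the usual "average local clustering coefficient" figure;
excluding those nodes is a defensible alternative but changes the mean.

**MCODE.** Vertex weight = (highest k-core order of the closed
neighborhood) × (density of that core). Complexes grow greedily from the
highest-weighted unused seed, admitting neighbors with weight ≥
(1 − node_score_cutoff) × seed weight; each node joins at most one complex
(fluff stays off, and requesting it raises rather than silently changing
the partition semantics). Complexes lacking a k-core of the configured
order (default 2) are discarded; haircut (default on, matching the
published defaults) iteratively strips members with fewer than two
in-complex connections. Score = density × size; ties in seed selection and
ranking break lexicographically for determinism.

**Co-expression.** Pearson r is computed vectorized against all rows; the
two-tailed p comes from the t transform t = r·√((n−2)/(1−r²)) with n−2
degrees of freedom. A partner set is {genes with |r| > 0.5 and p < 0.01}
by default; shared partners are the intersection of two queries' sets minus
the queries themselves. Exact |r| = 1 (duplicated rows) maps to p = 0
rather than NaN.

**Overrepresentation.** p = hypergeometric upper tail P(X ≥ k) with the
convention that k = 0 gives p = 1; FDR is Benjamini–Hochberg across the
terms tested (statsmodels implementation; unit tests cross-check the tail
against exhaustive enumeration of all C(N, n) draws on backgrounds ≤ 15).

## Scaffold hybridization

Ports are SMARTS patterns with designated attach/detach atoms; the packaged
library covers methoxy replacement, aromatic C–H substitution, carboxyl
replacement and phenol O-alkylation. Overlapping matches resolve greedily
by lowest atom index. Merging forms **single bonds only** — the
conservative chemically permissible default when the bond order of the new
conjugation is unspecified — either directly or through a two-point linker
fragment (methylene, ethylene, ether, amide packaged). The product is
sanitized (aromaticity re-perceived, valences checked), must be a single
component, and round-trips through canonical SMILES. Heavy atoms and
formal charge are conserved up to the detached atoms, which the test suite
checks over randomized merges. Self-merging a molecule with itself is
rejected.

3D embedding uses ETKDG distance geometry with a caller-supplied random
seed (identical seeds give identical coordinates) followed by UFF
minimization; embedding failure is reported in the result object rather
than raised so batch pipelines continue.

The four designed inhibitors of the motivating campaign have no published
structures. The module therefore ships *synthetic stand-in* hybrids built
from the named public parents (IC261, PF-670462, and a simplified
2-aryl-indazole phenol standing in for the nigellidine scaffold), labelled
as reconstructions; they demonstrate the machinery and claim no fidelity
to the originals.

## Docking-table arithmetic

Docking itself is out of scope; the module consumes score tables
(compound, target, Vina kcal/mol, cavity volume Å³). Improvement is
ΔΔG = score(reference) − score(compound), positive meaning the compound
binds more strongly, reported at the 1-decimal convention of the source
tables while internal arithmetic stays unrounded. The implied Ki
fold-change is exp(|ΔΔG|/RT) with RT = 0.5925 kcal/mol (298.15 K); the
informal "five-fold / twenty-five-fold" glosses for 1.0 / 2.0 kcal/mol
correspond to the computed 5.4 / 29.3 and are treated as approximations.
The balanced dual-target ranking sorts compounds by their *worse* score
(max of the two), ascending; single-target compounds are flagged and left
unranked. Non-negative scores parse but are flagged unfavorable.

## ADME rule engine

Descriptors are RDKit-computed: N/O donor–acceptor counting for HBD/HBA
(the counting behind the classic rule of five), strict rotatable bonds
(amide C–N excluded), Wildman–Crippen atom-contribution LogP and molar
refractivity, fragment-contribution TPSA. Consensus LogP is the mean of
available estimators; with one packaged estimator it equals that value, and
the "any individual estimator > 6" liability bound is checked against all
supplied values. The Ghose atom-count bound (20–70) is applied to heavy
atoms.

All five filters live in one declarative bounds table. Lipinski passes
with ≤ 1 violation; the others require full compliance. Solubility uses
the ESOL linear model; the five bands are half-open with each boundary
assigned to the **less-soluble** band, because only the top ("> −2") and
bottom ("< −8") edges are conventionally written strict. The
bioavailability score is the rule-based probability-class tree: anions are
banded on TPSA (≤ 75 → 0.85, ≤ 150 → 0.56, > 150 → 0.11); everything else
scores 0.55 when rule-of-five compliant, 0.17 otherwise. Zwitterions and
cations take the non-anion branch, which is what makes a rule-of-five-
failing zwitterion score 0.17.

The structural-alert catalog packages the three alert classes the campaign
turns on (Michael acceptor, quaternary nitrogen, stilbene linkage) as
SMARTS and is extensible by passing a larger catalog; shipping a full
PAINS set was deliberately avoided. CYP flags and GI absorption are
fixture-supplied model outputs, not predicted; absent a fixture value, GI
absorption falls back to a polar-surface/lipophilicity rule (TPSA ≤ 131.6
and WLOGP ≤ 5.88 → high) and is flagged approximate.

Liability triage fires six categories (bounds configurable): lipophilicity
(consensus > 4.5 or any estimator > 6), solubility (Log S < −7), molecular
weight (> 500, tightening to the 600 bound when exceeded), bioavailability
(score < 0.3 or low GI absorption), structural alerts, and drug-likeness
failure (≥ 2 failed rules). Reports are ordered most severe first under a
configurable severity ranking (drug-likeness failure highest).

Because the designed inhibitors' structures are unpublished, their printed
ADME values ship as a CSV fixture consumed by the liability and selection
layers, with unprinted fields filled by clearly labelled synthetic
stand-ins (see the data-file comments); descriptor computation is
exercised on public-structure compounds instead.

## Selection layer

Retention bands: retained at ΔΔG ≤ 1.0 kcal/mol, moderately reduced in
(1.0, 2.0], substantially reduced above; ki_fold = exp(ΔΔG/RT) is strictly
increasing, equals 1 at 0, and drops below 1 for variants that bind more
strongly. ADME deltas are signed so positive = improvement; the relative
LogP gain is carried alongside because it is the one criterion stated as a
percentage. Variant success fires on any of: relative LogP gain ≥ 30%,
Log S gain ≥ 1 (inclusive), variant Lipinski compliance, or
bioavailability ratio ≥ 2. Lead designation requires retained binding on
both kinases plus a ≥ 30% ADME gain; the gain metric defaults to relative
LogP and can be configured to the bioavailability ratio (as a campaign
whose crisis was permeability would), or to accept either.

The composite score's weights (0.40 ADME, 0.40 binding, 0.10 synthetic
accessibility, 0.10 strategic balance) are fixed by the campaign design,
but no formulas for the sub-scores were specified; the packaged
normalizations are this package's own declared choices: ADME = mean of
{Lipinski pass, capped BA/0.55, solubility-band index rescaled to [0, 1],
alert-free indicator}; binding = mean over targets of
clamp(1 − max(ΔΔG, 0)/2, 0, 1) (full credit at retained-or-better, zero at
the substantial-loss bound); synthetic accessibility = 1 up to 4.5 then
linear to 0 at 10; strategic balance = 1 − |ADME − binding|, an explicit
stand-in for an undefined concept. All four are drop-in replaceable.

## Synthetic data

Generators are pure functions of their spec (same seed ⇒ byte-identical
output), one named generator per operation.

* **Gene universes.** Panels sample without replacement from a shared
  role-coded symbol universe (`CMG####`); the packaged default uses the
  thirteen contributing panel sizes (76 … 95) with a 2460-symbol universe —
  the pool total is read as a post-deduplication count, since the listed
  panel sizes sum higher — a 102-gene disease set, 58 overlap, 8 retained.
  Disease-unique symbols are `OSA###`. The truth map is reproducible by
  direct set arithmetic on the emitted lists.
* **Planted graphs.** Planted-partition model: p_in within blocks, p_out
  between. At p_in = 1, p_out = 0 the blocks are disjoint cliques and
  module recovery must be exact (adjusted Rand 1), which the tests enforce
  over 20 seeds.
* **Expression.** Single-common-factor blocks:
  x = √ρ·f + √(1−ρ)·σ·ε, giving expected within-block correlation
  ρ/(ρ + (1−ρ)σ²) — exactly ρ at the default σ = 1, chosen so the expected
  correlation is analytically known.
* **Molecules.** A small catalog pairs each packaged structural alert with
  a carrier molecule (tetramethylammonium, methyl vinyl ketone,
  trans-stilbene) plus alert-free controls.

What the generators do **not** emulate: real gene identities, the true
association-network topology (so the published clustering coefficient
0.505 is not reproducible — any 66-node/171-edge graph fixes only the
average degree 5.18), docking physics, or SwissADME's trained models.
Passing tests therefore certify the arithmetic and algorithms, not
biological or chemical ground truth.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by design:
planted graphs of 15–30 nodes, expression matrices up to 1000 × 200,
brute-force oracles confined to ≤ 13-node graphs and ≤ 15-gene
backgrounds, 100-merge randomized chemistry sweeps. Property tests use
seeded generators; hypothesis cases are bounded. The acceptance script
threads its `--seed` through every stochastic generator and recomputes all
reported numbers at run time.

## Known limitations

* MCODE is a greedy heuristic; outside the planted-clique regime its
  modules need not be globally densest (the brute-force agreement tests
  target regimes where the optimum is unambiguous).
* One LogP estimator is packaged, so "consensus" degenerates to it for
  computed profiles; fixture profiles carry a second (maximum-method)
  value for the multi-estimator liability bound.
* The solubility boundary convention and the Ghose heavy-atom count are
  documented choices among published variants; swap the declarative tables
  to change them.
* Phenotype annotation and CYP/GI flags are carried, not predicted.
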