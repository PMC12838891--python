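"""ADME rule engine: descriptors, drug-likeness filters, solubility,
bioavailability and liability classification.

All rules are encoded declaratively so bounds can be inspected and swapped:

* the five drug-likeness filters (Lipinski, Ghose, Veber, Egan, Muegge);
* the ESOL linear solubility model with the five-band classification;
* the Abbott bioavailability decision tree (rule-based probability classes);
* a named structural-alert catalog (Brenk-style substructure patterns);
* the liability classifier used to triage optimization candidates
  (lipophilicity, solubility, molecular weight, bioavailability,
  structural alerts, drug-likeness failures).

Descriptors are computed with RDKit; trained-model predictions (CYP
inhibition, BBB, GI absorption) are fixture-supplied flags, with an optional
polar-surface/lipophilicity rule standing in for GI absorption when no
fixture value exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski as RDLipinski, rdMolDescriptors

__all__ = [
    "DescriptorSet",
    "RuleResult",
    "AdmeProfile",
    "Liability",
    "LiabilityReport",
    "ALERT_CATALOG",
    "RULE_BOUNDS",
    "ESOL_COEFFICIENTS",
    "SOLUBILITY_BANDS",
    "LIABILITY_BOUNDS",
    "SEVERITY_ORDER",
    "compute_descriptors",
    "rule_filters",
    "esol_logs",
    "solubility_class",
    "bioavailability_score",
    "structural_alerts",
    "identify_liabilities",
    "profile_molecule",
    "literature_profiles",
]


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptor battery for one molecule."""

    mw: float = float("nan")  # g/mol
    heavy_atoms: int = 0
    fsp3: float = 0.0
    rotatable_bonds: int = 0
    hbd: int = 0
    hba: int = 0
    molar_refractivity: float = float("nan")
    tpsa: float = float("nan")  # square Angstrom
    logp_wlogp: float = float("nan")  # Wildman-Crippen atom contribution
    logp_consensus: float = float("nan")
    aromatic_proportion: float = 0.0
    rings: int = 0
    carbons: int = 0
    heteroatoms: int = 0
    formal_charge: int = 0
    ionization_class: str = "neutral"  # neutral | anion | cation | zwitterion


@dataclass(frozen=True)
class RuleResult:
    rule_name: str
    violations: tuple[tuple[str, float, str], ...]  # (parameter, value, bound)
    n_violations: int
    passed: bool


@dataclass
class AdmeProfile:
    """Full ADME profile of one compound, computed or fixture-supplied."""

    compound: str
    descriptors: DescriptorSet
    rules: list[RuleResult]
    log_s_esol: float
    solubility_class: str
    bioavailability_score: float
    alerts: tuple[str, ...] = ()
    cyp_flags: dict[str, bool] = field(default_factory=dict)
    gi_absorption: str | None = None  # "high" | "low" | None
    gi_absorption_approximate: bool = False
    logp_individual: tuple[float, ...] = ()
    sa_score: float | None = None  # synthetic-accessibility, fixture input

    @property
    def mw(self) -> float:
        return self.descriptors.mw

    @property
    def logp_consensus(self) -> float:
        return self.descriptors.logp_consensus

    def rule(self, name: str) -> RuleResult | None:
        for r in self.rules:
            if r.rule_name == name:
                return r
        return None

    @property
    def lipinski_pass(self) -> bool:
        r = self.rule("Lipinski")
        return bool(r and r.passed)

    @property
    def n_rule_failures(self) -> int:
        return sum(1 for r in self.rules if not r.passed)

    @property
    def total_violations(self) -> int:
        return sum(r.n_violations for r in self.rules)


@dataclass(frozen=True)
class Liability:
    category: str
    triggering_value: object
    bound: str
    severity_rank: int


@dataclass(frozen=True)
class LiabilityReport:
    compound: str
    liabilities: tuple[Liability, ...]

    def __len__(self) -> int:
        return len(self.liabilities)

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(l.category for l in self.liabilities)


# ---------------------------------------------------------------------------
# Declarative rule tables
# ---------------------------------------------------------------------------

# (parameter, descriptor attribute, lower bound, upper bound); None = open.
# Integer lower bounds encode strict ">" constraints (carbons > 4 -> lo 5).
RULE_BOUNDS: dict[str, list[tuple[str, str, float | None, float | None]]] = {
    "Lipinski": [
        ("MW", "mw", None, 500.0),
        ("LogP", "logp_consensus", None, 5.0),
        ("HBD", "hbd", None, 5),
        ("HBA", "hba", None, 10),
    ],
    "Ghose": [
        ("MW", "mw", 160.0, 480.0),
        ("WLOGP", "logp_wlogp", -0.4, 5.6),
        ("MR", "molar_refractivity", 40.0, 130.0),
        ("atoms", "heavy_atoms", 20, 70),
    ],
    "Veber": [
        ("RotB", "rotatable_bonds", None, 10),
        ("TPSA", "tpsa", None, 140.0),
    ],
    "Egan": [
        ("WLOGP", "logp_wlogp", None, 5.88),
        ("TPSA", "tpsa", None, 131.6),
    ],
    "Muegge": [
        ("MW", "mw", 200.0, 600.0),
        ("LogP", "logp_consensus", -2.0, 5.0),
        ("TPSA", "tpsa", None, 150.0),
        ("rings", "rings", None, 7),
        ("carbons", "carbons", 5, None),
        ("heteroatoms", "heteroatoms", 2, None),
        ("RotB", "rotatable_bonds", None, 15),
        ("HBA", "hba", None, 10),
        ("HBD", "hbd", None, 5),
    ],
}

#: Lipinski conventionally passes with at most one violation; the others
#: require full compliance.
_MAX_VIOLATIONS_FOR_PASS = {"Lipinski": 1}

#: LogS = a + b*LogP + c*MW + d*RotB + e*AromaticProportion
ESOL_COEFFICIENTS = {
    "intercept": 0.16,
    "logp": -0.63,
    "mw": -0.0062,
    "rotatable_bonds": 0.066,
    "aromatic_proportion": -0.74,
}

#: (band name, exclusive lower edge); a value belongs to the first band whose
#: edge it strictly exceeds, so each printed boundary falls in the
#: less-soluble band (only "> -2" and "< -8" are printed as strict).
SOLUBILITY_BANDS = (
    ("highly_soluble", -2.0),
    ("soluble", -4.0),
    ("moderately_soluble", -6.0),
    ("poorly_soluble", -8.0),
    ("insoluble", None),
)

#: Brenk-style structural alerts; extensible by passing a custom catalog.
ALERT_CATALOG: dict[str, str] = {
    "michael_acceptor": "[CX3]=[CX3][CX3]=[OX1]",
    "quaternary_nitrogen": "[NX4,NX4+]",
    "stilbene": "c[CX3H1]=[CX3H1]c",
}

#: Liability triage bounds.
LIABILITY_BOUNDS = {
    "logp_consensus_max": 4.5,
    "logp_individual_max": 6.0,
    "log_s_min": -7.0,
    "mw_lipinski": 500.0,
    "mw_muegge": 600.0,
    "ba_min": 0.3,
    "rule_failures_max": 1,  # failing 2+ major rules is a liability
}

#: Ascending severity; later categories rank as more severe.
SEVERITY_ORDER = (
    "bioavailability",
    "solubility",
    "lipophilicity",
    "structural_alert",
    "molecular_weight",
    "druglikeness_failure",
)


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def _ionization_class(mol: Chem.Mol) -> str:
    pos = sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() > 0)
    neg = sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() < 0)
    if pos and neg:
        return "zwitterion"
    net = Chem.GetFormalCharge(mol)
    if net > 0:
        return "cation"
    if net < 0:
        return "anion"
    return "neutral"


def compute_descriptors(mol: Chem.Mol, extra_logp: dict[str, float] | None = None) -> DescriptorSet:
    """Compute the descriptor battery for a valid molecule.

    HBD/HBA follow the N/O donor-acceptor counting of the classic oral
    drug-likeness rules; rotatable bonds exclude amide C-N; the consensus
    lipophilicity is the mean of the Wildman-Crippen estimate and any
    externally supplied estimators in ``extra_logp``.
    """
    heavy = mol.GetNumHeavyAtoms()
    if heavy == 0:
        raise ValueError("molecule has no heavy atoms")
    carbons = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    wlogp = Crippen.MolLogP(mol)
    logps = [wlogp, *(extra_logp or {}).values()]
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        heavy_atoms=heavy,
        fsp3=rdMolDescriptors.CalcFractionCSP3(mol),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
        ),
        hbd=RDLipinski.NHOHCount(mol),
        hba=RDLipinski.NOCount(mol),
        molar_refractivity=Crippen.MolMR(mol),
        tpsa=Descriptors.TPSA(mol),
        logp_wlogp=wlogp,
        logp_consensus=sum(logps) / len(logps),
        aromatic_proportion=aromatic / heavy,
        rings=rdMolDescriptors.CalcNumRings(mol),
        carbons=carbons,
        heteroatoms=heavy - carbons,
        formal_charge=Chem.GetFormalCharge(mol),
        ionization_class=_ionization_class(mol),
    )


# ---------------------------------------------------------------------------
# Drug-likeness filters
# ---------------------------------------------------------------------------

def rule_filters(d: DescriptorSet) -> list[RuleResult]:
    """Evaluate the five drug-likeness filters from the declarative bounds."""
    results = []
    for rule, checks in RULE_BOUNDS.items():
        violations = []
        for param, attr, lo, hi in checks:
            value = getattr(d, attr)
            if lo is not None and value < lo:
                violations.append((param, float(value), f">= {lo}"))
            if hi is not None and value > hi:
                violations.append((param, float(value), f"<= {hi}"))
        n = len(violations)
        results.append(
            RuleResult(
                rule_name=rule,
                violations=tuple(violations),
                n_violations=n,
                passed=n <= _MAX_VIOLATIONS_FOR_PASS.get(rule, 0),
            )
        )
    return results


def esol_logs(d: DescriptorSet, coefficients: dict[str, float] | None = None) -> float:
    """Estimated aqueous solubility (log mol/L) from the ESOL linear model."""
    c = coefficients or ESOL_COEFFICIENTS
    return (
        c["intercept"]
        + c["logp"] * d.logp_consensus
        + c["mw"] * d.mw
        + c["rotatable_bonds"] * d.rotatable_bonds
        + c["aromatic_proportion"] * d.aromatic_proportion
    )


def solubility_class(log_s: float) -> str:
    """Map a Log S value to the five-band solubility classification."""
    for band, lower in SOLUBILITY_BANDS:
        if lower is None or log_s > lower:
            return band
    raise AssertionError("unreachable")


def bioavailability_score(d: DescriptorSet) -> float:
    """Rule-based oral bioavailability probability class.

    Anions are scored on polar surface area bands (0.85 / 0.56 / 0.11);
    everything else scores 0.55 when compliant with the rule of five
    (at most one violation) and 0.17 otherwise.
    """
    if d.ionization_class == "anion":
        if d.tpsa > 150.0:
            return 0.11
        if d.tpsa > 75.0:
            return 0.56
        return 0.85
    lipinski = next(r for r in rule_filters(d) if r.rule_name == "Lipinski")
    return 0.55 if lipinski.passed else 0.17


def structural_alerts(mol: Chem.Mol, catalog: dict[str, str] | None = None) -> tuple[str, ...]:
    """Names of all catalog substructure alerts matched by the molecule."""
    catalog = catalog if catalog is not None else ALERT_CATALOG
    hits = []
    for name, smarts in catalog.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"malformed alert pattern {name!r}: {smarts!r}")
        if mol.HasSubstructMatch(patt):
            hits.append(name)
    return tuple(sorted(hits))


# ---------------------------------------------------------------------------
# Liability triage
# ---------------------------------------------------------------------------

def identify_liabilities(
    p: AdmeProfile,
    bounds: dict[str, float] | None = None,
    severity_order: tuple[str, ...] = SEVERITY_ORDER,
) -> LiabilityReport:
    """Classify a profile's ADME liabilities, most severe first.

    Categories fire on: consensus lipophilicity above 4.5 or any single
    estimator above 6.0; Log S below -7; molecular weight above 500
    (or the stricter 600 bound when exceeded); bioavailability score below
    0.3 or predicted low GI absorption; any structural alert; and failure of
    two or more drug-likeness rules.
    """
    b = dict(LIABILITY_BOUNDS)
    if bounds:
        b.update(bounds)
    rank = {cat: i for i, cat in enumerate(severity_order)}
    out: list[Liability] = []

    logp_all = p.logp_individual or (p.logp_consensus,)
    if p.logp_consensus > b["logp_consensus_max"]:
        out.append(Liability("lipophilicity", p.logp_consensus,
                             f"consensus LogP <= {b['logp_consensus_max']}",
                             rank["lipophilicity"]))
    elif max(logp_all) > b["logp_individual_max"]:
        out.append(Liability("lipophilicity", max(logp_all),
                             f"all LogP estimates <= {b['logp_individual_max']}",
                             rank["lipophilicity"]))

    if p.log_s_esol < b["log_s_min"]:
        out.append(Liability("solubility", p.log_s_esol,
                             f"LogS >= {b['log_s_min']}", rank["solubility"]))

    if p.mw > b["mw_muegge"]:
        out.append(Liability("molecular_weight", p.mw,
                             f"MW <= {b['mw_muegge']}", rank["molecular_weight"]))
    elif p.mw > b["mw_lipinski"]:
        out.append(Liability("molecular_weight", p.mw,
                             f"MW <= {b['mw_lipinski']}", rank["molecular_weight"]))

    if p.bioavailability_score < b["ba_min"]:
        out.append(Liability("bioavailability", p.bioavailability_score,
                             f"bioavailability score >= {b['ba_min']}",
                             rank["bioavailability"]))
    elif p.gi_absorption == "low":
        out.append(Liability("bioavailability", "low GI absorption",
                             "predicted GI absorption high",
                             rank["bioavailability"]))

    if p.alerts:
        out.append(Liability("structural_alert", ";".join(p.alerts),
                             "zero structural alerts", rank["structural_alert"]))

    if p.n_rule_failures > b["rule_failures_max"]:
        out.append(Liability("druglikeness_failure", p.n_rule_failures,
                             f"<= {b['rule_failures_max']} rule failures",
                             rank["druglikeness_failure"]))

    out.sort(key=lambda l: -l.severity_rank)
    return LiabilityReport(compound=p.compound, liabilities=tuple(out))


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------

def profile_molecule(
    mol: Chem.Mol,
    name: str | None = None,
    alert_catalog: dict[str, str] | None = None,
    extra_logp: dict[str, float] | None = None,
    gi_absorption: str | None = None,
    cyp_flags: dict[str, bool] | None = None,
    sa_score: float | None = None,
) -> AdmeProfile:
    """Compute a full ADME profile from a structure.

    ``gi_absorption`` / ``cyp_flags`` come from fixtures when available;
    without a fixture value, GI absorption falls back to a polar-surface /
    lipophilicity rule (TPSA <= 131.6 and WLOGP <= 5.88 -> high) and is
    flagged approximate.
    """
    d = compute_descriptors(mol, extra_logp=extra_logp)
    log_s = esol_logs(d)
    approx_gi = gi_absorption is None
    if approx_gi:
        gi_absorption = "high" if (d.tpsa <= 131.6 and d.logp_wlogp <= 5.88) else "low"
    return AdmeProfile(
        compound=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
        descriptors=d,
        rules=rule_filters(d),
        log_s_esol=log_s,
        solubility_class=solubility_class(log_s),
        bioavailability_score=bioavailability_score(d),
        alerts=structural_alerts(mol, alert_catalog),
        cyp_flags=dict(cyp_flags or {}),
        gi_absorption=gi_absorption,
        gi_absorption_approximate=approx_gi,
        logp_individual=tuple([d.logp_wlogp, *(extra_logp or {}).values()]),
        sa_score=sa_score,
    )


def _rule_from_count(name: str, n: int) -> RuleResult:
    return RuleResult(
        rule_name=name, violations=(), n_violations=int(n),
        passed=int(n) <= _MAX_VIOLATIONS_FOR_PASS.get(name, 0),
    )


def literature_profiles() -> dict[str, AdmeProfile]:
    """Fixture profiles for the four designed inhibitors (ICLID, PFLID, ICL,
    PFL) whose structures are unpublished; values are the printed predictions
    plus clearly synthetic stand-ins for unprinted fields (see the data-file
    comments)."""
    with resources.as_file(resources.files("comolead") / "data" / "literature_adme.csv") as path:
        df = pd.read_csv(path, comment="#")
    profiles: dict[str, AdmeProfile] = {}
    for row in df.itertuples(index=False):
        d = DescriptorSet(
            mw=float(row.mw),
            hbd=int(row.hbd),
            hba=int(row.hba),
            logp_consensus=float(row.logp_consensus),
            logp_wlogp=float(row.logp_consensus),
        )
        alerts = tuple(str(row.alerts).split(";")) if isinstance(row.alerts, str) and row.alerts else ()
        rules = [
            _rule_from_count("Lipinski", row.lipinski_violations),
            _rule_from_count("Ghose", row.ghose_violations),
            _rule_from_count("Muegge", row.muegge_violations),
        ]
        log_s = float(row.log_s)
        profiles[str(row.compound)] = AdmeProfile(
            compound=str(row.compound),
            descriptors=d,
            rules=rules,
            log_s_esol=log_s,
            solubility_class=solubility_class(log_s),
            bioavailability_score=float(row.ba_score),
            alerts=alerts,
            gi_absorption=str(row.gi_absorption),
            logp_individual=(float(row.logp_consensus), float(row.logp_max_method)),
            sa_score=float(row.sa_score),
        )
    return profiles
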