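"""Variant triage and lead selection for ADME-guided optimization.

Implements the decision layer that sits on top of the ADME profiles and the
docking deltas: binding-retention banding of re-docked variants (with the
implied fold-change in Ki), ADME improvement deltas versus the parent
compound, the variant-success and lead-designation predicates, and the
weighted composite score used to pick the final lead.

The component weights of the composite score (40% ADME, 40% binding,
10% synthetic accessibility, 10% strategic balance) are fixed by the
campaign design; the sub-score normalizations are package choices declared
here so alternative constructions are drop-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .adme import AdmeProfile, SOLUBILITY_BANDS
from .docking import RT_KCAL_MOL

__all__ = [
    "RetentionPolicy",
    "AdmeDeltas",
    "VariantStrategy",
    "VARIANT_STRATEGIES",
    "LeadScoreWeights",
    "classify_retention",
    "adme_deltas",
    "variant_success",
    "lead_designation",
    "composite_lead_score",
    "candidate_subscores",
    "rank_candidates",
]


@dataclass(frozen=True)
class RetentionPolicy:
    """Banding thresholds for the binding-energy change of a variant.

    ``delta`` is variant score minus parent score in kcal/mol (positive =
    weaker binding): retained at <= 1.0, moderately reduced in (1.0, 2.0],
    substantially reduced above 2.0.
    """

    retained_max: float = 1.0
    moderate_max: float = 2.0
    rt: float = RT_KCAL_MOL

    def __post_init__(self) -> None:
        if not 0 < self.retained_max < self.moderate_max:
            raise ValueError("need 0 < retained_max < moderate_max")


@dataclass(frozen=True)
class AdmeDeltas:
    """Signed ADME improvements of a variant over its parent.

    Positive values point in the direction the optimization wants: lower
    lipophilicity (``d_logp``), higher solubility (``d_logs``), lower mass
    (``d_mw``), larger bioavailability ratio (``ba_ratio``), fewer rule
    violations (``violation_reduction``).  ``d_logp_rel`` is the relative
    lipophilicity improvement, the one criterion stated as a percentage.
    """

    d_logp: float
    d_logs: float
    d_mw: float
    ba_ratio: float
    violation_reduction: int
    d_logp_rel: float = 0.0


@dataclass(frozen=True)
class VariantStrategy:
    """A named optimization strategy with checkable target outcomes."""

    name: str
    targets: tuple[tuple[str, str], ...]  # (label, predicate id)

    def check(self, profile: AdmeProfile) -> dict[str, bool]:
        return {label: _PREDICATES[pid](profile) for label, pid in self.targets}


_PREDICATES = {
    "lipinski_pass": lambda p: p.lipinski_pass,
    "lipinski_le1": lambda p: (p.rule("Lipinski") is not None
                               and p.rule("Lipinski").n_violations <= 1),
    "ba_gt_050": lambda p: p.bioavailability_score > 0.50,
    "ba_040_055": lambda p: 0.40 <= p.bioavailability_score <= 0.55,
    "zero_alerts": lambda p: len(p.alerts) == 0,
    "le1_alert": lambda p: len(p.alerts) <= 1,
    "logs_gt_m6": lambda p: p.log_s_esol > -6.0,
    "hbd_3_5": lambda p: 3 <= p.descriptors.hbd <= 5,
    "tpsa_110_130": lambda p: 110.0 <= p.descriptors.tpsa <= 130.0,
    "gi_high": lambda p: p.gi_absorption == "high",
}

#: The three parallel optimization strategies and their target outcomes.
VARIANT_STRATEGIES: dict[str, VariantStrategy] = {
    "aggressive": VariantStrategy(
        "aggressive",
        (("Lipinski compliance", "lipinski_pass"),
         ("bioavailability > 0.50", "ba_gt_050"),
         ("zero structural alerts", "zero_alerts")),
    ),
    "moderate": VariantStrategy(
        "moderate",
        (("<= 1 Lipinski violation", "lipinski_le1"),
         ("bioavailability 0.40-0.55", "ba_040_055"),
         ("minimal structural alerts", "le1_alert")),
    ),
    "polarity": VariantStrategy(
        "polarity",
        (("LogS > -6", "logs_gt_m6"),
         ("HBD 3-5", "hbd_3_5"),
         ("TPSA 110-130", "tpsa_110_130"),
         ("high GI absorption", "gi_high")),
    ),
}


@dataclass(frozen=True)
class LeadScoreWeights:
    w_adme: float = 0.40
    w_binding: float = 0.40
    w_synth: float = 0.10
    w_balance: float = 0.10

    def __post_init__(self) -> None:
        total = self.w_adme + self.w_binding + self.w_synth + self.w_balance
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"lead-score weights must sum to 1, got {total}")


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

def classify_retention(
    delta_dg: float,
    policy: RetentionPolicy | None = None,
) -> tuple[str, float]:
    """Band a variant's binding-energy change and the implied Ki fold-change.

    ``ki_fold`` = exp(delta/RT) is continuous and strictly increasing in the
    delta, equals 1 at 0, and is below 1 when the variant binds more strongly
    than its parent.
    """
    policy = policy or RetentionPolicy()
    if delta_dg <= policy.retained_max:
        band = "retained"
    elif delta_dg <= policy.moderate_max:
        band = "moderately_reduced"
    else:
        band = "substantially_reduced"
    return band, math.exp(delta_dg / policy.rt)


# ---------------------------------------------------------------------------
# ADME deltas and success predicates
# ---------------------------------------------------------------------------

def adme_deltas(parent: AdmeProfile, variant: AdmeProfile) -> AdmeDeltas:
    """Quantify a variant's ADME improvements over its parent."""
    if parent.bioavailability_score == 0:
        raise ValueError("parent bioavailability score is zero; ratio undefined")
    d_logp = parent.logp_consensus - variant.logp_consensus
    return AdmeDeltas(
        d_logp=d_logp,
        d_logs=variant.log_s_esol - parent.log_s_esol,
        d_mw=parent.mw - variant.mw,
        ba_ratio=variant.bioavailability_score / parent.bioavailability_score,
        violation_reduction=parent.total_violations - variant.total_violations,
        d_logp_rel=d_logp / parent.logp_consensus if parent.logp_consensus else 0.0,
    )


def variant_success(deltas: AdmeDeltas, variant: AdmeProfile) -> tuple[bool, list[str]]:
    """Prioritization check: any one of the four improvement criteria fires.

    Criteria: relative lipophilicity improvement >= 30%, solubility gain of
    one or more log units (inclusive), Lipinski compliance of the variant,
    or a two-fold or greater bioavailability improvement.
    """
    fired = []
    if deltas.d_logp_rel >= 0.30:
        fired.append("logp_improvement_30pct")
    if deltas.d_logs >= 1.0:
        fired.append("solubility_one_log_unit")
    if variant.lipinski_pass:
        fired.append("lipinski_compliance")
    if deltas.ba_ratio >= 2.0:
        fired.append("bioavailability_two_fold")
    return bool(fired), fired


def lead_designation(
    retention_ck1d: str,
    retention_pink1: str,
    deltas: AdmeDeltas,
    rel_improvement_min: float = 0.30,
    metric: str = "logp_rel",
) -> bool:
    """Second-generation lead check: binding retained on both kinases plus a
    30%-or-greater ADME improvement.

    The improvement ``metric`` is relative lipophilicity by default (the one
    criterion stated as a percentage); ``"ba"`` instead uses the relative
    bioavailability gain (ba_ratio - 1), and ``"any"`` accepts either.
    """
    both_retained = retention_ck1d == "retained" and retention_pink1 == "retained"
    gains = {"logp_rel": deltas.d_logp_rel, "ba": deltas.ba_ratio - 1.0}
    if metric == "any":
        gain = max(gains.values())
    else:
        gain = gains[metric]
    return both_retained and gain >= rel_improvement_min


# ---------------------------------------------------------------------------
# Composite lead score
# ---------------------------------------------------------------------------

def composite_lead_score(
    adme_sub: float,
    binding_sub: float,
    synth_sub: float,
    balance_sub: float,
    weights: LeadScoreWeights | None = None,
) -> float:
    """Weighted sum of the four sub-scores, each in [0, 1]."""
    w = weights or LeadScoreWeights()
    for name, s in (("adme", adme_sub), ("binding", binding_sub),
                    ("synth", synth_sub), ("balance", balance_sub)):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"{name} sub-score {s} outside [0, 1]")
    return (w.w_adme * adme_sub + w.w_binding * binding_sub
            + w.w_synth * synth_sub + w.w_balance * balance_sub)


_BAND_INDEX = {band: i for i, (band, _) in enumerate(reversed(SOLUBILITY_BANDS))}


def candidate_subscores(
    profile: AdmeProfile,
    binding_deltas: dict[str, float],
) -> dict[str, float]:
    """Packaged sub-score normalizations for one candidate.

    adme_sub: mean of Lipinski pass, capped bioavailability ratio (vs the
    0.55 compliant class), solubility-band index rescaled to [0, 1], and an
    alert-free indicator.  binding_sub: mean over targets of
    1 - max(delta, 0)/2 clamped to [0, 1] (full credit at retained-or-better,
    zero at the substantial-loss bound).  synth_sub: 1 up to a synthetic
    accessibility of 4.5, then linear decay to 0 at 10.  balance_sub:
    1 - |adme_sub - binding_sub|.
    """
    band_idx = _BAND_INDEX[profile.solubility_class] / (len(SOLUBILITY_BANDS) - 1)
    adme_sub = (
        (1.0 if profile.lipinski_pass else 0.0)
        + min(profile.bioavailability_score / 0.55, 1.0)
        + band_idx
        + (1.0 if not profile.alerts else 0.0)
    ) / 4.0
    binding_terms = [
        min(max(1.0 - max(d, 0.0) / 2.0, 0.0), 1.0) for d in binding_deltas.values()
    ]
    binding_sub = sum(binding_terms) / len(binding_terms)
    sa = profile.sa_score if profile.sa_score is not None else 4.5
    synth_sub = 1.0 if sa <= 4.5 else max(0.0, 1.0 - (sa - 4.5) / 5.5)
    return {
        "adme_sub": adme_sub,
        "binding_sub": binding_sub,
        "synth_sub": synth_sub,
        "balance_sub": 1.0 - abs(adme_sub - binding_sub),
    }


def rank_candidates(
    candidates: dict[str, dict[str, float]],
    weights: LeadScoreWeights | None = None,
) -> list[tuple[str, float]]:
    """Score candidates (name -> sub-score dict) and rank them descending;
    ties break lexicographically so the ranking is order-invariant."""
    scored = [
        (name, composite_lead_score(s["adme_sub"], s["binding_sub"],
                                    s["synth_sub"], s["balance_sub"], weights))
        for name, s in candidates.items()
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
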