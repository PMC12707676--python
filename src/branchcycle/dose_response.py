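"""Hill dose-response scaling of state durations, death and fate probabilities.

Two saturating effect functions per drug share one Hill coefficient:

    E(D)   = (D/EC50_e)^n / (1 + (D/EC50_e)^n)    progression effect
    E_d(D) = (D/EC50_d)^n / (1 + (D/EC50_d)^n)    lethality effect

``E`` scales every Weibull downtime scale (lambda = lambda_max * E) and the
drug-hit fate-branch probabilities (q = q_max * E); ``E_d`` scales every
death probability (m_d = m_d_max * E_d).  At dose 0 every downtime is
instantaneous, no deaths occur and no drug branch is taken, so the treated
state machines collapse exactly onto the untreated one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import G2MTreatmentParams, STreatmentParams

__all__ = ["hill_effect", "scale_g2m", "scale_s",
           "EffectiveG2MParams", "EffectiveSParams"]


def hill_effect(dose: float, ec50: float, hill: float) -> float:
    """Saturating Hill effect in [0, 1); 0.5 at ``dose == ec50``."""
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    if ec50 <= 0 or hill <= 0:
        raise ValueError("ec50 and hill must be positive")
    if dose == 0:
        return 0.0
    x = (dose / ec50) ** hill
    return x / (1.0 + x)


@dataclass(frozen=True)
class EffectiveG2MParams:
    """Dose-scaled G2/M-drug parameters fed into the graph builder."""

    dose: float
    effect: float
    effect_d: float
    q1: float
    q2: float
    q3: float
    q4: float
    md_fr: float
    md_ur: float
    md_ms: float
    md_g1arrest: float
    md_sarrest: float
    lam_dg1: float
    lam_ur: float
    lam_fr: float
    lam_ms: float
    lam_g1arrest: float
    lam_ds: float
    lam_sarrest: float
    b_g2m: float
    b_dg2m: float
    a_s_scale: float
    b_s: float


@dataclass(frozen=True)
class EffectiveSParams:
    """Dose-scaled S-drug parameters fed into the graph builder."""

    dose: float
    effect: float
    effect_d: float
    q1: float
    q2: float
    q3: float
    md_fr: float
    md_ur: float
    md_g2marrest: float
    md_g1block: float
    lam_dg2m: float
    lam_ur: float
    lam_fr: float
    lam_g2marrest: float
    lam_g1block: float
    b_s: float
    b_ds: float
    a_g2m_scale: float
    b_g2m: float


def scale_g2m(trt: G2MTreatmentParams, dose: float) -> EffectiveG2MParams:
    """Apply the Hill effects of a G2/M-phase drug at ``dose`` nM."""
    e = hill_effect(dose, trt.ec50_e, trt.n_hill)
    ed = hill_effect(dose, trt.ec50_d, trt.n_hill)
    return EffectiveG2MParams(
        dose=dose, effect=e, effect_d=ed,
        q1=trt.q1 * e, q2=trt.q2 * e, q3=trt.q3 * e, q4=trt.q4,
        md_fr=trt.md_fr_max * ed, md_ur=trt.md_ur_max * ed,
        md_ms=trt.md_ms_max * ed, md_g1arrest=trt.md_g1arrest_max * ed,
        md_sarrest=trt.md_sarrest_max * ed,
        lam_dg1=trt.lam_dg1_max * e, lam_ur=trt.lam_ur_max * e,
        lam_fr=trt.lam_fr_max * e, lam_ms=trt.lam_ms_max * e,
        lam_g1arrest=trt.lam_g1arrest_max * e, lam_ds=trt.lam_ds_max * e,
        lam_sarrest=trt.lam_sarrest_max * e,
        b_g2m=trt.b_g2m, b_dg2m=trt.b_dg2m,
        a_s_scale=trt.a_s * e, b_s=trt.b_s,
    )


def scale_s(trt: STreatmentParams, dose: float) -> EffectiveSParams:
    """Apply the Hill effects of an S-phase drug at ``dose`` nM."""
    e = hill_effect(dose, trt.ec50_e, trt.n_hill)
    ed = hill_effect(dose, trt.ec50_d, trt.n_hill)
    return EffectiveSParams(
        dose=dose, effect=e, effect_d=ed,
        q1=trt.q1 * e, q2=trt.q2 * e, q3=trt.q3 * e,
        md_fr=trt.md_fr_max * ed, md_ur=trt.md_ur_max * ed,
        md_g2marrest=trt.md_g2marrest_max * ed,
        md_g1block=trt.md_g1block_max * ed,
        lam_dg2m=trt.lam_dg2m_max * e, lam_ur=trt.lam_ur_max * e,
        lam_fr=trt.lam_fr_max * e, lam_g2marrest=trt.lam_g2marrest_max * e,
        lam_g1block=trt.lam_g1block_max * e,
        b_s=trt.b_s, b_ds=trt.b_ds,
        a_g2m_scale=trt.a_g2m * e, b_g2m=trt.b_g2m,
    )
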