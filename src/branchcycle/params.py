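"""Parameter containers and built-in reference parameter sets.

Three reference models ship with the package, corresponding to published
posterior-mean calibrations of the framework against literature
flow-cytometry data:

* ``MODEL1`` - docetaxel on AGS gastric cancer cells (G2/M-phase drug),
* ``MODEL2`` - paclitaxel on H460 NSCLC cells (G2/M-phase drug),
* ``MODEL3`` - gemcitabine on H460 NSCLC cells (S-phase drug).

All times are hours, rates 1/hour, doses nM, probabilities dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


@dataclass(frozen=True)
class BaselineParams:
    """Untreated cell-cycle parameters.

    G1, S and G2/M completion times are gamma with shapes ``alpha1..3`` and a
    common rate ``beta0``; each mitosis yields two daughters.  ``n_gen``
    truncates the generation expansion (exact for any finite horizon once no
    appreciable mass reaches generation ``n_gen + 1``).
    """

    alpha1: float
    alpha2: float
    alpha3: float
    beta0: float
    n_gen: int = 8

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.alpha3, self.beta0) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")
        if self.n_gen < 1:
            raise ValueError("n_gen must be at least 1")

    @property
    def shapes(self) -> tuple[float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3)

    @property
    def mean_cycle(self) -> float:
        return (self.alpha1 + self.alpha2 + self.alpha3) / self.beta0


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} = {p} is not a probability")


@dataclass(frozen=True)
class G2MTreatmentParams:
    """Maximal-effect parameters of the G2/M-phase drug state machine.

    ``q1..q3`` split drug-hit mitotic exits into unfaithful repair (UR),
    faithful repair (FR) and mitotic slippage (MS); ``q4`` is the probability
    that a damage-inheriting G1 daughter re-enters a normal S phase.  The
    ``md_*_max`` are death probabilities and the ``lam_*_max`` Weibull scale
    maxima (hours) reached at saturating dose; both are scaled down by Hill
    effect functions with the shared coefficient ``n_hill`` and the two EC50s.
    ``(a_s, b_s)`` parameterize the recalibrated first post-treatment S phase.
    """

    q1: float
    q2: float
    q3: float
    q4: float
    md_fr_max: float
    md_ur_max: float
    md_ms_max: float
    md_g1arrest_max: float
    md_sarrest_max: float
    lam_dg1_max: float
    lam_ur_max: float
    lam_fr_max: float
    lam_ms_max: float
    lam_g1arrest_max: float
    lam_ds_max: float
    lam_sarrest_max: float
    b_g2m: float
    b_dg2m: float
    n_hill: float
    ec50_d: float
    ec50_e: float
    a_s: float
    b_s: float

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3", "q4", "md_fr_max", "md_ur_max",
                     "md_ms_max", "md_g1arrest_max", "md_sarrest_max"):
            _check_prob(name, getattr(self, name))
        if self.q1 + self.q2 + self.q3 > 1.0 + 1e-12:
            raise ValueError("q1 + q2 + q3 must not exceed 1")
        if self.q4 + self.md_g1arrest_max > 1.0 + 1e-12:
            raise ValueError(
                "q4 + md_g1arrest_max must not exceed 1 (G1-arrest fates)")
        for name in ("lam_dg1_max", "lam_ur_max", "lam_fr_max", "lam_ms_max",
                     "lam_g1arrest_max", "lam_ds_max", "lam_sarrest_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("b_g2m", "b_dg2m", "n_hill", "ec50_d", "ec50_e",
                     "a_s", "b_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class STreatmentParams:
    """Maximal-effect parameters of the S-phase drug state machine.

    ``q1`` is the G1/S-border block probability; ``q2``/``q3`` split drug-hit
    S exits into unfaithful/faithful repair.  Damage from unfaithful S repair
    is carried into an arrested G2/M state.  ``(a_g2m, b_g2m)`` parameterize
    the recalibrated first post-treatment G2/M phase of undamaged lineages.
    """

    q1: float
    q2: float
    q3: float
    md_fr_max: float
    md_ur_max: float
    md_g2marrest_max: float
    md_g1block_max: float
    lam_dg2m_max: float
    lam_ur_max: float
    lam_fr_max: float
    lam_g2marrest_max: float
    lam_g1block_max: float
    b_s: float
    b_ds: float
    n_hill: float
    ec50_d: float
    ec50_e: float
    a_g2m: float
    b_g2m: float

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3", "md_fr_max", "md_ur_max",
                     "md_g2marrest_max", "md_g1block_max"):
            _check_prob(name, getattr(self, name))
        if self.q2 + self.q3 > 1.0 + 1e-12:
            raise ValueError("q2 + q3 must not exceed 1")
        for name in ("lam_dg2m_max", "lam_ur_max", "lam_fr_max",
                     "lam_g2marrest_max", "lam_g1block_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("b_s", "b_ds", "n_hill", "ec50_d", "ec50_e",
                     "a_g2m", "b_g2m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def params_to_dict(p) -> dict:
    return asdict(p)


# ---------------------------------------------------------------------------
# Reference parameter sets (posterior means of the published calibration)

MODEL1_BASELINE = BaselineParams(alpha1=10.156, alpha2=11.068, alpha3=10.147,
                                 beta0=1.797)
MODEL2_BASELINE = BaselineParams(alpha1=9.215, alpha2=8.946, alpha3=10.017,
                                 beta0=1.824)
MODEL3_BASELINE = MODEL2_BASELINE  # same cell line, same untreated fit

MODEL1_G2M = G2MTreatmentParams(
    q1=0.575, q2=0.056, q3=0.130, q4=0.416,
    md_fr_max=0.599, md_ur_max=0.858, md_ms_max=0.335,
    md_g1arrest_max=0.168, md_sarrest_max=0.788,
    lam_dg1_max=19.292, lam_ur_max=55.708, lam_fr_max=23.375,
    lam_ms_max=15.076, lam_g1arrest_max=56.392, lam_ds_max=45.501,
    lam_sarrest_max=41.429,
    b_g2m=6.845, b_dg2m=8.969, n_hill=1.0,
    ec50_d=10.295, ec50_e=2.301, a_s=0.404, b_s=2.583,
)

MODEL2_G2M = G2MTreatmentParams(
    q1=0.619, q2=0.119, q3=0.102, q4=0.390,
    md_fr_max=0.143, md_ur_max=0.146, md_ms_max=0.296,
    md_g1arrest_max=0.282, md_sarrest_max=0.311,
    lam_dg1_max=2.075, lam_ur_max=20.426, lam_fr_max=5.753,
    lam_ms_max=4.831, lam_g1arrest_max=71.437, lam_ds_max=76.436,
    lam_sarrest_max=59.984,
    b_g2m=21.964, b_dg2m=18.483, n_hill=1.0,
    ec50_d=5.802, ec50_e=12.023, a_s=0.646, b_s=11.172,
)

MODEL3_S = STreatmentParams(
    q1=0.789, q2=0.218, q3=0.726,
    md_fr_max=0.443, md_ur_max=0.470, md_g2marrest_max=0.657,
    md_g1block_max=0.307,
    lam_dg2m_max=36.280, lam_ur_max=16.224, lam_fr_max=45.185,
    lam_g2marrest_max=43.440, lam_g1block_max=80.704,
    b_s=14.039, b_ds=10.744, n_hill=1.0,
    ec50_d=10.066, ec50_e=26.073, a_g2m=4.205, b_g2m=4.089,
)

#: in vitro dose ladders (nM) used for the dose-scan presets
DOSE_LADDERS = {
    "docetaxel": [0.5, 1.3, 2.6, 5.0, 10.0, 20.0],
    "paclitaxel": [3.3, 33.0, 170.0, 330.0, 1700.0, 3300.0],
    "gemcitabine": [10.0, 31.0, 63.0, 122.0, 1000.0, 10000.0],
}

#: single calibration-scale doses (nM): 3 nM docetaxel as reported; for
#: paclitaxel/gemcitabine ten times the respective progression EC50.
CALIBRATION_DOSES = {
    "docetaxel": 3.0,
    "paclitaxel": 120.0,
    "gemcitabine": 260.0,
}

PRESETS = {
    "model1": {"baseline": MODEL1_BASELINE, "g2m": MODEL1_G2M, "s": None,
               "drug": "docetaxel"},
    "model2": {"baseline": MODEL2_BASELINE, "g2m": MODEL2_G2M, "s": None,
               "drug": "paclitaxel"},
    "model3": {"baseline": MODEL3_BASELINE, "g2m": None, "s": MODEL3_S,
               "drug": "gemcitabine"},
}

#: duration of the apoptotic compartment (hours) before removal
APOPTOTIC_DURATION_H = 5.0
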