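"""Three-state Markov natural history of screen-detectable cancer.

The disease process is the progressive illness model

    free  --lambda1-->  PCDP  --lambda2-->  CP

where *free* is absence of detectable disease, PCDP is the pre-clinical
detectable phase (asymptomatic but screen-detectable) and CP is the
clinical phase (symptomatic surfacing).  Both transitions are
time-homogeneous exponential, so the mean sojourn time (MST) in the
pre-clinical phase is ``1 / lambda2`` and every derived quantity has a
closed form.

Parameters are stratified by mammographic feature (Tabar morphology for
tumours below 15 mm, plus a single unstratified stratum for tumours of
15 mm or larger); each stratum carries its own pre-clinical incidence
rate ``lambda1``, progression rate ``lambda2`` and screening test
sensitivity ``S``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "FeatureClass",
    "EXCLUDED_FEATURES",
    "StateLabel",
    "NaturalHistoryParams",
    "ParamSet",
    "transition_probability",
    "cumulative_risk_cp",
    "median_time_to_cp",
    "proportional_hazards_rates",
    "rates_to_offsets",
]

#: |lambda2 - lambda1| below this switches to the l'Hopital (equal-rates)
#: branch of the two-exponential convolution, avoiding catastrophic
#: cancellation.
EQUAL_RATE_TOL = 1e-9


class FeatureClass(str, enum.Enum):
    """Analysis strata: three mammographic appearances (<15 mm) + size stratum.

    ``LARGE`` is a tumour-size stratum (>= 15 mm), not an appearance; it
    carries its own parameter triple and no appearance sub-stratification.
    """

    STELLATE = "stellate"
    CIRCULAR = "circular"
    POWDERY_CRUSHED_STONE = "powdery_crushed_stone"
    LARGE = "large_ge15mm"

    # Ductal-type appearances: recognised on input, never fitted.
    CASTING = "casting"
    ARCHITECTURAL_DISTORTION = "architectural_distortion"


#: Appearances characteristic of ductal adenocarcinoma; parseable from
#: cohort files but excluded from every analysis.
EXCLUDED_FEATURES = frozenset(
    {FeatureClass.CASTING, FeatureClass.ARCHITECTURAL_DISTORTION}
)

#: The four strata that are actually modelled.
ANALYSIS_FEATURES = (
    FeatureClass.STELLATE,
    FeatureClass.CIRCULAR,
    FeatureClass.POWDERY_CRUSHED_STONE,
    FeatureClass.LARGE,
)


class StateLabel(str, enum.Enum):
    FREE = "free"
    PCDP = "pcdp"
    CP = "cp"


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Rate triple for one feature stratum.

    Parameters
    ----------
    lambda1 : float
        Pre-clinical incidence rate, events per person-year.  Stored per
        person-year internally; per-100,000 scaling is an I/O concern.
    lambda2 : float
        PCDP -> CP progression rate per year; ``mst() == 1 / lambda2``.
    sensitivity : float
        Per-screen detection probability while in PCDP, in (0, 1].
    period_label : str
        Free-text provenance, e.g. ``"1996-2010"``.
    """

    lambda1: float
    lambda2: float
    sensitivity: float = 1.0
    period_label: str = ""

    def __post_init__(self) -> None:
        if not (self.lambda1 > 0):
            raise ValueError(f"lambda1 must be positive, got {self.lambda1}")
        if not (self.lambda2 > 0):
            raise ValueError(f"lambda2 must be positive, got {self.lambda2}")
        if not (0.0 < self.sensitivity <= 1.0):
            raise ValueError(
                f"sensitivity must be in (0, 1], got {self.sensitivity}"
            )

    def mst(self) -> float:
        """Mean sojourn time in the pre-clinical phase, years."""
        return 1.0 / self.lambda2

    @classmethod
    def from_mst(
        cls,
        lambda1: float,
        mst: float,
        sensitivity: float = 1.0,
        period_label: str = "",
    ) -> "NaturalHistoryParams":
        return cls(lambda1, 1.0 / mst, sensitivity, period_label)


#: A fitted/assumed parameter triple per feature stratum.
ParamSet = Mapping[FeatureClass, NaturalHistoryParams]


def _check_time(t: float) -> None:
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")


def transition_probability(
    params: NaturalHistoryParams,
    from_state: StateLabel,
    to_state: StateLabel,
    t: float,
) -> float:
    """P(state(t) = ``to_state`` | state(0) = ``from_state``).

    Closed-form solution of the Kolmogorov forward equations for the
    progressive two-rate chain.  ``t`` in years.
    """
    _check_time(t)
    from_state = StateLabel(from_state)
    to_state = StateLabel(to_state)
    lam1, lam2 = params.lambda1, params.lambda2

    if from_state is StateLabel.CP:
        return 1.0 if to_state is StateLabel.CP else 0.0
    if from_state is StateLabel.PCDP:
        if to_state is StateLabel.FREE:
            return 0.0
        p_stay = math.exp(-lam2 * t)
        return p_stay if to_state is StateLabel.PCDP else 1.0 - p_stay
    # from FREE
    p_ff = math.exp(-lam1 * t)
    if to_state is StateLabel.FREE:
        return p_ff
    if abs(lam2 - lam1) < EQUAL_RATE_TOL:
        p_fp = lam1 * t * math.exp(-lam1 * t)
    else:
        p_fp = lam1 / (lam2 - lam1) * (math.exp(-lam1 * t) - math.exp(-lam2 * t))
    if to_state is StateLabel.PCDP:
        return p_fp
    return 1.0 - p_ff - p_fp  # CP by complement


def cumulative_risk_cp(params: NaturalHistoryParams, t) -> float:
    """Cumulative risk of clinical surfacing within ``t`` years of PCDP entry.

    ``1 - exp(-lambda2 * t)``: the progression CDF in the absence of any
    early-detection intervention.  Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = -np.expm1(-params.lambda2 * t)
    return float(out) if out.ndim == 0 else out


def median_time_to_cp(params: NaturalHistoryParams) -> float:
    """Median time from PCDP entry to clinical surfacing: ``ln 2 / lambda2``."""
    return math.log(2.0) / params.lambda2


def proportional_hazards_rates(
    baseline: NaturalHistoryParams,
    coefficients: Mapping[FeatureClass, tuple[float, float]],
    feature: FeatureClass,
) -> NaturalHistoryParams:
    """Per-feature rates from a baseline triple and log-rate offsets.

    The two transition intensities follow proportional-hazards forms
    ``lambda1(f) = lambda1_0 * exp(beta1_f)`` and
    ``lambda2(f) = lambda2_0 * exp(beta2_f)``; the reference feature's
    offsets are (0, 0).  This parameterisation is a bijection with the
    per-feature rate triple, see :func:`rates_to_offsets`.
    """
    feature = FeatureClass(feature)
    b1, b2 = coefficients.get(feature, (0.0, 0.0))
    if not (math.isfinite(b1) and math.isfinite(b2)):
        raise ValueError(f"non-finite coefficients for {feature.value}: {(b1, b2)}")
    return replace(
        baseline,
        lambda1=baseline.lambda1 * math.exp(b1),
        lambda2=baseline.lambda2 * math.exp(b2),
    )


def rates_to_offsets(
    baseline: NaturalHistoryParams, target: NaturalHistoryParams
) -> tuple[float, float]:
    """Inverse of :func:`proportional_hazards_rates`: recover (beta1, beta2)."""
    return (
        math.log(target.lambda1 / baseline.lambda1),
        math.log(target.lambda2 / baseline.lambda2),
    )
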