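"""Synthetic screening cohorts with the structure the model assumes.

The generator draws, for each woman, feature-specific competing onset
times (exponential, rate ``lambda1(f)``; earliest wins), an exponential
sojourn with mean MST(f), a screening schedule (fixed-interval service
preset, or the trial rule: 24-month interval under age 50 and 33 months
at 50 or older), Bernoulli attendance per invitation and Bernoulli(S(f))
detection at each attended screen during the pre-clinical phase, then
classifies the outcome into the four detection modes.

Two presets emulate the study designs the model was built for: a
1977-1985 randomised trial (invited and uninvited arms, age-dependent
interval) and a 1996-2010 service-screening period (fixed interval,
default biennial).  The preset parameter values encode only the textual
constraints on the two periods (longer sojourn times and lower stellate
sensitivity early; sensitivity >= 0.95 and a roughly doubled share of
calcification-type tumours late); see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .likelihood import Cohort, DetectionMode, WomanRecord
from .natural_history import FeatureClass, NaturalHistoryParams, ParamSet

__all__ = ["ScenarioConfig", "generate_cohort", "tabulate_cohort",
           "trial_1977_config", "service_1996_config"]

#: warn above this total pre-clinical incidence (per person-year)
_PLAUSIBLE_TOTAL_LAMBDA1 = 0.01


def _period2_params() -> dict[FeatureClass, NaturalHistoryParams]:
    mk = NaturalHistoryParams.from_mst
    return {
        FeatureClass.STELLATE: mk(78e-5, 3.76, 0.95, "1996-2010"),
        FeatureClass.CIRCULAR: mk(66e-5, 2.65, 0.95, "1996-2010"),
        FeatureClass.POWDERY_CRUSHED_STONE: mk(46e-5, 4.26, 0.95, "1996-2010"),
        FeatureClass.LARGE: mk(56e-5, 1.50, 0.95, "1996-2010"),
    }


def _period1_params() -> dict[FeatureClass, NaturalHistoryParams]:
    mk = NaturalHistoryParams.from_mst
    return {
        FeatureClass.STELLATE: mk(75e-5, 4.50, 0.75, "1977-1985"),
        FeatureClass.CIRCULAR: mk(57e-5, 3.30, 0.85, "1977-1985"),
        FeatureClass.POWDERY_CRUSHED_STONE: mk(18e-5, 4.30, 0.85, "1977-1985"),
        FeatureClass.LARGE: mk(100e-5, 1.80, 0.65, "1977-1985"),
    }


@dataclass
class ScenarioConfig:
    """Everything needed to generate one cohort, seed included.

    ``interval`` is the fixed inter-screening interval in years for the
    service design; the trial design ignores it and applies the age rule
    (2.0 years under 50, 2.75 years at 50+).  ``invited_fraction`` < 1
    creates an unscreened arm.  Ages only gate the schedule rule; rates
    are age-free, mirroring the fitted model.
    """

    preset: str = "custom"                   # trial_1977 | service_1996 | custom
    n: int = 10_000
    params: dict[FeatureClass, NaturalHistoryParams] = field(default_factory=_period2_params)
    interval: float = 2.0
    lead_in: float = 2.0                     # disease-free run-in before first screen
    horizon: float = 12.0                    # follow-up from entry, years
    attendance: float = 1.0
    invited_fraction: float = 1.0
    entry_age_range: tuple[float, float] = (40.0, 74.0)
    age_rule: bool = False                   # trial interval rule 24/33 months
    period_label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.preset not in ("trial_1977", "service_1996", "custom"):
            raise ValueError(f"unknown preset {self.preset!r}")
        total = sum(p.lambda1 for p in self.params.values())
        if total > _PLAUSIBLE_TOTAL_LAMBDA1:
            import warnings
            warnings.warn(
                f"total pre-clinical incidence {total * 1e5:.0f} per 100,000/yr "
                "exceeds a plausible population level", stacklevel=2,
            )

    def schedule(self, entry_age: float) -> np.ndarray:
        """Invitation times (years since entry) for a woman of this entry age."""
        if self.age_rule:
            delta = 2.0 if entry_age < 50.0 else 2.75
        else:
            delta = self.interval
        n_rounds = int(math.floor((self.horizon - self.lead_in) / delta + 1e-9)) + 1
        if n_rounds <= 0:
            return np.zeros(0)
        times = self.lead_in + delta * np.arange(n_rounds)
        return np.minimum(times[times <= self.horizon + 1e-9], self.horizon)


def trial_1977_config(n: int = 10_000, seed: int | None = None, **kw) -> ScenarioConfig:
    """Randomised-trial design: invited vs uninvited, 24/33-month age rule."""
    kw.setdefault("params", _period1_params())
    kw.setdefault("invited_fraction", 0.5)
    kw.setdefault("attendance", 0.85)
    return ScenarioConfig(
        preset="trial_1977", n=n, age_rule=True,
        period_label="1977-1985", seed=seed, **kw,
    )


def service_1996_config(n: int = 10_000, seed: int | None = None, **kw) -> ScenarioConfig:
    """Service-screening design: everyone invited on a fixed interval (18-36 mo)."""
    kw.setdefault("params", _period2_params())
    if not 1.5 <= kw.get("interval", 2.0) <= 3.0:
        raise ValueError("service interval must lie in 18-36 months")
    return ScenarioConfig(
        preset="service_1996", n=n, period_label="1996-2010", seed=seed, **kw,
    )


def _classify_onset_case(
    t_onset: float, v: float, schedule: np.ndarray,
    attended: np.ndarray, detected: np.ndarray, horizon: float,
) -> tuple[DetectionMode, float, int | None, tuple[float, ...]]:
    """Outcome of one woman whose pre-clinical onset is at ``t_onset``."""
    att_times = schedule[attended]
    # first attended screen inside (onset, surfacing) with a positive read
    in_phase = attended & (schedule > t_onset) & (schedule < v)
    hit = in_phase & detected
    if hit.any():
        t_det = schedule[hit][0]
        if t_det <= horizon:
            screens = tuple(att_times[att_times <= t_det])
            return (DetectionMode.SCREEN_DETECTED, t_det, len(screens), screens)
    if v <= horizon:
        prior = tuple(att_times[att_times < v])
        if prior:
            return (DetectionMode.INTERVAL_CANCER, v, None, prior)
        return (DetectionMode.CLINICAL, v, None, ())
    screens = tuple(att_times[att_times <= horizon])
    return (DetectionMode.CENSORED, horizon, None, screens)


def generate_cohort(config: ScenarioConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its ground-truth sidecar table.

    Returns ``(cohort, truth)``; ``truth`` has one row per woman with the
    latent onset feature/time and sojourn (NaN where no onset occurred
    within follow-up), for parameter-recovery experiments.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    feats = list(config.params.keys())
    lam1 = np.array([config.params[f].lambda1 for f in feats])

    ages = rng.uniform(*config.entry_age_range, size=n)
    invited = rng.random(n) < config.invited_fraction
    # competing feature-specific onsets; earliest wins
    onsets = rng.exponential(1.0 / lam1, size=(n, len(feats)))
    which = onsets.argmin(axis=1)
    t_onset = onsets.min(axis=1)
    sojourn = np.empty(n)
    for k, f in enumerate(feats):
        mask = which == k
        sojourn[mask] = rng.exponential(
            config.params[f].mst(), size=int(mask.sum())
        )
    surfacing = t_onset + sojourn
    active = t_onset <= config.horizon  # onset inside follow-up can matter

    # attendance / detection draws, fixed width across age groups
    max_rounds = max(
        (len(config.schedule(a)) for a in (config.entry_age_range[0],
                                           config.entry_age_range[1])),
        default=0,
    )
    attend_draws = rng.random((n, max_rounds)) < config.attendance
    detect_draws = rng.random((n, max_rounds))

    records: list[WomanRecord] = []
    truth_rows = []
    # cache censored-schedule tuples per (age-band, attendance pattern)
    for i in range(n):
        sched = config.schedule(ages[i]) if invited[i] else np.zeros(0)
        r = len(sched)
        attended = attend_draws[i, :r]
        if active[i]:
            f = feats[which[i]]
            detected = detect_draws[i, :r] < config.params[f].sensitivity
            mode, t_out, rnd, screens = _classify_onset_case(
                t_onset[i], surfacing[i], sched, attended, detected, config.horizon
            )
            feature = f if mode is not DetectionMode.CENSORED else None
        else:
            att = sched[attended]
            mode, t_out, rnd, screens = (
                DetectionMode.CENSORED, config.horizon, None, tuple(att),
            )
            feature = None
        records.append(WomanRecord(
            id=f"w{i:07d}", screen_times=screens, outcome=mode,
            outcome_time=float(t_out), outcome_round=rnd, feature=feature,
            period=config.period_label,
        ))
        truth_rows.append({
            "id": f"w{i:07d}", "entry_age": float(ages[i]),
            "invited": bool(invited[i]),
            "onset_feature": feats[which[i]].value if active[i] else None,
            "onset_time": float(t_onset[i]) if active[i] else np.nan,
            "sojourn": float(sojourn[i]) if active[i] else np.nan,
        })
    cohort = Cohort(records, period_label=config.period_label)
    return cohort, pd.DataFrame(truth_rows)


def tabulate_cohort(cohort: Cohort) -> pd.DataFrame:
    """Descriptive counts/percentages of cancers by feature and detection mode.

    One row per (feature, size stratum, detection mode); percentages are
    of all cancer records and sum to 100 up to rounding.  A cancer-free
    cohort yields an empty frame.
    """
    cancers = cohort.cancers()
    if not cancers:
        return pd.DataFrame(
            columns=["feature", "size_stratum", "detection_mode", "count", "percent"]
        )
    df = pd.DataFrame({
        "feature": [r.feature.value for r in cancers],
        "size_stratum": [
            ">=15mm" if r.feature is FeatureClass.LARGE else "<15mm" for r in cancers
        ],
        "detection_mode": [r.outcome.value for r in cancers],
    })
    out = (
        df.groupby(["feature", "size_stratum", "detection_mode"])
        .size().rename("count").reset_index()
    )
    out["percent"] = 100.0 * out["count"] / out["count"].sum()
    return out
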