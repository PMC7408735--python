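"""Exact likelihood of individual screening histories.

Under the three-state exponential model with per-screen sensitivity S,
every detection mode has a closed-form probability (or density) built
from a single kernel,

    A(a, b; T) = integral_a^b  lambda1 e^{-lambda1 u} e^{-lambda2 (T-u)} du,

the probability of entering the pre-clinical phase in (a, b] and still
being pre-clinical (undetected progression aside) at time T.  Screens
attended at 0 < t_1 < ... < t_k from a disease-free entry at time 0;
each attended screen during PCDP detects with probability S, so a case
missed at m consecutive screens carries weight (1 - S)^m.

Detection modes and their contributions (t_0 = 0):

* screen-detected at round j:
    S * sum_{i=1..j} (1-S)^{j-i} A(t_{i-1}, t_i; t_j)
* interval cancer surfacing at v, j attended screens before v
  (false-negative component + newly-arising component):
    lambda2 * [ sum_{i=1..j} (1-S)^{j-i+1} A(t_{i-1}, t_i; v) + A(t_j, v; v) ]
* clinically surfacing with no prior screen (j = 0): lambda2 * A(0, v; v)
* censored at tau after k screens (still free, or pre-clinical and missed):
    e^{-lambda1 tau} + sum_{i=1..k} (1-S)^{k-i+1} A(t_{i-1}, t_i; tau)
    + A(t_k, tau; tau)

These masses/densities sum to one over the outcome space for any
schedule, which the test suite verifies by adaptive quadrature.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate

from .natural_history import (
    ANALYSIS_FEATURES,
    EXCLUDED_FEATURES,
    FeatureClass,
    NaturalHistoryParams,
    ParamSet,
    EQUAL_RATE_TOL,
)

__all__ = [
    "DetectionMode",
    "WomanRecord",
    "Cohort",
    "pcdp_kernel",
    "lik_screen_detected",
    "lik_interval_cancer_density",
    "interval_cancer_components",
    "lik_censored",
    "lik_clinical_unscreened_density",
    "woman_log_likelihood",
    "cohort_log_likelihood",
    "detection_mode_masses",
    "CompiledCohort",
]


# ---------------------------------------------------------------------------
# data model


class DetectionMode(str, enum.Enum):
    SCREEN_DETECTED = "screen_detected"
    INTERVAL_CANCER = "interval_cancer"
    CLINICAL = "clinical"
    CENSORED = "censored"


@dataclass(frozen=True)
class WomanRecord:
    """One woman's screening event history.

    Times are years since her (disease-free) entry.  ``outcome_time`` is
    the detecting screen's time for screen-detected cases, the clinical
    surfacing time for interval/clinical cases and the censoring time
    otherwise.  ``outcome_round`` is the 1-based index of the detecting
    screen for screen-detected cases.
    """

    id: str
    screen_times: tuple[float, ...]
    outcome: DetectionMode
    outcome_time: float
    outcome_round: int | None = None
    feature: FeatureClass | None = None
    entry_time: float = 0.0
    period: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "screen_times", tuple(float(t) for t in self.screen_times))
        object.__setattr__(self, "outcome", DetectionMode(self.outcome))
        if self.feature is not None:
            object.__setattr__(self, "feature", FeatureClass(self.feature))
        ts = self.screen_times
        if any(t < 0 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"record {self.id}: screen times must be strictly increasing and >= 0")
        if self.outcome is DetectionMode.CENSORED:
            if self.feature is not None:
                raise ValueError(f"record {self.id}: censored record must not carry a feature")
            if ts and self.outcome_time < ts[-1]:
                raise ValueError(f"record {self.id}: censor time before last screen")
        else:
            if self.feature is None:
                raise ValueError(f"record {self.id}: cancer outcome requires a feature")
        if self.outcome is DetectionMode.SCREEN_DETECTED:
            j = self.outcome_round
            if j is None or not (1 <= j <= len(ts)):
                raise ValueError(f"record {self.id}: invalid detection round {j}")
            if not math.isclose(self.outcome_time, ts[j - 1]):
                raise ValueError(f"record {self.id}: outcome_time must equal the round-{j} screen time")
        if self.outcome is DetectionMode.INTERVAL_CANCER:
            if not ts or self.outcome_time <= ts[-1]:
                raise ValueError(f"record {self.id}: interval surfacing must follow the last attended screen")
        if self.outcome is DetectionMode.CLINICAL and ts:
            # clinical (unscreened) cases surface before any attended screen
            if self.outcome_time > ts[0]:
                raise ValueError(f"record {self.id}: clinical outcome with prior attended screens")

    @property
    def screens_before_outcome(self) -> tuple[float, ...]:
        """Screens attended strictly before a surfacing time (for densities)."""
        return tuple(t for t in self.screen_times if t < self.outcome_time)


@dataclass
class Cohort:
    """A collection of validated screening histories."""

    records: list[WomanRecord]
    period_label: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def person_years(self) -> float:
        return float(sum(r.outcome_time for r in self.records))

    def cancers(self) -> list[WomanRecord]:
        return [r for r in self.records if r.outcome is not DetectionMode.CENSORED]


# ---------------------------------------------------------------------------
# kernel

def pcdp_kernel(lam1: float, lam2: float, a, b, T):
    """A(a, b; T): enter PCDP in (a, b], remain pre-clinical at T.

    Vectorised over ``a``, ``b``, ``T`` (broadcast); the rates are scalar.
    Written in overflow-safe form: all exponents are <= 0 when T >= b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    T = np.asarray(T, dtype=float)
    if abs(lam2 - lam1) < EQUAL_RATE_TOL:
        out = lam1 * np.exp(-lam1 * T) * (b - a)
    else:
        out = (
            lam1
            / (lam2 - lam1)
            * (np.exp(lam2 * (b - T) - lam1 * b) - np.exp(lam2 * (a - T) - lam1 * a))
        )
    return float(out) if out.ndim == 0 else out


def _check_screens(screen_times: Sequence[float]) -> tuple[float, ...]:
    ts = tuple(float(t) for t in screen_times)
    if any(t < 0 for t in ts) or any(y <= x for x, y in zip(ts, ts[1:])):
        raise ValueError("screen times must be strictly increasing and >= 0")
    return ts


# ---------------------------------------------------------------------------
# detection-mode contributions

def lik_screen_detected(
    params: NaturalHistoryParams, screen_times: Sequence[float], j: int
) -> float:
    """Probability of detection at the j-th attended screen (1-based)."""
    ts = _check_screens(screen_times)
    if not (1 <= j <= len(ts)):
        raise ValueError(f"round index {j} outside 1..{len(ts)}")
    S = params.sensitivity
    bounds = (0.0,) + ts[:j]
    i = np.arange(1, j + 1)
    terms = pcdp_kernel(
        params.lambda1, params.lambda2,
        np.array(bounds[:-1]), np.array(bounds[1:]), ts[j - 1],
    )
    return float(S * np.sum((1.0 - S) ** (j - i) * np.atleast_1d(terms)))


def interval_cancer_components(
    params: NaturalHistoryParams, screen_times: Sequence[float], v: float
) -> tuple[float, float]:
    """(false-negative, newly-arising) components of the interval density at v."""
    ts = _check_screens(screen_times)
    if ts and v <= ts[-1]:
        raise ValueError("surfacing time must follow the last attended screen")
    if v <= 0:
        raise ValueError("surfacing time must be positive")
    lam1, lam2, S = params.lambda1, params.lambda2, params.sensitivity
    j = len(ts)
    fn = 0.0
    if j:
        bounds = (0.0,) + ts
        i = np.arange(1, j + 1)
        terms = np.atleast_1d(
            pcdp_kernel(lam1, lam2, np.array(bounds[:-1]), np.array(bounds[1:]), v)
        )
        fn = float(lam2 * np.sum((1.0 - S) ** (j - i + 1) * terms))
    last = ts[-1] if ts else 0.0
    new = float(lam2 * pcdp_kernel(lam1, lam2, last, v, v))
    return fn, new


def lik_interval_cancer_density(
    params: NaturalHistoryParams, screen_times: Sequence[float], v: float
) -> float:
    """Density (per year) of clinical surfacing at v after >= 1 negative screen."""
    fn, new = interval_cancer_components(params, screen_times, v)
    return fn + new


def lik_clinical_unscreened_density(params: NaturalHistoryParams, v: float) -> float:
    """Density of clinical surfacing at v with no attended screen."""
    return lik_interval_cancer_density(params, (), v)


def lik_censored(
    params: NaturalHistoryParams, screen_times: Sequence[float], tau: float
) -> float:
    """Probability of reaching tau without diagnosis: disease-free, or
    pre-clinical and missed at every attended screen."""
    ts = _check_screens(screen_times)
    if ts and tau < ts[-1]:
        raise ValueError("censor time before last attended screen")
    lam1, lam2, S = params.lambda1, params.lambda2, params.sensitivity
    k = len(ts)
    total = math.exp(-lam1 * tau)
    if k:
        bounds = (0.0,) + ts
        i = np.arange(1, k + 1)
        terms = np.atleast_1d(
            pcdp_kernel(lam1, lam2, np.array(bounds[:-1]), np.array(bounds[1:]), tau)
        )
        total += float(np.sum((1.0 - S) ** (k - i + 1) * terms))
    last = ts[-1] if ts else 0.0
    total += float(pcdp_kernel(lam1, lam2, last, tau, tau))
    return total


# ---------------------------------------------------------------------------
# per-record and cohort likelihood

def _record_event_loglik(params: NaturalHistoryParams, record: WomanRecord) -> float:
    if record.outcome is DetectionMode.SCREEN_DETECTED:
        p = lik_screen_detected(params, record.screen_times, record.outcome_round)
    elif record.outcome is DetectionMode.INTERVAL_CANCER:
        p = lik_interval_cancer_density(
            params, record.screens_before_outcome, record.outcome_time
        )
    elif record.outcome is DetectionMode.CLINICAL:
        p = lik_clinical_unscreened_density(params, record.outcome_time)
    else:
        p = lik_censored(params, record.screen_times, record.outcome_time)
    if p <= 0:
        return -math.inf
    return math.log(p)


def woman_log_likelihood(
    params: ParamSet | NaturalHistoryParams,
    record: WomanRecord,
    features: Sequence[FeatureClass] | None = None,
) -> float:
    """Log-likelihood contribution of one woman.

    The feature-specific disease processes are treated as independent, so
    a woman with a cancer of feature f contributes f's event term times
    every other fitted feature's no-event (censored-form) term, and a
    censored woman contributes each fitted feature's no-event term.

    ``params`` may be a single triple (single-feature model) or a mapping
    feature -> triple; ``features`` restricts the fitted set.
    """
    if isinstance(params, NaturalHistoryParams):
        if record.outcome is not DetectionMode.CENSORED and record.feature is None:
            raise ValueError(f"record {record.id}: cancer outcome without feature")
        return _record_event_loglik(params, record)

    fitted = tuple(features) if features is not None else tuple(params.keys())
    total = 0.0
    event_feature = record.feature if record.outcome is not DetectionMode.CENSORED else None
    if event_feature is not None and event_feature not in params:
        raise ValueError(
            f"record {record.id}: feature {event_feature.value} not in parameter set"
        )
    for f in fitted:
        if f is event_feature:
            total += _record_event_loglik(params[f], record)
        else:
            screens = tuple(t for t in record.screen_times if t <= record.outcome_time)
            p = lik_censored(params[f], screens, record.outcome_time)
            total += math.log(p) if p > 0 else -math.inf
    return total


def cohort_log_likelihood(
    params: ParamSet | NaturalHistoryParams,
    cohort: Cohort | Iterable[WomanRecord],
    features: Sequence[FeatureClass] | None = None,
) -> float:
    """Sum of :func:`woman_log_likelihood` over the cohort."""
    total = 0.0
    for record in cohort:
        try:
            total += woman_log_likelihood(params, record, features)
        except ValueError as exc:
            raise ValueError(f"record {record.id}: {exc}") from exc
    return total


# ---------------------------------------------------------------------------
# total-probability decomposition (quadrature; used by tests & diagnostics)

def detection_mode_masses(
    params: NaturalHistoryParams,
    screen_times: Sequence[float],
    tau: float,
) -> dict[str, float]:
    """Outcome-mode probability masses for a fully-attended schedule.

    Integrates the surfacing densities between screens by adaptive
    quadrature and returns a dict with keys ``screen_detected`` (list per
    round), ``interval`` (includes pre-first-screen clinical surfacing),
    ``censored`` and ``total``.  ``total`` equals 1 up to quadrature error
    for any valid schedule — the model's total-probability identity.
    """
    ts = _check_screens(screen_times)
    if tau < (ts[-1] if ts else 0.0):
        raise ValueError("tau before last screen")
    per_round = [lik_screen_detected(params, ts, j) for j in range(1, len(ts) + 1)]
    edges = (0.0,) + ts + (tau,)
    surfacing = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        prior = tuple(t for t in ts if t <= lo)
        val, _ = integrate.quad(
            lambda v: lik_interval_cancer_density(params, prior, v),
            lo, hi, epsabs=1e-12, epsrel=1e-10, limit=200,
        )
        surfacing += val
    censored = lik_censored(params, ts, tau)
    total = sum(per_round) + surfacing + censored
    return {
        "screen_detected": per_round,
        "interval": surfacing,
        "censored": censored,
        "total": total,
    }


# ---------------------------------------------------------------------------
# compiled cohort: flat-array evaluation for fitting

_MODE_CENSORED = 0
_MODE_SCREEN = 1
_MODE_DENSITY = 2


class CompiledCohort:
    """Flat-array representation of a cohort likelihood for one feature set.

    Identical histories are grouped and counted, and every kernel term
    A(a, b; T) * (1-S)^p across all records is laid out in flat arrays so
    one likelihood evaluation is a handful of vectorised operations.
    Results are identical (to floating-point association order) to the
    naive per-record sum; ``cohort_log_likelihood`` is the reference.
    """

    def __init__(
        self,
        cohort: Cohort | Iterable[WomanRecord],
        features: Sequence[FeatureClass] | None = None,
    ):
        records = list(cohort)
        if features is None:
            feats = sorted(
                {r.feature for r in records if r.feature is not None},
                key=lambda f: f.value,
            )
            features = feats or [FeatureClass.STELLATE]
        self.features = tuple(FeatureClass(f) for f in features)
        for f in self.features:
            if f in EXCLUDED_FEATURES:
                raise ValueError(f"feature {f.value} is excluded from analysis")
        self.n_records = len(records)
        self._per_feature = [
            self._compile_feature(records, f) for f in self.features
        ]
        self.n_events = {
            f: sum(1 for r in records if r.feature is f) for f in self.features
        }

    @staticmethod
    def _profile_key(record: WomanRecord, feature: FeatureClass):
        if record.feature is feature and record.outcome is not DetectionMode.CENSORED:
            if record.outcome is DetectionMode.SCREEN_DETECTED:
                return (_MODE_SCREEN, record.screen_times[: record.outcome_round],
                        record.outcome_time, record.outcome_round)
            return (_MODE_DENSITY, record.screens_before_outcome, record.outcome_time, None)
        screens = tuple(t for t in record.screen_times if t <= record.outcome_time)
        return (_MODE_CENSORED, screens, record.outcome_time, None)

    def _compile_feature(self, records, feature):
        counts: dict[tuple, int] = {}
        for r in records:
            key = self._profile_key(r, feature)
            counts[key] = counts.get(key, 0) + 1

        a_, b_, T_, pow_, seg_ = [], [], [], [], []
        mode = np.empty(len(counts), dtype=np.int8)
        tau = np.zeros(len(counts))
        cnt = np.empty(len(counts))
        for s, ((m, screens, t, rnd), c) in enumerate(counts.items()):
            mode[s] = m
            cnt[s] = c
            bounds = (0.0,) + screens
            k = len(screens)
            if m == _MODE_SCREEN:
                # terms i=1..j with power j-i, T = t_j
                for i in range(1, rnd + 1):
                    a_.append(bounds[i - 1]); b_.append(bounds[i])
                    T_.append(t); pow_.append(rnd - i); seg_.append(s)
            else:
                # censored / density: missed terms with power k-i+1, plus
                # the newly-arising term (t_k, t; t) at power 0
                for i in range(1, k + 1):
                    a_.append(bounds[i - 1]); b_.append(bounds[i])
                    T_.append(t); pow_.append(k - i + 1); seg_.append(s)
                a_.append(bounds[k]); b_.append(t); T_.append(t)
                pow_.append(0); seg_.append(s)
                if m == _MODE_CENSORED:
                    tau[s] = t
        return {
            "a": np.asarray(a_), "b": np.asarray(b_), "T": np.asarray(T_),
            "pow": np.asarray(pow_, dtype=float), "seg": np.asarray(seg_, dtype=np.intp),
            "mode": mode, "tau": tau, "count": cnt, "n_profiles": len(counts),
        }

    def loglik_feature(
        self, index: int, lam1: float, lam2: float, sensitivity: float
    ) -> float:
        c = self._per_feature[index]
        kern = pcdp_kernel(lam1, lam2, c["a"], c["b"], c["T"])
        w = np.where(c["pow"] == 0, 1.0, (1.0 - sensitivity) ** c["pow"])
        seg = np.bincount(c["seg"], weights=kern * w, minlength=c["n_profiles"])
        p = np.where(
            c["mode"] == _MODE_SCREEN, sensitivity * seg,
            np.where(c["mode"] == _MODE_DENSITY, lam2 * seg, seg),
        )
        p = p + np.where(c["mode"] == _MODE_CENSORED, np.exp(-lam1 * c["tau"]), 0.0)
        if np.any(p <= 0):
            return -math.inf
        return float(np.dot(c["count"], np.log(p)))

    def loglik(self, params: ParamSet) -> float:
        total = 0.0
        for i, f in enumerate(self.features):
            p = params[f]
            total += self.loglik_feature(i, p.lambda1, p.lambda2, p.sensitivity)
        return total
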