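"""Interval-cancer burden as a function of screening interval and sensitivity.

The screening-performance metric is the proportional interval-cancer
incidence I/E: interval cancers as a fraction of the expected (background)
clinical incidence in the absence of screening.  Under steady-state
repeated screening every ``delta`` years, with pre-clinical sojourn
Exp(lambda = 1/MST) and per-screen sensitivity S, a tumour whose onset is
uniform within a screening cycle becomes an interval cancer iff it
surfaces clinically before the first successful screen, giving the closed
form (a = exp(-lambda * delta)):

    I/E = 1 - S (1 - a) / [ lambda delta (1 - (1 - S) a) ]

(derivation in docs/methods.md; an independent renewal simulation
confirms it).  At S = 1 this reduces to 1 - (1 - a)/(lambda delta); at
S = 0 screening detects nothing and I/E = 1.

Two estimators are provided: the closed form (default) and a woman-level
four-arm randomised-design microsimulation with configurable horizon,
attendance and onset initialisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .natural_history import FeatureClass, NaturalHistoryParams, ParamSet

__all__ = [
    "RegimeSpec",
    "IETable",
    "ie_closed_form",
    "simulate_renewal_ie",
    "simulate_rct",
    "RCTResult",
    "build_ie_table",
    "policy_threshold_search",
    "round_half_away",
]

#: Default grids mirroring the published policy table.
DEFAULT_DELTAS = (1.0, 2.0, 3.0)
DEFAULT_SENSITIVITIES = (0.4, 0.5, 0.6, 0.8, 1.0)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def ie_closed_form(mst: float, sensitivity: float, delta: float) -> float:
    """Steady-state proportional interval-cancer incidence, as a proportion.

    Parameters
    ----------
    mst : float
        Mean sojourn time in the pre-clinical phase, years.
    sensitivity : float
        Per-screen detection probability in [0, 1]; 0 returns exactly 1.
    delta : float
        Inter-screening interval, years.
    """
    if mst <= 0:
        raise ValueError("mst must be positive")
    if delta <= 0:
        raise ValueError("inter-screening interval must be positive")
    if not (0.0 <= sensitivity <= 1.0):
        raise ValueError("sensitivity must be in [0, 1]")
    if sensitivity == 0.0:
        return 1.0
    lam = 1.0 / mst
    a = math.exp(-lam * delta)
    return 1.0 - sensitivity * (1.0 - a) / (lam * delta * (1.0 - (1.0 - sensitivity) * a))


def simulate_renewal_ie(
    mst: float,
    sensitivity: float,
    delta: float,
    n: int,
    seed: int | np.random.Generator,
) -> float:
    """Monte-Carlo I/E from the steady-state renewal picture.

    ``n`` tumours enter the pre-clinical phase at times uniform within a
    screening cycle; screens recur every ``delta`` years with per-screen
    detection Bernoulli(S); sojourns are Exp(1/mst).  A tumour surfacing
    before its first successful screen is an interval cancer.  The
    returned interval fraction estimates :func:`ie_closed_form` and is
    the independent oracle for it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = 1.0 / mst
    u = rng.uniform(0.0, delta, size=n)          # onset position in cycle
    x = rng.exponential(1.0 / lam, size=n)       # sojourn
    if sensitivity == 0.0:
        return 1.0
    m = rng.geometric(sensitivity, size=n)       # index of first successful screen
    interval = x < (m * delta - u)
    return float(np.mean(interval))


@dataclass(frozen=True)
class RegimeSpec:
    """One arm of the simulated randomised design."""

    label: str
    interval: float          # years; inf for the unscreened arm
    horizon: float
    attendance: float = 1.0

    def __post_init__(self) -> None:
        if not math.isinf(self.interval):
            if self.interval <= 0:
                raise ValueError("interval must be positive")
            if self.horizon < self.interval:
                raise ValueError("horizon must cover at least one interval")
        if not (0.0 < self.attendance <= 1.0):
            raise ValueError("attendance must be in (0, 1]")

    @property
    def rounds(self) -> int:
        if math.isinf(self.interval):
            return 0
        return int(math.floor(self.horizon / self.interval))

    @classmethod
    def standard_arms(
        cls, horizon: float = 30.0, attendance: float = 1.0
    ) -> tuple["RegimeSpec", ...]:
        return (
            cls("annual", 1.0, horizon, attendance),
            cls("biennial", 2.0, horizon, attendance),
            cls("triennial", 3.0, horizon, attendance),
            cls("none", math.inf, horizon, attendance),
        )


@dataclass
class RCTResult:
    """Per-arm outcome counts and empirical I/E ratios."""

    counts: pd.DataFrame          # index: arm; columns: outcome counts + person-years
    ie: dict[str, float | None]   # arm label -> empirical I/E (None if undefined)
    screen_detected_by_round: dict[str, np.ndarray]


def _simulate_arm(
    params: NaturalHistoryParams,
    regime: RegimeSpec,
    n: int,
    rng: np.random.Generator,
    onset: str,
) -> dict:
    """Vectorised single-arm cohort: onset, sojourn, per-screen detection."""
    lam1, lam2, S = params.lambda1, params.lambda2, params.sensitivity
    horizon = regime.horizon
    if onset == "exponential":
        o = rng.exponential(1.0 / lam1, size=n)
    elif onset == "steady_state":
        # every woman develops a tumour, onset uniform over follow-up:
        # emulates the stationary flow of onsets the closed form assumes
        o = rng.uniform(0.0, horizon, size=n)
    else:
        raise ValueError(f"unknown onset mode {onset!r}")
    x = rng.exponential(1.0 / lam2, size=n)
    v = o + x                                    # clinical surfacing time

    if math.isinf(regime.interval):
        clinical = v <= horizon
        py = np.minimum(v, horizon)
        return {
            "screen_detected": 0, "interval": 0,
            "clinical": int(clinical.sum()), "censored": int((~clinical).sum()),
            "person_years": float(py.sum()), "by_round": np.zeros(0, dtype=int),
        }

    screens = np.arange(regime.interval, horizon + 1e-12, regime.interval)
    R = len(screens)
    # attendance and detection per invitation; success = attended & detected
    attend = rng.random((n, R)) < regime.attendance
    detect = rng.random((n, R)) < S
    in_pcdp = (screens[None, :] > o[:, None]) & (screens[None, :] < v[:, None])
    success = attend & detect & in_pcdp
    any_success = success.any(axis=1)
    first = np.where(any_success, success.argmax(axis=1), R)
    t_detect = np.where(any_success, screens[np.minimum(first, R - 1)], np.inf)

    screen_det = any_success & (t_detect <= horizon)
    surfaced = (~screen_det) & (v <= horizon)
    # interval vs clinical: any attended screen before surfacing?
    attended_before = (attend & (screens[None, :] < v[:, None])).any(axis=1)
    interval = surfaced & attended_before
    clinical = surfaced & ~attended_before
    censored = ~screen_det & ~surfaced

    end = np.where(screen_det, t_detect, np.where(surfaced, v, horizon))
    by_round = np.bincount(first[screen_det], minlength=R)[:R]
    return {
        "screen_detected": int(screen_det.sum()), "interval": int(interval.sum()),
        "clinical": int(clinical.sum()), "censored": int(censored.sum()),
        "person_years": float(end.sum()), "by_round": by_round,
    }


def simulate_rct(
    params: NaturalHistoryParams,
    regimes: Sequence[RegimeSpec],
    n_per_arm: int,
    seed: int,
    onset: str = "exponential",
) -> RCTResult:
    """Microsimulate a multi-arm randomised screening design.

    Each woman's pre-clinical onset is drawn either from rate ``lambda1``
    (``onset='exponential'``, whole-population cohort) or uniformly over
    follow-up (``onset='steady_state'``, tumour-bearing flow matching the
    closed form's stationarity assumption).  Empirical I/E of a screening
    arm = interval cancers per person-year in that arm divided by clinical
    cancers per person-year in the unscreened arm.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    rows, by_round = {}, {}
    for reg in regimes:
        rows[reg.label] = _simulate_arm(params, reg, n_per_arm, rng, onset)
        by_round[reg.label] = rows[reg.label].pop("by_round")
    counts = pd.DataFrame(rows).T

    control = next((r for r in regimes if math.isinf(r.interval)), None)
    ie: dict[str, float | None] = {}
    if control is not None:
        c = rows[control.label]
        if c["clinical"] == 0:
            base = None
        else:
            base = c["clinical"] / c["person_years"]
        for reg in regimes:
            if math.isinf(reg.interval):
                continue
            r = rows[reg.label]
            ie[reg.label] = (
                None if base is None
                else (r["interval"] / r["person_years"]) / base
            )
    return RCTResult(counts=counts, ie=ie, screen_detected_by_round=by_round)


@dataclass
class IETable:
    """Grid of proportional interval-cancer incidence (percent).

    ``data`` columns: feature, delta, sensitivity (float or the string
    ``"estimated"``), ie_percent (unrounded), ie_rounded (integer display
    value, half-away-from-zero).
    """

    data: pd.DataFrame

    def validate_monotonicity(self) -> None:
        """I/E must rise with the interval and fall with sensitivity."""
        df = self.data[self.data["sensitivity"] != "estimated"]
        for (f, s), grp in df.groupby(["feature", "sensitivity"]):
            vals = grp.sort_values("delta")["ie_percent"].to_numpy()
            if np.any(np.diff(vals) < 0):
                raise ValueError(f"I/E not non-decreasing in delta for {f}, S={s}")
        for (f, d), grp in df.groupby(["feature", "delta"]):
            g = grp.assign(s=grp["sensitivity"].astype(float)).sort_values("s")
            if np.any(np.diff(g["ie_percent"].to_numpy()) > 0):
                raise ValueError(f"I/E not non-increasing in S for {f}, delta={d}")

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot_table(
            index=["delta", "sensitivity"], columns="feature",
            values="ie_rounded", aggfunc="first", sort=False,
        )


def build_ie_table(
    params: ParamSet,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    sensitivities: Sequence[float | str] = DEFAULT_SENSITIVITIES,
    method: str = "closed_form",
    n_sim: int = 1_000_000,
    seed: int | None = None,
) -> IETable:
    """Evaluate the I/E grid over features x intervals x sensitivities.

    ``sensitivities`` may include the string ``"estimated"``, which takes
    each feature's fitted sensitivity from ``params``.  ``method`` is
    ``"closed_form"`` or ``"simulation"`` (renewal Monte Carlo, requires
    ``seed``).
    """
    if method not in ("closed_form", "simulation"):
        raise ValueError(f"unknown method {method!r}")
    if method == "simulation" and seed is None:
        raise ValueError("simulation method requires an explicit seed")
    rng = np.random.default_rng(seed) if method == "simulation" else None
    rows = []
    for s_spec in sensitivities:
        for delta in deltas:
            for feature, p in params.items():
                s = p.sensitivity if s_spec == "estimated" else float(s_spec)
                if method == "closed_form":
                    val = ie_closed_form(p.mst(), s, delta)
                else:
                    val = simulate_renewal_ie(p.mst(), s, delta, n_sim, rng)
                rows.append({
                    "feature": FeatureClass(feature).value,
                    "delta": float(delta),
                    "sensitivity": s_spec if s_spec == "estimated" else float(s_spec),
                    "ie_percent": 100.0 * val,
                    "ie_rounded": round_half_away(100.0 * val),
                })
    table = IETable(pd.DataFrame(rows))
    if method == "closed_form":
        table.validate_monotonicity()
    return table


def policy_threshold_search(
    params: ParamSet,
    criterion: float,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    tol: float = 1e-6,
) -> dict[float, dict]:
    """Minimal sensitivity meeting an I/E criterion, per interval.

    For each interval the worst-case (largest-I/E) feature binds; the
    minimal S with max_f I/E(f, S, delta) <= criterion is found by
    bisection (I/E is strictly decreasing in S).  ``criterion`` is a
    percentage in (0, 100).  Infeasible intervals report the binding
    feature instead of an S.
    """
    if not (0.0 < criterion < 100.0):
        raise ValueError("criterion must be a percentage in (0, 100)")
    target = criterion / 100.0
    out: dict[float, dict] = {}
    for delta in deltas:
        def worst(s: float) -> tuple[float, FeatureClass]:
            vals = {f: ie_closed_form(p.mst(), s, delta) for f, p in params.items()}
            f_bind = max(vals, key=vals.get)
            return vals[f_bind], f_bind

        at_one, bind = worst(1.0)
        if at_one > target:
            out[float(delta)] = {"feasible": False, "binding_feature": bind.value}
            continue
        lo, hi = 0.0, 1.0   # worst(lo) >= target >= worst(hi)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if worst(mid)[0] > target:
                lo = mid
            else:
                hi = mid
        out[float(delta)] = {"feasible": True, "min_sensitivity": hi}
    return out
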