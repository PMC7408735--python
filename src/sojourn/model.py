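"""Fitting the natural-history model to screening histories.

`ScreeningHistoryModel` is built from a :class:`~sojourn.likelihood.Cohort`
and fits a (lambda1, lambda2, S) triple per feature stratum, working on
the unconstrained scale (log lambda1, log lambda2, logit S).  Two fitting
routes are provided:

* ``fit()`` — maximum likelihood (L-BFGS-B), Wald 95% intervals from the
  observed information on the transformed scale;
* ``fit_mcmc()`` — component-wise random-walk Metropolis with proposal
  scales adapted during burn-in only (frozen afterwards, preserving
  detailed balance); point estimate = posterior median, intervals =
  posterior percentiles.

Sensitivity and lambda2 are only weakly jointly identified from the
screen-detected / interval split; the fitter flags flat sensitivity
curvature in the diagnostics rather than failing.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .likelihood import Cohort, CompiledCohort, cohort_log_likelihood
from .natural_history import FeatureClass, NaturalHistoryParams

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "ScreeningHistoryModel",
    "ScreeningFitResults",
    "ScreeningMCMCResults",
    "fit_mle",
    "fit_mcmc",
    "sensitivity_adjusted_mst",
]

_PARAM_NAMES = ("lambda1", "lambda2", "sensitivity")
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors on the transformed scale.

    Normal priors on log lambda1 and log lambda2 (mean, sd) and a
    Beta(a, b) prior on S (default uniform).  The sampler works in
    y = logit S, so the Beta density carries its Jacobian S(1-S).
    """

    log_lambda1: tuple[float, float] = (0.0, 10.0)
    log_lambda2: tuple[float, float] = (0.0, 10.0)
    sensitivity_beta: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.log_lambda1[1] <= 0 or self.log_lambda2[1] <= 0:
            raise ValueError("prior sds must be positive")
        if min(self.sensitivity_beta) <= 0:
            raise ValueError("Beta prior parameters must be positive")

    def logpdf_transformed(self, x1: float, x2: float, y: float) -> float:
        """Log prior density at (log lam1, log lam2, logit S)."""
        m1, s1 = self.log_lambda1
        m2, s2 = self.log_lambda2
        a, b = self.sensitivity_beta
        lp = -0.5 * ((x1 - m1) / s1) ** 2 - math.log(s1)
        lp += -0.5 * ((x2 - m2) / s2) ** 2 - math.log(s2)
        # Beta(a,b) on S plus Jacobian dS/dy = S(1-S)
        logS = -np.logaddexp(0.0, -y)
        log1mS = -np.logaddexp(0.0, y)
        lp += (a - 1.0) * logS + (b - 1.0) * log1mS + logS + log1mS
        return float(lp)


@dataclass(frozen=True)
class ChainConfig:
    """Metropolis chain settings (spec'd defaults; scale down for tests)."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    n_chains: int = 4
    initial_scale: float = 0.3
    adapt_window: int = 100
    target_acceptance: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_iter, self.burn_in, self.thin, self.n_chains) <= 0:
            raise ValueError("chain config entries must be positive")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


def _to_unconstrained(p: NaturalHistoryParams, fix_s: bool) -> np.ndarray:
    v = [math.log(p.lambda1), math.log(p.lambda2)]
    if not fix_s:
        v.append(special.logit(min(p.sensitivity, 1.0 - 1e-12)))
    return np.array(v)


class ScreeningHistoryModel:
    """Three-state screening natural-history model for a cohort.

    Parameters
    ----------
    cohort : Cohort
        Validated screening histories (see :mod:`sojourn.likelihood`).
    features : sequence of FeatureClass, optional
        Strata to fit; defaults to every feature observed in the cohort.
    fix_sensitivity : mapping, optional
        Feature -> fixed S value (e.g. ``{f: 1.0}`` for a perfect-test
        fit); fixed sensitivities are excluded from the parameter vector.
    """

    def __init__(
        self,
        cohort: Cohort,
        features: Sequence[FeatureClass] | None = None,
        fix_sensitivity: Mapping[FeatureClass, float] | None = None,
    ):
        self.cohort = cohort
        self.compiled = CompiledCohort(cohort, features)
        self.features = self.compiled.features
        self.fix_sensitivity = {
            FeatureClass(f): float(s) for f, s in (fix_sensitivity or {}).items()
        }
        for f in self.features:
            if self.compiled.n_events.get(f, 0) == 0:
                warnings.warn(
                    f"feature {f.value} has zero cancer events: lambda1 is at "
                    "the boundary and its estimate is not identified",
                    stacklevel=2,
                )
        self._layout: list[tuple[FeatureClass, bool]] = [
            (f, f in self.fix_sensitivity) for f in self.features
        ]
        self.n_params = sum(2 if fixed else 3 for _, fixed in self._layout)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ScreeningHistoryModel":
        from .io import cohort_from_dataframe

        return cls(cohort_from_dataframe(df), **kwargs)

    # -- parameter packing ---------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> dict[FeatureClass, NaturalHistoryParams]:
        out = {}
        pos = 0
        for f, fixed in self._layout:
            lam1 = math.exp(theta[pos]); lam2 = math.exp(theta[pos + 1])
            if fixed:
                s = self.fix_sensitivity[f]; pos += 2
            else:
                s = float(special.expit(theta[pos + 2])); pos += 3
            out[f] = NaturalHistoryParams(lam1, lam2, max(s, 1e-12),
                                          period_label=self.cohort.period_label)
        return out

    def _pack(self, params: Mapping[FeatureClass, NaturalHistoryParams]) -> np.ndarray:
        return np.concatenate([
            _to_unconstrained(params[f], fixed) for f, fixed in self._layout
        ])

    def loglike(self, theta: np.ndarray) -> float:
        params = self._unpack(np.asarray(theta, dtype=float))
        total = 0.0
        for i, f in enumerate(self.features):
            p = params[f]
            total += self.compiled.loglik_feature(i, p.lambda1, p.lambda2, p.sensitivity)
        return total

    def _default_start(self) -> np.ndarray:
        """Moment-flavoured start: crude incidence for lambda1, MST 3 y, S 0.85."""
        py = max(self.cohort.person_years, 1.0)
        theta = []
        for f, fixed in self._layout:
            rate = max(self.compiled.n_events.get(f, 0), 0.5) / py
            theta += [math.log(rate), math.log(1.0 / 3.0)]
            if not fixed:
                theta.append(special.logit(0.85))
        return np.array(theta)

    # -- maximum likelihood --------------------------------------------------

    def fit(
        self,
        start: Mapping[FeatureClass, NaturalHistoryParams] | None = None,
        gtol: float = 1e-9,
        maxiter: int = 1000,
    ) -> "ScreeningFitResults":
        """Maximise the cohort log-likelihood; Wald intervals from the
        observed information on the transformed scale (delta method via
        the monotone maps exp / expit)."""
        x0 = self._pack(start) if start is not None else self._default_start()
        # per-record objective: convergence tolerances independent of n
        n = max(self.compiled.n_records, 1)
        nll = lambda th: -self.loglike(th) / n
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-13},
        )
        hess = _numerical_hessian(nll, res.x)
        cov = _safe_inverse(hess) / n
        return ScreeningFitResults(
            model=self, theta=res.x, cov=cov, loglike=-res.fun * n,
            converged=bool(res.success), optimizer_message=str(res.message),
        )

    # -- MCMC ----------------------------------------------------------------

    def fit_mcmc(
        self,
        seed: int,
        prior: PriorSpec | None = None,
        chain_config: ChainConfig | None = None,
        start: Mapping[FeatureClass, NaturalHistoryParams] | None = None,
    ) -> "ScreeningMCMCResults":
        """Component-wise random-walk Metropolis on the transformed scale.

        The seed is required explicitly; with a fixed seed and config the
        draws are bit-identical.  Proposal scales are tuned toward
        20-40% acceptance during burn-in and frozen afterwards.
        """
        if seed is None:
            raise ValueError("an explicit seed is required")
        prior = prior or PriorSpec()
        cfg = chain_config or ChainConfig()
        x0 = self._pack(start) if start is not None else self._default_start()

        def log_post(theta: np.ndarray) -> float:
            ll = self.loglike(theta)
            if not math.isfinite(ll):
                return -math.inf
            pos = 0
            lp = ll
            for f, fixed in self._layout:
                if fixed:
                    x1, x2 = theta[pos], theta[pos + 1]
                    m1, s1 = prior.log_lambda1
                    m2, s2 = prior.log_lambda2
                    lp += (-0.5 * ((x1 - m1) / s1) ** 2 - math.log(s1)
                           - 0.5 * ((x2 - m2) / s2) ** 2 - math.log(s2))
                    pos += 2
                else:
                    lp += prior.logpdf_transformed(theta[pos], theta[pos + 1], theta[pos + 2])
                    pos += 3
            return lp

        lp0 = log_post(x0)
        if not math.isfinite(lp0):
            bad = self._param_labels()[0]
            raise ValueError(
                f"non-finite posterior at initialization (first parameter {bad})"
            )

        rng = np.random.default_rng(seed)
        d = self.n_params
        chains, acc_rates = [], []
        for _ in range(cfg.n_chains):
            draws, acc = _metropolis_chain(log_post, x0.copy(), lp0, cfg, d, rng)
            chains.append(draws)
            acc_rates.append(acc)
        draws = np.vstack(chains)
        acc_rate = np.mean(acc_rates, axis=0)
        diagnostics = {
            "acceptance_rate": acc_rate.tolist(),
            "ess": [float(_ess(draws[:, j])) for j in range(d)],
            "n_chains": cfg.n_chains,
            "n_draws": int(draws.shape[0]),
        }
        if np.any(acc_rate < 0.1) or np.any(acc_rate > 0.6):
            warnings.warn(
                "post-adaptation acceptance rate outside [0.1, 0.6] for some "
                f"component: {np.round(acc_rate, 3).tolist()}", stacklevel=2,
            )
        return ScreeningMCMCResults(
            model=self, draws_transformed=draws, diagnostics=diagnostics,
            prior=prior, chain_config=cfg, seed=seed,
        )

    def _param_labels(self) -> list[str]:
        labels = []
        for f, fixed in self._layout:
            labels += [f"lambda1[{f.value}]", f"lambda2[{f.value}]"]
            if not fixed:
                labels.append(f"sensitivity[{f.value}]")
        return labels


def _metropolis_chain(log_post, x, lp, cfg: ChainConfig, d: int,
                      rng: np.random.Generator):
    scales = np.full(d, cfg.initial_scale)
    acc_window = np.zeros(d)
    acc_post = np.zeros(d)
    kept = []
    n_post = cfg.n_iter - cfg.burn_in
    for it in range(cfg.n_iter):
        for j in range(d):
            prop = x.copy()
            prop[j] += scales[j] * rng.standard_normal()
            lp_prop = log_post(prop)
            if math.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                acc_window[j] += 1
                if it >= cfg.burn_in:
                    acc_post[j] += 1
        if it < cfg.burn_in and (it + 1) % cfg.adapt_window == 0:
            rate = acc_window / cfg.adapt_window
            scales *= np.exp(rate - cfg.target_acceptance)
            acc_window[:] = 0.0
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            kept.append(x.copy())
    return np.array(kept), acc_post / max(n_post, 1)


def _ess(x: np.ndarray) -> float:
    """Effective sample size, initial-positive-sequence autocovariance sum."""
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov


# ---------------------------------------------------------------------------
# results objects


class _ResultsBase:
    """Shared reporting surface: per-parameter frame, MST, summary table."""

    model: ScreeningHistoryModel

    def params_frame(self) -> pd.DataFrame:
        raise NotImplementedError

    def natural_history_params(self) -> dict[FeatureClass, NaturalHistoryParams]:
        df = self.params_frame()
        out = {}
        for f in self.model.features:
            row = df.loc[df["feature"] == f.value].set_index("parameter")["estimate"]
            out[f] = NaturalHistoryParams(
                row["lambda1"], row["lambda2"], row["sensitivity"],
                period_label=self.model.cohort.period_label,
            )
        return out

    def mst(self, feature: FeatureClass) -> tuple[float, tuple[float, float]]:
        """Sensitivity-adjusted MST (point, 95% interval): reciprocal of the
        lambda2 summaries, endpoints swapped (monotone decreasing map)."""
        feature = FeatureClass(feature)
        df = self.params_frame()
        row = df[(df["feature"] == feature.value) & (df["parameter"] == "lambda2")]
        if row.empty:
            raise KeyError(f"feature {feature.value} not in fit")
        est = 1.0 / row["estimate"].iloc[0]
        lo, hi = row["ci_low"].iloc[0], row["ci_high"].iloc[0]
        return est, (1.0 / hi, 1.0 / lo)

    def summary(self) -> str:
        df = self.params_frame().copy()
        lines = [
            f"{type(self).__name__}: {len(self.model.cohort)} women, "
            f"{len(self.model.cohort.cancers())} cancers, "
            f"features: {', '.join(f.value for f in self.model.features)}",
            f"{'parameter':<34}{'estimate':>12}{'95% low':>12}{'95% high':>12}",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['parameter'] + '[' + r['feature'] + ']':<34}"
                f"{r['estimate']:>12.5g}{r['ci_low']:>12.5g}{r['ci_high']:>12.5g}"
            )
        for f in self.model.features:
            est, (lo, hi) = self.mst(f)
            lines.append(
                f"{'MST[' + f.value + '] (years)':<34}{est:>12.4g}{lo:>12.4g}{hi:>12.4g}"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        df = self.params_frame()
        payload = {
            "parameters": df.to_dict(orient="records"),
            "mst": {
                f.value: {"estimate": self.mst(f)[0],
                          "ci": list(self.mst(f)[1])}
                for f in self.model.features
            },
        }
        payload.update(self._provenance())
        return json.dumps(payload, indent=2)

    def _provenance(self) -> dict:
        return {}


@dataclass
class ScreeningFitResults(_ResultsBase):
    """Maximum-likelihood results with observed-information intervals."""

    model: ScreeningHistoryModel
    theta: np.ndarray
    cov: np.ndarray
    loglike: float
    converged: bool
    optimizer_message: str = ""

    #: transformed-scale SE above which sensitivity is flagged weakly identified
    FLAT_SENSITIVITY_SE = 5.0

    def __post_init__(self) -> None:
        se = np.sqrt(np.maximum(np.diag(self.cov), 0.0))
        self._se = se
        self.diagnostics = {"interval_method": "observed-information (Wald, transformed scale)"}
        labels = self.model._param_labels()
        flat = [
            lab for lab, s in zip(labels, se)
            if lab.startswith("sensitivity") and (s > self.FLAT_SENSITIVITY_SE or s == 0.0)
        ]
        if flat:
            self.diagnostics["weakly_identified"] = flat
            warnings.warn(
                f"flat sensitivity profile (weak identification): {flat}", stacklevel=2
            )
        if not self.converged:
            warnings.warn(f"optimizer did not converge: {self.optimizer_message}",
                          stacklevel=2)

    def params_frame(self) -> pd.DataFrame:
        rows = []
        pos = 0
        for f, fixed in self.model._layout:
            for name in _PARAM_NAMES:
                if name == "sensitivity" and fixed:
                    rows.append({
                        "feature": f.value, "parameter": name,
                        "estimate": self.model.fix_sensitivity[f],
                        "ci_low": self.model.fix_sensitivity[f],
                        "ci_high": self.model.fix_sensitivity[f], "fixed": True,
                    })
                    continue
                x = self.theta[pos]; s = self._se[pos]
                lo_t, hi_t = x - _Z95 * s, x + _Z95 * s
                tf = special.expit if name == "sensitivity" else np.exp
                rows.append({
                    "feature": f.value, "parameter": name,
                    "estimate": float(tf(x)), "ci_low": float(tf(lo_t)),
                    "ci_high": float(tf(hi_t)), "fixed": False,
                })
                pos += 1
        return pd.DataFrame(rows)

    def _provenance(self) -> dict:
        return {
            "method": "mle",
            "loglike": self.loglike,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }


@dataclass
class ScreeningMCMCResults(_ResultsBase):
    """Posterior draws and percentile intervals from Metropolis sampling."""

    model: ScreeningHistoryModel
    draws_transformed: np.ndarray
    diagnostics: dict
    prior: PriorSpec
    chain_config: ChainConfig
    seed: int

    @property
    def draws(self) -> pd.DataFrame:
        """Draws on the natural scale (rates per person-year, S as probability)."""
        cols = {}
        pos = 0
        for f, fixed in self.model._layout:
            cols[f"lambda1[{f.value}]"] = np.exp(self.draws_transformed[:, pos])
            cols[f"lambda2[{f.value}]"] = np.exp(self.draws_transformed[:, pos + 1])
            if fixed:
                pos += 2
            else:
                cols[f"sensitivity[{f.value}]"] = special.expit(
                    self.draws_transformed[:, pos + 2]
                )
                pos += 3
        return pd.DataFrame(cols)

    def quantiles(self, probs: Sequence[float]) -> pd.DataFrame:
        return self.draws.quantile(list(probs))

    def params_frame(self) -> pd.DataFrame:
        d = self.draws
        rows = []
        for f, fixed in self.model._layout:
            for name in _PARAM_NAMES:
                col = f"{name}[{f.value}]"
                if name == "sensitivity" and fixed:
                    sfix = self.model.fix_sensitivity[f]
                    rows.append({"feature": f.value, "parameter": name,
                                 "estimate": sfix, "ci_low": sfix,
                                 "ci_high": sfix, "fixed": True})
                    continue
                x = d[col].to_numpy()
                rows.append({
                    "feature": f.value, "parameter": name,
                    "estimate": float(np.median(x)),
                    "ci_low": float(np.percentile(x, 2.5)),
                    "ci_high": float(np.percentile(x, 97.5)), "fixed": False,
                })
        return pd.DataFrame(rows)

    def _provenance(self) -> dict:
        return {
            "method": "mcmc",
            "seed": self.seed,
            "prior": {
                "log_lambda1": list(self.prior.log_lambda1),
                "log_lambda2": list(self.prior.log_lambda2),
                "sensitivity_beta": list(self.prior.sensitivity_beta),
            },
            "chain_config": {
                "n_iter": self.chain_config.n_iter,
                "burn_in": self.chain_config.burn_in,
                "thin": self.chain_config.thin,
                "n_chains": self.chain_config.n_chains,
            },
            "diagnostics": self.diagnostics,
        }


# ---------------------------------------------------------------------------
# functional wrappers


def fit_mle(cohort: Cohort, features=None, fix_sensitivity=None, **kw) -> ScreeningFitResults:
    return ScreeningHistoryModel(cohort, features, fix_sensitivity).fit(**kw)


def fit_mcmc(cohort: Cohort, seed: int, features=None, fix_sensitivity=None,
             **kw) -> ScreeningMCMCResults:
    return ScreeningHistoryModel(cohort, features, fix_sensitivity).fit_mcmc(seed, **kw)


def sensitivity_adjusted_mst(
    results: _ResultsBase, feature: FeatureClass
) -> tuple[float, tuple[float, float]]:
    """MST with its 95% interval from a joint (lambda2, S) fit.

    The adjustment is that S is *estimated*: fixing S = 1 on the same
    data attributes missed cancers to fast progression and typically
    shortens the apparent MST.  Compare with
    ``ScreeningHistoryModel(cohort, fix_sensitivity={feature: 1.0}).fit()``.
    """
    return results.mst(feature)
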