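"""Benchmark-dose analysis for continuous, decreasing dose-response data.

Summary data (per-group mean, SD, n) are fit by maximum likelihood under
normal residuals with a common sigma, using the exponential and Hill model
families in their 3- and 4-parameter forms (the standard continuous suites):

    exponential-3:  f(x) = a exp(-b x^d)
    exponential-5:  f(x) = a (c + (1 - c) exp(-b x^d))
    hill-3:         f(x) = a (1 - x^d / (k^d + x^d))
    hill-5:         f(x) = a (1 - (1 - c) x^d / (k^d + x^d))

The benchmark response is a shift of ``magnitude`` background standard
deviations (default 1 SD) below the fitted background f(0); the background SD
is the model residual sigma.  Models are screened by a likelihood-ratio
goodness-of-fit test against the saturated (full group-means) model and the
accepted fits are combined by AIC-weighted model averaging; a parametric
bootstrap over the averaged model set yields the 90% confidence interval
(BMDL = 5th, BMDU = 95th percentile).

Fitting is deterministic: a fixed lattice of starts, doses normalized
internally by the largest dose (which makes the estimates exactly
scale-equivariant), responses by the control mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseData",
    "BMRSpec",
    "BMDModelFit",
    "BMDResult",
    "BMDNotReached",
    "FitFailure",
    "DEFAULT_FAMILIES",
    "fit_model",
    "fit_all",
    "bmd_from_fit",
    "goodness_of_fit",
    "model_average",
    "read_dose_response_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_FAMILIES = ("exponential-3", "exponential-5", "hill-3", "hill-5")

#: Acceptance threshold for the goodness-of-fit p-value.
GOF_ALPHA = 0.05


class BMDNotReached(RuntimeError):
    """The fitted curve never declines by the benchmark response."""


class FitFailure(RuntimeError):
    """No optimization start converged for a model family."""


@dataclass(frozen=True)
class DoseResponseData:
    """Continuous summary dose-response data for a decreasing endpoint."""

    doses: np.ndarray  # mg/kg
    means: np.ndarray  # % of control response
    sds: np.ndarray
    ns: np.ndarray
    endpoint: str = "ChAT activity"
    direction: str = "decreasing"

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        n = np.asarray(self.ns, dtype=int)
        if not (d.shape == m.shape == s.shape == n.shape) or d.ndim != 1:
            raise ValueError("doses, means, sds, ns must be 1-D of equal length")
        if np.any(d < 0):
            raise ValueError("doses must be >= 0")
        if not np.any(d == 0):
            raise ValueError("a dose-0 control group is required")
        if np.any(s <= 0):
            raise ValueError("group SDs must be > 0")
        if np.any(n < 2):
            raise ValueError("group n must be >= 2")
        if self.direction != "decreasing":
            raise ValueError("only decreasing endpoints are supported")
        order = np.argsort(d, kind="stable")
        for name, arr in zip(("doses", "means", "sds", "ns"), (d, m, s, n)):
            object.__setattr__(self, name, arr[order])

    @property
    def n_groups(self) -> int:
        return self.doses.size

    @property
    def control_sd(self) -> float:
        return float(self.sds[self.doses == 0][0])


@dataclass(frozen=True)
class BMRSpec:
    """Benchmark response: a decrease of ``magnitude`` background SDs."""

    magnitude: float = 1.0
    type: str = "sd"
    direction: str = "decreasing"

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ValueError("BMR magnitude must be > 0")
        if self.type != "sd":
            raise ValueError("only SD-based BMR is supported")


# ---------------------------------------------------------------------------
# model families (internal scale: x in [0, 1], y near 1)
# ---------------------------------------------------------------------------

# parameter layout per family: (names, curve fn, bounds, n_curve_params)
_LN_B_BOUNDS = (-16.0, 7.0)
_D_BOUNDS = (1.0, 4.0)
_C_BOUNDS = (0.0, 0.999)


def _lnx(x):
    # ln(x) with the x = 0 entries masked (their derivative terms vanish)
    with np.errstate(divide="ignore"):
        return np.where(x > 0, np.log(np.maximum(x, 1e-300)), 0.0)


def _exp3(theta, x, grad=False):
    a, lnb, d = theta
    xd = x**d
    e = np.exp(-np.exp(lnb) * xd)
    f = a * e
    if not grad:
        return f
    bxd = np.exp(lnb) * xd
    return f, np.stack([e, -f * bxd, -f * bxd * _lnx(x)])


def _exp5(theta, x, grad=False):
    a, lnb, c, d = theta
    xd = x**d
    e = np.exp(-np.exp(lnb) * xd)
    f = a * (c + (1.0 - c) * e)
    if not grad:
        return f
    bxd = np.exp(lnb) * xd
    t = a * (1.0 - c) * e
    return f, np.stack([f / a, -t * bxd, a * (1.0 - e), -t * bxd * _lnx(x)])


def _hill3(theta, x, grad=False):
    a, lnk, d = theta
    xd = x**d
    kd = np.exp(lnk) ** d
    h = xd / (kd + xd)
    f = a * (1.0 - h)
    if not grad:
        return f
    hh = h * (1.0 - h)
    return f, np.stack([1.0 - h, a * d * hh, -a * hh * (_lnx(x) - lnk)])


def _hill5(theta, x, grad=False):
    a, lnk, c, d = theta
    xd = x**d
    kd = np.exp(lnk) ** d
    h = xd / (kd + xd)
    f = a * (1.0 - (1.0 - c) * h)
    if not grad:
        return f
    hh = (1.0 - c) * h * (1.0 - h)
    return f, np.stack([f / a, a * d * hh, a * h, -a * hh * (_lnx(x) - lnk)])


_FAMILY_DEFS: dict[str, dict] = {
    "exponential-3": {
        "fn": _exp3,
        "names": ("a", "ln_b", "d"),
        "bounds": [(0.2, 5.0), _LN_B_BOUNDS, _D_BOUNDS],
    },
    "exponential-5": {
        "fn": _exp5,
        "names": ("a", "ln_b", "c", "d"),
        "bounds": [(0.2, 5.0), _LN_B_BOUNDS, _C_BOUNDS, _D_BOUNDS],
    },
    "hill-3": {
        "fn": _hill3,
        "names": ("a", "ln_k", "d"),
        "bounds": [(0.2, 5.0), (-9.0, 4.0), _D_BOUNDS],
    },
    "hill-5": {
        "fn": _hill5,
        "names": ("a", "ln_k", "c", "d"),
        "bounds": [(0.2, 5.0), (-9.0, 4.0), _C_BOUNDS, _D_BOUNDS],
    },
}


def _starts(family: str) -> list[np.ndarray]:
    """The documented deterministic multi-start lattice (10 starts/family)."""
    defs = _FAMILY_DEFS[family]
    lnbs = np.linspace(-4.0, 3.0, 5)  # potency scale on normalized doses
    starts = []
    for d0 in (1.0, 2.0):
        for lnb in lnbs:
            if len(defs["names"]) == 3:
                starts.append(np.array([1.0, lnb, d0]))
            else:
                starts.append(np.array([1.0, lnb, 0.3, d0]))
    return starts


@dataclass(frozen=True)
class BMDModelFit:
    """A converged maximum-likelihood fit of one model family."""

    family: str
    params: dict[str, float]  # natural-scale curve parameters
    sigma: float  # residual SD, response units
    loglik: float
    aic: float
    gof_p: float | None
    gof_df: int
    bmd_point: float | None  # mg/kg; None if the curve never reaches the BMR
    n_curve_params: int
    xscale: float
    yscale: float
    theta_internal: np.ndarray  # optimizer coordinates, kept for warm starts
    converged: bool = True

    def predict(self, doses: np.ndarray) -> np.ndarray:
        """Fitted mean response at the given doses (natural scale)."""
        x = np.asarray(doses, dtype=float) / self.xscale
        return self.yscale * _FAMILY_DEFS[self.family]["fn"](self.theta_internal, x)

    @property
    def accepted(self) -> bool:
        return self.gof_p is not None and self.gof_p > GOF_ALPHA


def _neg_profile_loglik(
    theta: np.ndarray, fn: Callable, x: np.ndarray, m: np.ndarray,
    s2n1: np.ndarray, n: np.ndarray,
) -> tuple[float, np.ndarray]:
    f, jac = fn(theta, x, grad=True)
    resid = m - f
    ss = float(np.sum(s2n1 + n * resid**2))
    ntot = n.sum()
    if not np.isfinite(ss) or ss <= 0:
        return np.inf, np.zeros_like(theta)
    grad = -(ntot / ss) * (jac @ (n * resid))
    return 0.5 * ntot * math.log(ss), grad


def _loglik_from_ss(ss: float, n_total: int) -> float:
    sigma2 = ss / n_total
    return -0.5 * n_total * (math.log(2.0 * math.pi * sigma2) + 1.0)


def fit_model(
    data: DoseResponseData,
    family: str,
    starts: Sequence[np.ndarray] | None = None,
) -> BMDModelFit:
    """Maximum-likelihood fit of one family to summary data.

    The likelihood is built from group means, SDs and n under normal
    residuals with a common sigma (sigma profiled out analytically).
    Deterministic: a fixed lattice of starts, best final likelihood wins,
    ties by first-found.
    """
    if family not in _FAMILY_DEFS:
        raise ValueError(f"unknown family {family!r}; known: {sorted(_FAMILY_DEFS)}")
    if data.n_groups < 3:
        raise ValueError("need >= 3 dose groups including control")
    defs = _FAMILY_DEFS[family]
    xscale = float(data.doses.max())
    yscale = float(data.means[data.doses == 0][0])
    if xscale <= 0 or yscale <= 0:
        raise ValueError("max dose and control mean must be > 0")
    x = data.doses / xscale
    m = data.means / yscale
    s2n1 = (data.ns - 1) * (data.sds / yscale) ** 2
    n = data.ns.astype(float)

    best = None
    for theta0 in starts if starts is not None else _starts(family):
        res = optimize.minimize(
            _neg_profile_loglik,
            theta0,
            args=(defs["fn"], x, m, s2n1, n),
            method="L-BFGS-B",
            jac=True,
            bounds=defs["bounds"],
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise FitFailure(f"{family}: no optimization start converged")

    theta = best.x
    n_total = int(n.sum())
    f = defs["fn"](theta, x)
    ss = float(np.sum(s2n1 + n * (m - f) ** 2))
    sigma = yscale * math.sqrt(ss / n_total)
    loglik = _loglik_from_ss(ss, n_total) - n_total * math.log(yscale)
    k = len(defs["names"]) + 1  # curve params + sigma
    aic = 2.0 * k - 2.0 * loglik

    # natural-scale parameters
    params: dict[str, float] = {}
    for name, val in zip(defs["names"], theta):
        if name == "a":
            params[name] = float(val * yscale)
        elif name == "ln_b":
            d = theta[-1]
            params["b"] = float(np.exp(val) / xscale**d)
        elif name == "ln_k":
            params["k"] = float(np.exp(val) * xscale)
        else:
            params[name] = float(val)

    fit = BMDModelFit(
        family=family,
        params=params,
        sigma=sigma,
        loglik=loglik,
        aic=aic,
        gof_p=None,
        gof_df=data.n_groups - len(defs["names"]),
        bmd_point=None,
        n_curve_params=len(defs["names"]),
        xscale=xscale,
        yscale=yscale,
        theta_internal=theta,
    )
    p = goodness_of_fit(fit, data)
    try:
        bmd = bmd_from_fit(fit, BMRSpec(), fit.sigma)
    except BMDNotReached:
        bmd = None
    return BMDModelFit(
        **{**fit.__dict__, "gof_p": p, "bmd_point": bmd}
    )


def goodness_of_fit(fit: BMDModelFit, data: DoseResponseData) -> float:
    """Likelihood-ratio test of the fit against the saturated means model.

    The statistic 2(logL_full - logL_model) is referred to chi-square with
    (n_groups - n_curve_params) degrees of freedom.  With no degrees of
    freedom left the test is undefined; the model then passes only if it
    interpolates the group means (p reported as 1), else it is rejected.
    """
    yscale = fit.yscale
    m = data.means / yscale
    s2n1 = (data.ns - 1) * (data.sds / yscale) ** 2
    n = data.ns.astype(float)
    n_total = int(n.sum())
    f = fit.predict(data.doses) / yscale
    ss_model = float(np.sum(s2n1 + n * (m - f) ** 2))
    ss_full = float(np.sum(s2n1))
    stat = n_total * math.log(ss_model / ss_full)
    df = data.n_groups - fit.n_curve_params
    if df <= 0:
        return 1.0 if stat <= n_total * math.log(1.0 + 1e-9) else 0.0
    return float(stats.chi2.sf(max(stat, 0.0), df))


def bmd_from_fit(
    fit: BMDModelFit, bmr: BMRSpec, background_sd: float
) -> float:
    """Smallest positive dose at which f(0) - f(x) equals the BMR.

    Solved by bracketing and Brent's method to relative tolerance 1e-8.
    Raises :class:`BMDNotReached` if the decline is not attained within
    10x the largest observed dose.
    """
    if background_sd <= 0:
        raise ValueError("background SD must be > 0")
    delta = bmr.magnitude * background_sd
    f0 = float(fit.predict(np.array([0.0]))[0])

    def g(x: float) -> float:
        return f0 - float(fit.predict(np.array([x]))[0]) - delta

    hi = 10.0 * fit.xscale
    if g(hi) < 0:
        raise BMDNotReached(
            f"{fit.family}: response never declines by {delta:g} within {hi:g} mg/kg"
        )
    lo = 0.0
    # expand a positive lower bracket for brentq
    x = hi
    while g(x) > 0 and x > 1e-12 * fit.xscale:
        hi = x
        x /= 2.0
    lo = x
    root = optimize.brentq(g, lo, hi, rtol=1e-9, xtol=1e-15)
    return float(root)


def fit_all(
    data: DoseResponseData, families: Iterable[str] = DEFAULT_FAMILIES
) -> list[BMDModelFit]:
    """Fit every family; failed fits are logged and excluded."""
    fits = []
    for family in families:
        try:
            fits.append(fit_model(data, family))
        except FitFailure as exc:
            logger.warning("fit failure: %s", exc)
    return fits


# ---------------------------------------------------------------------------
# model averaging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BMDResult:
    """Model-averaged benchmark dose with its 90% bootstrap interval."""

    bmd: float  # mg/kg
    bmdl: float  # 5th percentile
    bmdu: float  # 95th percentile
    weights: dict[str, float]
    fits: tuple[BMDModelFit, ...]
    n_boot: int
    seed: int
    n_failed_replicates: int = 0
    warning: str | None = None

    def __post_init__(self) -> None:
        if not self.bmdl <= self.bmd <= self.bmdu:
            raise ValueError("bmdl <= bmd <= bmdu violated")

    def per_model_table(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append(
                {
                    "family": f.family,
                    "params": ";".join(f"{k}={v:.6g}" for k, v in f.params.items()),
                    "sigma": f.sigma,
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "gof_p": f.gof_p,
                    "bmd_point": f.bmd_point,
                    "weight": self.weights.get(f.family, 0.0),
                }
            )
        return pd.DataFrame(rows)


def _aic_weights(fits: Sequence[BMDModelFit]) -> np.ndarray:
    aic = np.array([f.aic for f in fits])
    w = np.exp(-0.5 * (aic - aic.min()))
    return w / w.sum()


def _averaged_bmd(
    fits: Sequence[BMDModelFit],
    bmr: BMRSpec,
    background_sd: dict[str, float] | None = None,
) -> tuple[float, np.ndarray]:
    """AIC-weight-averaged BMD on the log scale over fits that reach the BMR.

    ``background_sd`` maps family -> SD used for the BMR; by default each
    fit's own residual sigma is used.
    """
    w = _aic_weights(fits)
    bmds = []
    for f in fits:
        sd = background_sd.get(f.family, f.sigma) if background_sd else f.sigma
        try:
            bmds.append(bmd_from_fit(f, bmr, sd))
        except BMDNotReached:
            bmds.append(np.nan)
    bmds = np.array(bmds)
    ok = np.isfinite(bmds)
    if not ok.any():
        raise BMDNotReached("no fitted model reaches the benchmark response")
    wok = w[ok] / w[ok].sum()
    return float(np.exp(np.sum(wok * np.log(bmds[ok])))), w


def model_average(
    fits: Sequence[BMDModelFit],
    data: DoseResponseData,
    bmr: BMRSpec = BMRSpec(),
    n_boot: int = 1000,
    seed: int = 0,
) -> BMDResult:
    """AIC-weighted model averaging with a parametric bootstrap 90% interval.

    Each bootstrap replicate draws the generating family with probability
    equal to its AIC weight, resamples group means (normal, sigma/sqrt(n))
    and group SDs (scaled chi-square) from that fit, refits every accepted
    family warm-started from the original estimates, and records the
    weight-averaged BMD; BMDL/BMDU are the 5th/95th percentiles of the
    replicate distribution.
    """
    accepted = list(fits)  # the caller passes the accepted set
    if not accepted:
        raise ValueError("no accepted fits to average")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")

    bmd, w = _averaged_bmd(accepted, bmr)
    weights = {f.family: float(wi) for f, wi in zip(accepted, w)}
    # the background SD defining the BMR is held at the original estimates
    # across bootstrap replicates (the BMR is a property of the observed
    # study, not of each resample)
    background = {f.family: f.sigma for f in accepted}

    rng = np.random.default_rng(seed)
    reps: list[float] = []
    n_failed = 0
    families = [f.family for f in accepted]
    warm = {f.family: [f.theta_internal] for f in accepted}
    for _ in range(n_boot):
        gen = accepted[rng.choice(len(accepted), p=w)]
        f_mean = gen.predict(data.doses)
        means = rng.normal(f_mean, gen.sigma / np.sqrt(data.ns))
        sds = gen.sigma * np.sqrt(
            rng.chisquare(data.ns - 1) / (data.ns - 1)
        )
        try:
            data_b = DoseResponseData(
                doses=data.doses, means=means, sds=sds, ns=data.ns,
                endpoint=data.endpoint,
            )
            fits_b = []
            for fam in families:
                try:
                    fits_b.append(fit_model(data_b, fam, starts=warm[fam]))
                except FitFailure:
                    continue
            if not fits_b:
                raise FitFailure("no family converged in replicate")
            bmd_b, _ = _averaged_bmd(fits_b, bmr, background)
            reps.append(bmd_b)
        except (FitFailure, BMDNotReached, ValueError):
            n_failed += 1
    if not reps:
        raise FitFailure("all bootstrap replicates failed")
    warning = None
    if n_failed > 0.2 * n_boot:
        warning = f"{n_failed}/{n_boot} bootstrap replicates failed"
        logger.warning(warning)

    reps_arr = np.array(reps)
    bmdl = float(np.percentile(reps_arr, 5.0))
    bmdu = float(np.percentile(reps_arr, 95.0))
    # the point estimate is kept inside the interval (can escape by a hair
    # when the bootstrap distribution is extremely tight)
    bmdl, bmdu = min(bmdl, bmd), max(bmdu, bmd)
    return BMDResult(
        bmd=bmd,
        bmdl=bmdl,
        bmdu=bmdu,
        weights=weights,
        fits=tuple(fits),
        n_boot=n_boot,
        seed=seed,
        n_failed_replicates=n_failed,
        warning=warning,
    )


def read_dose_response_csv(path: str | Path) -> DoseResponseData:
    """Read a dose-response CSV with columns dose, mean, sd, n."""
    df = pd.read_csv(path)
    required = ["dose", "mean", "sd", "n"]
    if list(df.columns)[: len(required)] != required:
        raise ValueError(f"expected leading columns {required}, got {list(df.columns)}")
    return DoseResponseData(
        doses=df["dose"].to_numpy(float),
        means=df["mean"].to_numpy(float),
        sds=df["sd"].to_numpy(float),
        ns=df["n"].to_numpy(int),
    )
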