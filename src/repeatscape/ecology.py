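"""Rank-abundance/dominance models and diversity statistics.

A genome is treated as an ecological community: TE families are
species and individual TE copies (or the reads supporting them) are
individuals.  Five classical RAD models are fitted to the ranked
abundance vector by maximum likelihood and compared by BIC:

=============  ====================================  ==========
model          expected abundance at rank r          parameters
=============  ====================================  ==========
Null           (J/S) * sum_{x=r}^{S} 1/x             0
Preemption     J * alpha * (1-alpha)^(r-1)           1
Lognormal      exp(mu + sigma * Phi^-1((S-r+.5)/S))  2
Zipf           J * p * r^gamma                       2
Mandelbrot     J * c * (r+beta)^gamma                3
=============  ====================================  ==========

All models share a Poisson log-likelihood sum(a_r ln e_r - e_r) with
the ln(a_r!) constant dropped; since the constant is identical across
models it cancels in every BIC comparison.  BIC = -2 loglik + k ln S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODEL_K = {"Null": 0, "Preemption": 1, "Lognormal": 2, "Zipf": 2, "Mandelbrot": 3}
_EPS = 1e-9


@dataclass
class AbundanceVector:
    """Family abundances ranked in descending order.

    Counts may be fractional (e.g. genome fractions scaled to reads per
    million); ties in counts take ranks in family-label order.
    """

    families: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.size == 0:
            raise ValueError("abundance vector is empty")
        if np.any(counts <= 0):
            raise ValueError("all abundances must be positive")
        order = sorted(range(len(counts)), key=lambda i: (-counts[i], self.families[i]))
        self.families = [self.families[i] for i in order]
        self.counts = counts[order]

    @classmethod
    def from_mapping(cls, mapping) -> "AbundanceVector":
        items = list(mapping.items())
        return cls([k for k, _ in items], np.array([v for _, v in items], float))

    @property
    def J(self) -> float:
        return float(self.counts.sum())

    @property
    def S(self) -> int:
        return len(self.counts)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, self.S + 1)


@dataclass
class RADFit:
    model: str
    parameters: dict[str, float]
    expected: np.ndarray
    loglik: float
    converged: bool = True
    diagnostic: str = ""

    @property
    def k(self) -> int:
        return MODEL_K[self.model]

    @property
    def bic(self) -> float:
        S = len(self.expected)
        return -2.0 * self.loglik + self.k * math.log(S)


@dataclass
class DiversityStats:
    H: float
    E: float  # NaN when S == 1
    richness: int


def poisson_loglik(observed: np.ndarray, expected: np.ndarray) -> float:
    """sum(a_r ln e_r - e_r); the ln(a_r!) constant is dropped."""
    expected = np.maximum(expected, _EPS)
    return float(np.sum(observed * np.log(expected) - expected))


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def expected_null(J: float, S: int) -> np.ndarray:
    """Brokenstick expectation (J/S) * sum_{x=r}^{S} 1/x for r = 1..S."""
    if S < 1 or J < 0:
        raise ValueError("need S >= 1 and J >= 0")
    inv = 1.0 / np.arange(1, S + 1)
    tail = np.cumsum(inv[::-1])[::-1]  # tail[r-1] = sum_{x=r}^{S} 1/x
    return (J / S) * tail


def fit_null(vec: AbundanceVector) -> RADFit:
    expected = expected_null(vec.J, vec.S)
    return RADFit("Null", {}, expected, poisson_loglik(vec.counts, expected))


def fit_preemption(vec: AbundanceVector) -> RADFit:
    """Geometric-series model: rank r takes J * alpha * (1-alpha)^(r-1)."""
    if vec.S < 2:
        raise ValueError("preemption fit needs S >= 2")
    J, r = vec.J, vec.ranks

    def nll(alpha: float) -> float:
        e = J * alpha * (1 - alpha) ** (r - 1)
        return -poisson_loglik(vec.counts, e)

    res = optimize.minimize_scalar(
        nll, bounds=(1e-9, 1 - 1e-9), method="bounded",
        options={"xatol": 1e-12},
    )
    alpha = float(res.x)
    expected = J * alpha * (1 - alpha) ** (r - 1)
    return RADFit("Preemption", {"alpha": alpha}, expected, -float(res.fun),
                  converged=bool(res.success))


def _lognormal_expected(mu: float, sigma: float, S: int) -> np.ndarray:
    z = stats.norm.ppf((S - np.arange(1, S + 1) + 0.5) / S)
    # clamp the exponent so optimizer excursions cannot overflow
    return np.exp(np.clip(mu + sigma * z, -700.0, 700.0))


def fit_lognormal(vec: AbundanceVector) -> RADFit:
    """Lognormal RAD via (S - r + 0.5)/S plotting-position quantiles."""
    if vec.S < 3:
        raise ValueError("lognormal fit needs S >= 3")
    S = vec.S
    logc = np.log(vec.counts)

    def nll(theta: np.ndarray) -> float:
        mu, logsig = theta
        return -poisson_loglik(vec.counts, _lognormal_expected(mu, np.exp(logsig), S))

    best = None
    sig0 = max(float(np.std(logc, ddof=0)), 1e-3)
    for mu0, s0 in [(float(np.mean(logc)), sig0),
                    (float(np.mean(logc)), 1.0),
                    (float(np.median(logc)), 0.5),
                    (float(np.mean(logc)) + 1.0, sig0),
                    (float(np.mean(logc)) - 1.0, 2.0)]:
        res = optimize.minimize(
            nll, x0=[mu0, np.log(s0)], method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = float(best.x[0]), float(np.exp(best.x[1]))
    expected = _lognormal_expected(mu, sigma, S)
    return RADFit("Lognormal", {"mu": mu, "sigma": sigma}, expected,
                  -float(best.fun), converged=bool(best.success))


def fit_zipf(vec: AbundanceVector) -> RADFit:
    """Power-law model a_r = J * p * r^gamma with p in (0, 1]."""
    if vec.S < 3:
        raise ValueError("Zipf fit needs S >= 3")
    J, r = vec.J, vec.ranks.astype(float)
    logr = np.log(r)

    def nll(theta: np.ndarray) -> float:
        logp, gamma = theta
        e = J * np.exp(np.clip(logp + gamma * logr, -700.0, 700.0))
        return -poisson_loglik(vec.counts, e)

    # least-squares line on the log-log RAD plot as the primary start
    slope, intercept = np.polyfit(logr, np.log(vec.counts / J), 1)
    starts = [(min(intercept, -1e-9), slope),
              (np.log(vec.counts[0] / J), slope),
              (np.log(max(vec.counts[0] / J, 1e-6)), -1.0),
              (-1.0, -0.5), (-0.5, -2.0)]
    best = None
    for logp0, g0 in starts:
        res = optimize.minimize(
            nll, x0=[logp0, g0], method="L-BFGS-B",
            bounds=[(-50.0, 0.0), (-25.0, 25.0)],
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    p, gamma = float(np.exp(best.x[0])), float(best.x[1])
    expected = J * p * r ** gamma
    return RADFit("Zipf", {"p": p, "gamma": gamma}, expected, -float(best.fun),
                  converged=bool(best.success))


def fit_mandelbrot(vec: AbundanceVector) -> RADFit:
    """Zipf-Mandelbrot a_r = J * c * (r+beta)^gamma with beta > -1.

    The Zipf solution (beta = 0) is always among the starting points,
    so the fitted likelihood can never fall below Zipf's.
    """
    if vec.S < 4:
        raise ValueError("Mandelbrot fit needs S >= 4")
    J, r = vec.J, vec.ranks.astype(float)
    zipf = fit_zipf(vec)

    def nll(theta: np.ndarray) -> float:
        logc, beta, gamma = theta
        e = J * np.exp(np.clip(logc + gamma * np.log(r + beta), -700.0, 700.0))
        return -poisson_loglik(vec.counts, e)

    z0 = (math.log(zipf.parameters["p"]), 0.0, zipf.parameters["gamma"])
    starts = [z0,
              (z0[0], 1.0, z0[2]),
              (z0[0], 5.0, 2 * z0[2]),
              (z0[0], 10.0, 2 * z0[2]),
              (0.0, 0.5, -1.0),
              (1.0, 5.0, -2.0)]
    best = None
    for s in starts:
        res = optimize.minimize(
            nll, x0=list(s), method="L-BFGS-B",
            bounds=[(-50.0, 50.0), (-1 + 1e-6, 1e6), (-25.0, 25.0)],
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    # never report worse than the nested Zipf optimum
    if -best.fun < zipf.loglik:
        c, beta, gamma = zipf.parameters["p"], 0.0, zipf.parameters["gamma"]
        return RADFit("Mandelbrot", {"c": c, "beta": beta, "gamma": gamma},
                      zipf.expected.copy(), zipf.loglik,
                      converged=False, diagnostic="fell back to Zipf optimum")
    c, beta, gamma = float(np.exp(best.x[0])), float(best.x[1]), float(best.x[2])
    expected = J * c * (r + beta) ** gamma
    return RADFit("Mandelbrot", {"c": c, "beta": beta, "gamma": gamma}, expected,
                  -float(best.fun), converged=bool(best.success))


_FITTERS = {
    "Null": fit_null,
    "Preemption": fit_preemption,
    "Lognormal": fit_lognormal,
    "Zipf": fit_zipf,
    "Mandelbrot": fit_mandelbrot,
}


def select_model(
    vec: Union[AbundanceVector, Sequence[float], dict],
) -> list[RADFit]:
    """Fit every applicable model and rank ascending by BIC.

    Models whose sample-size preconditions fail are skipped.  Raises if
    every fit fails, listing per-model diagnostics.
    """
    if isinstance(vec, dict):
        vec = AbundanceVector.from_mapping(vec)
    elif not isinstance(vec, AbundanceVector):
        arr = np.asarray(vec, dtype=float)
        vec = AbundanceVector([f"F{i}" for i in range(len(arr))], arr)
    fits: list[RADFit] = []
    failures: dict[str, str] = {}
    for name, fitter in _FITTERS.items():
        try:
            fits.append(fitter(vec))
        except Exception as exc:  # noqa: BLE001
            failures[name] = str(exc)
    if not fits:
        raise RuntimeError(f"all RAD fits failed: {failures}")
    return sorted(fits, key=lambda f: f.bic)


def simulate_rad(
    model: str,
    params: dict[str, float],
    S: int,
    J: float = 10_000.0,
    seed: int = 0,
) -> np.ndarray:
    """Poisson counts around a RAD model's expected rank abundances.

    Ranks whose draw is zero are dropped (an unobserved family is not
    part of the community), so the returned vector may be shorter than
    ``S``.  Supported models: Null, Preemption, Lognormal, Zipf,
    Mandelbrot (parameters as in the corresponding fitters; Lognormal
    ignores ``J``).
    """
    r = np.arange(1, S + 1)
    if model == "Null":
        expected = expected_null(J, S)
    elif model == "Preemption":
        a = params["alpha"]
        expected = J * a * (1 - a) ** (r - 1)
    elif model == "Lognormal":
        expected = _lognormal_expected(params["mu"], params["sigma"], S)
    elif model == "Zipf":
        expected = J * params["p"] * r ** params["gamma"]
    elif model == "Mandelbrot":
        expected = J * params["c"] * (r + params["beta"]) ** params["gamma"]
    else:
        raise ValueError(f"unknown RAD model {model!r}")
    counts = np.random.default_rng(seed).poisson(expected)
    return counts[counts > 0].astype(float)


def fit_summary(fits: Sequence[RADFit]) -> pd.DataFrame:
    rows = [
        {"model": f.model, "k": f.k, "loglik": f.loglik, "bic": f.bic,
         **{f"param_{k}": v for k, v in f.parameters.items()}}
        for f in fits
    ]
    df = pd.DataFrame(rows)
    df["delta_bic"] = df["bic"] - df["bic"].min()
    return df


def diversity(vec: Union[AbundanceVector, Sequence[float], dict]) -> DiversityStats:
    """Shannon diversity H (natural log), evenness E = H/ln S, richness S."""
    if isinstance(vec, dict):
        vec = AbundanceVector.from_mapping(vec)
    elif not isinstance(vec, AbundanceVector):
        arr = np.asarray(vec, dtype=float)
        vec = AbundanceVector([f"F{i}" for i in range(len(arr))], arr)
    p = vec.counts / vec.J
    H = float(-np.sum(p * np.log(p)))
    if vec.S == 1:
        return DiversityStats(H=0.0, E=float("nan"), richness=1)
    return DiversityStats(H=H, E=H / math.log(vec.S), richness=vec.S)
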