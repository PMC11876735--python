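"""Sum-of-exponentials kinetics: fitting, half-lives, and TIACs.

Time-activity curves f(t) = sum_i a_i exp(-lambda_i t) (fractions of
injected activity, effective rates in 1/h) are fitted by unweighted least
squares with multi-start variable projection: for trial rates the
amplitudes are solved linearly, and the rates are refined numerically.
Three candidate shapes are supported —

* ``monoexp``:          one term, a >= 0;
* ``biexp``:            two washout terms, both a >= 0;
* ``uptake-washout``:   two terms with exactly one negative amplitude and
                        f(0) >= 0, modeling organs (typically kidneys) whose
                        uptake peaks near 24 h before washing out.

The winner among the requested candidates is the fit with the smallest
AICc.  The terminal effective half-life is ln2 / min(rates); a fit whose
terminal half-life exceeds the physical half-life is flagged (noise can
push it there) but not rejected.

The time-integrated activity coefficient (TIAC, historically the residence
time) is the integral of f over all time: analytically sum(a_i/lambda_i)
for a fitted model, or a trapezoid over the observed samples plus an
analytic tail for the hybrid estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .constants import LU177, PhysicalConstants
from .errors import ConfigurationError, FittingError

__all__ = [
    "KineticFit",
    "fit_time_activity",
    "tiac_analytic",
    "tiac_hybrid",
    "MODELS",
]

MODELS = ("monoexp", "biexp", "uptake-washout")
_N_TERMS = {"monoexp": 1, "biexp": 2, "uptake-washout": 2}


@dataclass
class KineticFit:
    """A fitted sum-of-exponentials model.

    Rates are stored in ascending order, so ``rates[0]`` is the terminal
    (slowest) rate and ``amplitudes[0]`` its amplitude.
    """

    model: str
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    sse: float
    aicc: float
    n_samples: int
    terminal_effective_half_life: float = 0.0
    tiac: float = 0.0
    superphysical_flag: bool = False
    physical_half_life: float = LU177.physical_half_life

    def __post_init__(self) -> None:
        if len(self.amplitudes) != len(self.rates) or not self.rates:
            raise ValueError("amplitudes and rates must have equal, nonzero length")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be strictly positive")
        order = np.argsort(self.rates)
        self.rates = tuple(float(self.rates[i]) for i in order)
        self.amplitudes = tuple(float(self.amplitudes[i]) for i in order)
        self.terminal_effective_half_life = math.log(2.0) / self.rates[0]
        self.tiac = float(
            sum(a / r for a, r in zip(self.amplitudes, self.rates))
        )
        self.superphysical_flag = (
            self.terminal_effective_half_life > self.physical_half_life
        )

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a = np.asarray(self.amplitudes)
        lam = np.asarray(self.rates)
        return a @ np.exp(-np.outer(lam, t))


def _amplitudes_for_rates(
    t: np.ndarray, y: np.ndarray, lam: np.ndarray, w: np.ndarray, model: str
) -> np.ndarray | None:
    """Profiled amplitudes for fixed rates (variable projection step)."""
    E = np.exp(-np.outer(t, lam)) * w[:, None]
    yw = y * w
    if model in ("monoexp", "biexp"):
        a, _ = optimize.nnls(E, yw)
        return a
    # uptake-washout: amplitudes free, sign pattern validated by caller
    a, *_ = np.linalg.lstsq(E, yw, rcond=None)
    return a


def _valid_amplitudes(a: np.ndarray, model: str) -> bool:
    if model == "uptake-washout":
        return int(np.sum(a < 0)) == 1 and float(np.sum(a)) >= -1e-12
    return bool(np.all(a >= 0))


def _sse_for_logrates(
    loglam: np.ndarray, t: np.ndarray, y: np.ndarray, w: np.ndarray, model: str
) -> float:
    lam = np.exp(loglam)
    if lam.size > 1 and abs(loglam[0] - loglam[1]) < 1e-6:
        return np.inf  # degenerate: coincident rates
    a = _amplitudes_for_rates(t, y, lam, w, model)
    resid = (y - a @ np.exp(-np.outer(lam, t))) * w
    return float(resid @ resid)


def _fit_one_model(
    model: str,
    t: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    n_starts: int,
    rng: np.random.Generator,
    constants: PhysicalConstants,
) -> tuple[np.ndarray, np.ndarray, float] | None:
    n_terms = _N_TERMS[model]
    lo, hi = math.log(constants.decay_constant / 10.0), math.log(10.0)
    grid = np.linspace(lo, hi, max(n_starts, 4))
    starts: list[np.ndarray] = []
    if n_terms == 1:
        starts = [np.array([g]) for g in grid[:n_starts]]
    else:
        # deterministic spread of rate pairs plus seeded random pairs
        for i in range(0, len(grid) - 1, 2):
            starts.append(np.array([grid[i], grid[min(i + len(grid) // 2, len(grid) - 1)]]))
        while len(starts) < n_starts:
            starts.append(rng.uniform(lo, hi, size=2))
        starts = starts[:n_starts]

    best: tuple[float, np.ndarray] | None = None
    for x0 in starts:
        res = optimize.minimize(
            _sse_for_logrates,
            x0,
            args=(t, y, w, model),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x)
    if best is None:
        return None
    lam = np.exp(best[1])
    a = _amplitudes_for_rates(t, y, lam, w, model)
    if a is None or not _valid_amplitudes(a, model):
        return None
    resid = (y - a @ np.exp(-np.outer(lam, t))) * w
    return a, lam, float(resid @ resid)


def _aicc(sse: float, n: int, k: int, yscale: float) -> float:
    if n <= k + 1:
        return np.inf
    # floor the SSE at a numerical-resolution scale so that on noiseless data
    # nested models compare by parameter count, not by round-off residuals
    sse = max(sse, n * (1e-8 * max(yscale, 1e-30)) ** 2)
    return n * math.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_time_activity(
    times: Sequence[float],
    fractions: Sequence[float],
    candidate_models: Sequence[str] = MODELS,
    weights: str | None = None,
    n_starts: int = 20,
    seed: int = 0,
    constants: PhysicalConstants = LU177,
) -> KineticFit:
    """Fit candidate exponential models and select by AICc.

    Parameters
    ----------
    times, fractions:
        Strictly increasing times [h] and measured fractions of injected
        activity.
    candidate_models:
        Subset of ``{"monoexp", "biexp", "uptake-washout"}``.
    weights:
        ``None`` for unweighted least squares (default) or ``"1/y"``.
    n_starts:
        Multi-start count over a log-spaced rate grid spanning
        [lambda_phys/10, 10 /h].

    Candidates with fewer samples than free parameters are skipped with a
    warning; if every candidate fails a :class:`FittingError` is raised.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need >=2 paired (time, fraction) samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    unknown = set(candidate_models) - set(MODELS)
    if unknown:
        raise ConfigurationError(f"unknown candidate models: {sorted(unknown)}")
    if weights is None:
        w = np.ones_like(y)
    elif weights == "1/y":
        w = 1.0 / np.sqrt(np.maximum(np.abs(y), 1e-12))
    else:
        raise ConfigurationError(f"unknown weighting scheme {weights!r}")

    rng = np.random.default_rng(seed)
    fits: list[KineticFit] = []
    for model in candidate_models:
        k = 2 * _N_TERMS[model]
        if t.size < k:
            warnings.warn(
                f"model {model!r} skipped: {t.size} samples < {k} parameters",
                stacklevel=2,
            )
            continue
        result = _fit_one_model(model, t, y, w, n_starts, rng, constants)
        if result is None:
            continue
        a, lam, sse = result
        fits.append(
            KineticFit(
                model=model,
                amplitudes=tuple(a),
                rates=tuple(lam),
                sse=sse,
                aicc=_aicc(sse, t.size, k, float(np.max(np.abs(y)))),
                n_samples=int(t.size),
                physical_half_life=constants.physical_half_life,
            )
        )
    if not fits:
        raise FittingError(
            f"no candidate model among {tuple(candidate_models)} could be fitted"
        )
    finite = [f for f in fits if np.isfinite(f.aicc)]
    pool = finite if finite else fits
    return min(pool, key=lambda f: (f.aicc, f.sse))


def tiac_analytic(fit: KineticFit) -> float:
    """Analytic TIAC tau = sum(a_i / lambda_i) of a fitted model [h]."""
    if any(r <= 0 for r in fit.rates):
        raise ValueError("all rates must be strictly positive")
    return float(sum(a / r for a, r in zip(fit.amplitudes, fit.rates)))


def tiac_hybrid(
    times: Sequence[float],
    fractions: Sequence[float],
    tail_rule: str = "physical-decay",
    fit: KineticFit | None = None,
    constants: PhysicalConstants = LU177,
) -> float:
    """Hybrid TIAC: trapezoid over the observed samples plus an analytic tail.

    The tail extends the last sample to infinity, either at the physical
    decay rate (``tail_rule="physical-decay"``: f_last / lambda_phys — the
    conservative choice when the terminal phase is poorly determined) or at
    the fitted terminal rate (``tail_rule="terminal-fit"``, requiring
    ``fit``).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need >=2 samples for the hybrid TIAC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    body = float(np.trapezoid(y, t))
    if tail_rule == "physical-decay":
        tail = float(y[-1]) / constants.decay_constant
    elif tail_rule == "terminal-fit":
        if fit is None:
            raise ConfigurationError("tail_rule='terminal-fit' requires a KineticFit")
        tail = float(y[-1]) / fit.rates[0]
    else:
        raise ConfigurationError(f"unknown tail rule {tail_rule!r}")
    return body + tail
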