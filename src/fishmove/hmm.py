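"""Two-state bivariate-normal hidden Markov model with informative priors.

The daily observation x_t = (h_t, v_t) — log horizontal and log vertical
movement — is modelled as a 2-state HMM. State R ("resident") has low
movement rates, state M ("migrating") high ones. The latent sequence S_1..S_T
follows a first-order Markov chain with transition matrix

    Gamma = [[g_RR, 1 - g_RR],
             [1 - g_MM, g_MM]],

initial distribution fixed uniform, and state-conditional emissions
x_t | S_t = j ~ MVN(mu_j, Sigma_j) with

    mu_j = (mu_jH, mu_jV),
    Sigma_j = [[s_jH^2, r_j s_jH s_jV], [r_j s_jH s_jV, s_jV^2]].

Twelve free parameters per fish: two self-transition probabilities plus five
emission parameters per state. Estimation is maximum a posteriori: the
forward-algorithm log-likelihood plus

* a Beta(alpha, beta) prior on each self-transition probability (default
  Beta(99, 1), prior mean 0.99, i.e. an expected dwell of 100 days) that
  makes states track seasonal shifts rather than day-to-day noise;
* optionally, independent Gaussian priors N(m_jd, delta_jd) on the four state
  means (delta is a *variance*), built from data-rich fish and used to anchor
  state identity when refitting data-poor tracks.

Numerical maximisation runs on an unconstrained transform (logit for gamma,
identity for mu, log for sigma, Fisher-z for rho) with multiple jittered
restarts; decoding uses forward–backward smoothing followed by per-day argmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, ndtr, ndtri

from .io import MovementPath, StateError, UsageError

try:  # jitted recursions; pure-python fallback keeps the module importable
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


RESIDENT, MIGRATING = 0, 1
STATE_NAMES = ("R", "M")

#: Smoothed-probability threshold below which a day's classification is
#: reported as uncertain.
UNCERTAINTY_THRESHOLD = 0.85

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class HMMParameters:
    """The 12 free parameters of one fish's model.

    ``mu``, ``sigma`` are (2, 2) arrays indexed [state, dimension] with state
    order (R, M) and dimension order (H, V); ``rho`` is length-2 per state.
    The initial distribution ``omega`` is fixed uniform and never estimated.
    """

    gamma_rr: float
    gamma_mm: float
    mu: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray

    omega = np.array([0.5, 0.5])

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(2, 2)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(2, 2)
        self.rho = np.asarray(self.rho, dtype=float).reshape(2)
        if not (0.0 < self.gamma_rr < 1.0 and 0.0 < self.gamma_mm < 1.0):
            raise ValueError("self-transition probabilities must lie in (0, 1)")
        if np.any(self.sigma <= 0.0) or np.any(np.abs(self.rho) >= 1.0):
            raise ValueError("sigma must be > 0 and |rho| < 1 (positive-definite Sigma)")

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.gamma_rr, 1.0 - self.gamma_rr],
                [1.0 - self.gamma_mm, self.gamma_mm],
            ]
        )

    def covariance(self, j: int) -> np.ndarray:
        sh, sv = self.sigma[j]
        c = self.rho[j] * sh * sv
        return np.array([[sh * sh, c], [c, sv * sv]])

    def swapped(self) -> "HMMParameters":
        """Parameters with the two state labels exchanged."""
        return HMMParameters(
            self.gamma_mm, self.gamma_rr, self.mu[::-1].copy(), self.sigma[::-1].copy(),
            self.rho[::-1].copy(),
        )


@dataclass
class TransitionPrior:
    """Beta(alpha, beta) prior on each self-transition probability."""

    alpha: float = 99.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def expected_dwell_days(self) -> float:
        """Expected dwell 1/(1 - prior mean self-transition)."""
        return 1.0 / (1.0 - self.mean)

    def logpdf(self, g: float) -> float:
        if not 0.0 < g < 1.0:
            raise ValueError("gamma outside (0, 1)")
        lognorm = gammaln(self.alpha + self.beta) - gammaln(self.alpha) - gammaln(self.beta)
        return float(lognorm + (self.alpha - 1.0) * math.log(g) + (self.beta - 1.0) * math.log1p(-g))


@dataclass
class MeanPriors:
    """Gaussian priors N(m_jd, delta_jd) on the four state means of one species.

    ``m`` and ``delta`` are (2, 2) arrays [state, dimension] on the log scale;
    delta is a variance.
    """

    m: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float).reshape(2, 2)
        self.delta = np.asarray(self.delta, dtype=float).reshape(2, 2)
        if np.any(self.delta <= 0):
            raise ValueError("prior variances delta must be positive")
        if not self.m[RESIDENT, 0] < self.m[MIGRATING, 0]:
            raise ValueError("resident prior horizontal mean must be below migrating")

    def logpdf(self, mu: np.ndarray) -> float:
        z = (np.asarray(mu) - self.m) ** 2 / self.delta
        return float(-0.5 * np.sum(z + np.log(2.0 * np.pi * self.delta)))

    def scaled(self, factor: float) -> "MeanPriors":
        """Same prior means, all variances multiplied by ``factor``."""
        return MeanPriors(self.m.copy(), self.delta * factor)


@dataclass
class FitConfig:
    n_restarts: int = 10
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-9  # L-BFGS-B ftol (relative)
    sigma_floor: float = 1e-3
    #: extra starting points (HMMParameters) tried before the jittered ones,
    #: e.g. a baseline fit when re-running a sensitivity scenario
    extra_initials: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise UsageError("n_restarts must be >= 1")


@dataclass
class FittedModel:
    """MAP fit of one movement path: parameters, smoothing, decoding."""

    path: MovementPath
    params: HMMParameters
    log_posterior: float
    converged: bool
    smoothed: np.ndarray | None = None  # (T, 2) P(S_t = j | x_{1:T})
    states: np.ndarray | None = None  # (T,) in {0 (R), 1 (M)}
    uncertain: np.ndarray | None = None  # (T,) bool
    n_restarts_converged: int = 0

    @property
    def T(self) -> int:
        return len(self.path)

    def state_fraction(self, j: int) -> float:
        if self.states is None:
            raise StateError("fit not decoded")
        return float(np.mean(self.states == j))


# ---------------------------------------------------------------------------
# Emission densities
# ---------------------------------------------------------------------------


def emission_logdensity(x, j: int, p: HMMParameters) -> float:
    """Log bivariate-normal density of observation ``x=(h, v)`` under state j."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite observation")
    lb = _emission_logb(x.reshape(-1, 2)[:, 0], x.reshape(-1, 2)[:, 1], p)
    return float(lb[0, j])


def _emission_logb(h: np.ndarray, v: np.ndarray, p: HMMParameters) -> np.ndarray:
    """(T, 2) matrix of state-conditional log emission densities."""
    out = np.empty((h.size, 2))
    for j in range(2):
        sh, sv = p.sigma[j]
        r = p.rho[j]
        zh = (h - p.mu[j, 0]) / sh
        zv = (v - p.mu[j, 1]) / sv
        om = 1.0 - r * r
        quad = (zh * zh - 2.0 * r * zh * zv + zv * zv) / om
        out[:, j] = -LOG2PI - math.log(sh * sv) - 0.5 * math.log(om) - 0.5 * quad
    return out


# ---------------------------------------------------------------------------
# Forward / backward recursions (jitted)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _forward_kernel(logb, g_rr, g_mm):  # pragma: no cover - exercised via wrappers
    """Scaled forward recursion. Returns (loglik, filtered (T,2))."""
    T = logb.shape[0]
    filt = np.empty((T, 2))
    m = max(logb[0, 0], logb[0, 1])
    a0 = 0.5 * math.exp(logb[0, 0] - m)
    a1 = 0.5 * math.exp(logb[0, 1] - m)
    c = a0 + a1
    ll = math.log(c) + m
    a0 /= c
    a1 /= c
    filt[0, 0] = a0
    filt[0, 1] = a1
    for t in range(1, T):
        p0 = a0 * g_rr + a1 * (1.0 - g_mm)
        p1 = a0 * (1.0 - g_rr) + a1 * g_mm
        m = max(logb[t, 0], logb[t, 1])
        b0 = math.exp(logb[t, 0] - m)
        b1 = math.exp(logb[t, 1] - m)
        a0 = p0 * b0
        a1 = p1 * b1
        c = a0 + a1
        ll += math.log(c) + m
        a0 /= c
        a1 /= c
        filt[t, 0] = a0
        filt[t, 1] = a1
    return ll, filt


@njit(cache=False)
def _backward_smooth_kernel(logb, g_rr, g_mm, filt):  # pragma: no cover
    """Normalised backward pass; returns smoothed (T,2) from filtered probs."""
    T = logb.shape[0]
    sm = np.empty((T, 2))
    b0 = 0.5
    b1 = 0.5
    sm[T - 1, 0] = filt[T - 1, 0]
    sm[T - 1, 1] = filt[T - 1, 1]
    for t in range(T - 2, -1, -1):
        m = max(logb[t + 1, 0], logb[t + 1, 1])
        e0 = math.exp(logb[t + 1, 0] - m) * b0
        e1 = math.exp(logb[t + 1, 1] - m) * b1
        nb0 = g_rr * e0 + (1.0 - g_rr) * e1
        nb1 = (1.0 - g_mm) * e0 + g_mm * e1
        c = nb0 + nb1
        b0 = nb0 / c
        b1 = nb1 / c
        w0 = filt[t, 0] * b0
        w1 = filt[t, 1] * b1
        s = w0 + w1
        sm[t, 0] = w0 / s
        sm[t, 1] = w1 / s
    return sm


def forward_loglik(path: MovementPath, p: HMMParameters) -> float:
    """Marginal log-likelihood via the (scaled) forward algorithm."""
    if len(path) < 1:
        raise UsageError("empty path")
    logb = _emission_logb(path.h, path.v, p)
    ll, _ = _forward_kernel(logb, p.gamma_rr, p.gamma_mm)
    return float(ll)


def smooth_states(path: MovementPath, p: HMMParameters) -> np.ndarray:
    """Forward–backward smoothed state probabilities P(S_t = j | x_{1:T})."""
    logb = _emission_logb(path.h, path.v, p)
    _, filt = _forward_kernel(logb, p.gamma_rr, p.gamma_mm)
    return _backward_smooth_kernel(logb, p.gamma_rr, p.gamma_mm, filt)


def allocate_states(
    smoothed: np.ndarray, threshold: float = UNCERTAINTY_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day argmax state allocation with uncertainty flags.

    Ties go to the resident state; a day is flagged uncertain when the winning
    smoothed probability falls below ``threshold``.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    states = (smoothed[:, MIGRATING] > smoothed[:, RESIDENT]).astype(np.int8)
    uncertain = smoothed.max(axis=1) < threshold
    return states, uncertain


# ---------------------------------------------------------------------------
# Posterior
# ---------------------------------------------------------------------------


def log_posterior(
    path: MovementPath,
    p: HMMParameters,
    tp: TransitionPrior,
    mp: MeanPriors | None = None,
) -> float:
    """Forward log-likelihood plus log prior terms.

    Beta prior terms use the normalised pdf; with alpha = beta = 1 (flat) and
    no mean priors this equals ``forward_loglik`` exactly.
    """
    lp = forward_loglik(path, p)
    lp += tp.logpdf(p.gamma_rr) + tp.logpdf(p.gamma_mm)
    if mp is not None:
        lp += mp.logpdf(p.mu)
    return lp


# ---------------------------------------------------------------------------
# Parameter transform
# ---------------------------------------------------------------------------
# theta = [logit g_RR, logit g_MM, mu_RH, mu_RV, mu_MH, mu_MV,
#          log s_RH, log s_RV, log s_MH, log s_MV, atanh r_R, atanh r_M]

N_PARAMS = 12


def _pack(p: HMMParameters) -> np.ndarray:
    def logit(x):
        return math.log(x / (1.0 - x))

    return np.concatenate(
        [
            [logit(p.gamma_rr), logit(p.gamma_mm)],
            p.mu.ravel(),
            np.log(p.sigma.ravel()),
            np.arctanh(p.rho),
        ]
    )


def _unpack(theta: np.ndarray) -> HMMParameters:
    expit = lambda z: 1.0 / (1.0 + math.exp(-z))
    return HMMParameters(
        expit(theta[0]),
        expit(theta[1]),
        theta[2:6].reshape(2, 2),
        np.exp(theta[6:10]).reshape(2, 2),
        np.tanh(theta[10:12]),
    )


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------


def _initial_params(
    path: MovementPath, tp: TransitionPrior, mp: MeanPriors | None
) -> HMMParameters:
    """Deterministic starting point from data quantiles (or prior means)."""
    if mp is not None:
        mu = mp.m.copy()
    else:
        qlo = np.quantile(path.x, 0.25, axis=0)
        qhi = np.quantile(path.x, 0.75, axis=0)
        mu = np.vstack([qlo, qhi])
    sd = np.maximum(np.std(path.x, axis=0), 0.05)
    sigma = np.vstack([0.75 * sd, 0.75 * sd])
    g0 = float(np.clip(tp.mean, 0.05, 0.99))
    return HMMParameters(g0, g0, mu, sigma, np.zeros(2))


def _jitter(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = theta.copy()
    out[0:2] += rng.normal(0.0, 0.5, 2)
    out[2:6] += rng.normal(0.0, 0.3, 4)
    out[6:10] += rng.normal(0.0, 0.3, 4)
    out[10:12] += rng.normal(0.0, 0.3, 2)
    return out


def fit_map(
    path: MovementPath,
    tp: TransitionPrior | None = None,
    mp: MeanPriors | None = None,
    cfg: FitConfig | None = None,
) -> FittedModel:
    """Fit the 12-parameter model by numerically maximising the log posterior.

    Bounded quasi-Newton (L-BFGS-B) on the unconstrained transform, with
    ``cfg.n_restarts`` jittered starting points (plus any ``extra_initials``);
    the best-posterior restart wins. Deterministic given ``cfg.seed``.

    Label identifiability: without mean priors, states are relabelled after
    optimisation so that R has the smaller horizontal mean (resident = low
    movement); with mean priors the labels are anchored by the priors and no
    reordering happens. The returned fit is decoded (smoothed, allocated).

    A fit is reported ``converged=False`` when every restart fails, or when
    the winner is degenerate: a state's expected occupancy (sum of its
    smoothed probabilities) below 2 days, or a sigma at its lower bound.
    """
    if len(path) < 2:
        raise UsageError("fit_map needs T >= 2")
    tp = tp or TransitionPrior()
    cfg = cfg or FitConfig()
    rng = np.random.default_rng(cfg.seed)
    h, v = path.h, path.v

    def objective(theta: np.ndarray) -> float:
        try:
            p = _unpack(theta)
        except (ValueError, OverflowError):
            return 1e12
        logb = _emission_logb(h, v, p)
        if not np.all(np.isfinite(logb)):
            return 1e12
        ll, _ = _forward_kernel(logb, p.gamma_rr, p.gamma_mm)
        lp = ll + tp.logpdf(p.gamma_rr) + tp.logpdf(p.gamma_mm)
        if mp is not None:
            lp += mp.logpdf(p.mu)
        if not math.isfinite(lp):
            return 1e12
        return -lp

    log_floor = math.log(cfg.sigma_floor)
    bounds = (
        [(-7.0, 7.0)] * 2 + [(-25.0, 25.0)] * 4 + [(log_floor, 8.0)] * 4 + [(-5.0, 5.0)] * 2
    )

    base = _pack(_initial_params(path, tp, mp))
    starts = [_pack(q) for q in cfg.extra_initials]
    starts.append(base)
    while len(starts) < cfg.n_restarts + len(cfg.extra_initials):
        starts.append(_jitter(base, rng))

    best = None
    n_ok = 0
    for theta0 in starts:
        res = minimize(
            objective,
            np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": cfg.max_iter, "ftol": cfg.tol},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            continue
        n_ok += int(res.success)
        if best is None or res.fun < best.fun:
            best = res

    if best is None:
        p = _initial_params(path, tp, mp)
        fit = FittedModel(path, p, -math.inf, converged=False)
        fit.smoothed = smooth_states(path, p)
        fit.states, fit.uncertain = allocate_states(fit.smoothed)
        return fit

    params = _unpack(best.x)
    if mp is None and params.mu[RESIDENT, 0] > params.mu[MIGRATING, 0]:
        params = params.swapped()

    smoothed = smooth_states(path, params)
    states, uncertain = allocate_states(smoothed)
    occupancy = smoothed.sum(axis=0)
    degenerate = (
        occupancy.min() < 2.0
        or np.any(params.sigma <= cfg.sigma_floor * (1.0 + 1e-6))
    )
    fit = FittedModel(
        path,
        params,
        float(-best.fun),
        converged=bool(n_ok > 0 and not degenerate),
        smoothed=smoothed,
        states=states,
        uncertain=uncertain,
        n_restarts_converged=n_ok,
    )
    return fit


# ---------------------------------------------------------------------------
# Pseudo-residuals
# ---------------------------------------------------------------------------


def pseudo_residuals(path: MovementPath, p: HMMParameters) -> np.ndarray:
    """One-step-ahead forecast normal pseudo-residuals, (T, 2) for (h, v).

    For each day and dimension the forecast CDF mixes the state-conditional
    marginal normal CDFs with predictive state weights (the filtered
    distribution propagated one step; the uniform initial distribution at
    t = 1). Under a correct model the residuals are approximately standard
    normal.
    """
    logb = _emission_logb(path.h, path.v, p)
    _, filt = _forward_kernel(logb, p.gamma_rr, p.gamma_mm)
    G = p.transition_matrix
    pred = np.vstack([p.omega, filt[:-1] @ G])  # (T, 2)
    out = np.empty((len(path), 2))
    for d, series in enumerate((path.h, path.v)):
        z = (series[:, None] - p.mu[:, d][None, :]) / p.sigma[:, d][None, :]
        u = np.sum(pred * ndtr(z), axis=1)
        out[:, d] = ndtri(np.clip(u, 1e-12, 1.0 - 1e-12))
    return out


# ---------------------------------------------------------------------------
# Univariate variant (horizontal-only observation model)
# ---------------------------------------------------------------------------


@dataclass
class UnivariateFit:
    """2-state fit using only the horizontal dimension (comparison model)."""

    path: MovementPath
    gamma_rr: float
    gamma_mm: float
    mu: np.ndarray  # (2,)
    sigma: np.ndarray  # (2,)
    log_posterior: float
    converged: bool
    smoothed: np.ndarray | None = None
    states: np.ndarray | None = None


def fit_map_univariate(
    path: MovementPath,
    tp: TransitionPrior | None = None,
    cfg: FitConfig | None = None,
) -> UnivariateFit:
    """MAP fit of the univariate (h-only) observation model.

    Same Markov chain and Beta transition prior as the bivariate model; the
    emission is a univariate normal per state (6 free parameters). Used to
    quantify what the vertical dimension adds to state allocation.
    """
    tp = tp or TransitionPrior()
    cfg = cfg or FitConfig()
    rng = np.random.default_rng(cfg.seed)
    h = path.h

    def make_logb(mu, sig):
        z = (h[:, None] - mu[None, :]) / sig[None, :]
        return -0.5 * (z * z) - np.log(sig)[None, :] - 0.5 * LOG2PI

    def objective(theta):
        g0 = 1.0 / (1.0 + math.exp(-theta[0]))
        g1 = 1.0 / (1.0 + math.exp(-theta[1]))
        mu = theta[2:4]
        sig = np.exp(theta[4:6])
        logb = make_logb(mu, sig)
        if not np.all(np.isfinite(logb)):
            return 1e12
        ll, _ = _forward_kernel(logb, g0, g1)
        lp = ll + tp.logpdf(g0) + tp.logpdf(g1)
        return -lp if math.isfinite(lp) else 1e12

    glogit = math.log(tp.mean / (1.0 - tp.mean)) if 0 < tp.mean < 1 else 3.0
    base = np.array(
        [
            glogit,
            glogit,
            float(np.quantile(h, 0.25)),
            float(np.quantile(h, 0.75)),
            math.log(max(np.std(h) * 0.75, 0.05)),
            math.log(max(np.std(h) * 0.75, 0.05)),
        ]
    )
    bounds = [(-7, 7)] * 2 + [(-25, 25)] * 2 + [(math.log(cfg.sigma_floor), 8.0)] * 2
    best = None
    n_ok = 0
    for i in range(cfg.n_restarts):
        theta0 = base if i == 0 else base + rng.normal(0, 0.3, 6)
        res = minimize(
            objective,
            np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": cfg.max_iter, "ftol": cfg.tol},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            continue
        n_ok += int(res.success)
        if best is None or res.fun < best.fun:
            best = res

    if best is None:
        raise StateError(f"{path.fish_id}: univariate fit failed in all restarts")

    th = best.x
    g0 = 1.0 / (1.0 + math.exp(-th[0]))
    g1 = 1.0 / (1.0 + math.exp(-th[1]))
    mu = th[2:4].copy()
    sig = np.exp(th[4:6])
    if mu[0] > mu[1]:  # resident = low horizontal movement
        mu, sig = mu[::-1].copy(), sig[::-1].copy()
        g0, g1 = g1, g0
    logb = make_logb(mu, sig)
    _, filt = _forward_kernel(logb, g0, g1)
    smoothed = _backward_smooth_kernel(logb, g0, g1, filt)
    states, _ = allocate_states(smoothed)
    return UnivariateFit(
        path, g0, g1, mu, sig, float(-best.fun), n_ok > 0, smoothed, states
    )
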