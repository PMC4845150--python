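"""Joint Gaussian-copula regression of a continuous and a binary channel.

Model
-----
With order ``p`` histories (most-recent-first) of the continuous channel
``y`` and the binary channel ``x``, the two conditional margins are

* continuous:  ``y_t ~ Normal(mu_t, sigma^2)`` with
  ``mu_t = c_y + sum_i a_i y_{t-i} + sum_i b_i x_{t-i}``;
* binary (probit):  ``P(x_t = 1) = Phi(eta_t)`` with
  ``eta_t = c_x + sum_i d_i x_{t-i} + sum_i e_i y_{t-i}``.

Same-bin dependence is carried by a Gaussian copula with correlation ``rho``
through the latent-threshold construction: with ``z = (y_t - mu_t)/sigma``,

    P(x_t = 1 | y_t) = Phi((eta_t + rho z) / sqrt(1 - rho^2)),

which preserves the probit marginal exactly and gives a closed-form,
quadrature-free likelihood.  The first ``p`` bins of each trial condition the
likelihood but contribute no terms, so trials are independent contributions.

Fitting maximizes the joint conditional log-likelihood by L-BFGS with an
analytic gradient, warm-started from least squares (continuous margin) and a
probit Newton solve (binary margin) at ``rho = 0``.  ``sigma`` is optimized
on a log scale and ``rho`` on an arctanh scale so the constraints
``sigma > 0`` and ``|rho| < 1`` are built in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr

__all__ = [
    "JointModel",
    "FitResult",
    "cond_means",
    "mixed_pair_loglik",
    "joint_loglik",
    "continuous_loglik",
    "discrete_loglik",
    "fit",
    "aic",
    "select_order",
    "RESTRICTIONS",
]

_LOG_2PI = math.log(2.0 * math.pi)
RESTRICTIONS = ("full", "no_spike_to_lfp", "no_lfp_to_spike")


@dataclass
class JointModel:
    """Parameters of the joint model at order ``p``."""

    p: int
    c_y: float
    a: np.ndarray  # own-lag coefficients of the continuous mean
    b: np.ndarray  # spike-history -> continuous-mean cross coefficients
    sigma: float
    c_x: float
    d: np.ndarray  # own-lag coefficients of the probit mean
    e: np.ndarray  # continuous-history -> probit cross coefficients
    rho: float

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        if self.p < 1:
            raise ValueError("order p must be >= 1")
        for name, vec in (("a", self.a), ("b", self.b), ("d", self.d), ("e", self.e)):
            if vec.shape != (self.p,):
                raise ValueError(
                    f"coefficient vector {name} has length {vec.size}, expected p={self.p}"
                )
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not abs(self.rho) < 1:
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")

    def to_dict(self) -> dict:
        return {
            "p": self.p,
            "c_y": self.c_y,
            "a": list(self.a),
            "b": list(self.b),
            "sigma": self.sigma,
            "c_x": self.c_x,
            "d": list(self.d),
            "e": list(self.e),
            "rho": self.rho,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointModel":
        return cls(
            p=int(d["p"]),
            c_y=float(d["c_y"]),
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            sigma=float(d["sigma"]),
            c_x=float(d["c_x"]),
            d=np.asarray(d["d"], dtype=float),
            e=np.asarray(d["e"], dtype=float),
            rho=float(d["rho"]),
        )


@dataclass
class FitResult:
    """A fitted model with its likelihood, AIC and diagnostics."""

    model: JointModel
    loglik: float
    k: int
    converged: bool
    n_obs: int
    restriction: str = "full"
    message: str = ""
    se: dict | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k


def save_fit(fr: FitResult, path):
    """Serialize a FitResult as flat key=value text (round-trippable)."""
    m = fr.model
    with open(path, "w") as fh:
        fh.write(f"order={m.p}\n")
        fh.write(f"c_y={float(m.c_y)!r}\n")
        fh.write("a=" + ",".join(repr(float(v)) for v in m.a) + "\n")
        fh.write("b=" + ",".join(repr(float(v)) for v in m.b) + "\n")
        fh.write(f"sigma={float(m.sigma)!r}\n")
        fh.write(f"c_x={float(m.c_x)!r}\n")
        fh.write("d=" + ",".join(repr(float(v)) for v in m.d) + "\n")
        fh.write("e=" + ",".join(repr(float(v)) for v in m.e) + "\n")
        fh.write(f"rho={float(m.rho)!r}\n")
        fh.write(f"loglik={float(fr.loglik)!r}\n")
        fh.write(f"k={fr.k}\n")
        fh.write(f"aic={float(fr.aic)!r}\n")
        fh.write(f"converged={int(fr.converged)}\n")
        fh.write(f"n_obs={fr.n_obs}\n")
        fh.write(f"restriction={fr.restriction}\n")
    return path


def load_fit(path) -> FitResult:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            key, _, val = line.strip().partition("=")
            kv[key] = val
    vec = lambda s: np.asarray([float(v) for v in s.split(",")]) if s else np.array([])
    model = JointModel(
        p=int(kv["order"]),
        c_y=float(kv["c_y"]),
        a=vec(kv["a"]),
        b=vec(kv["b"]),
        sigma=float(kv["sigma"]),
        c_x=float(kv["c_x"]),
        d=vec(kv["d"]),
        e=vec(kv["e"]),
        rho=float(kv["rho"]),
    )
    return FitResult(
        model=model,
        loglik=float(kv["loglik"]),
        k=int(kv["k"]),
        converged=bool(int(kv["converged"])),
        n_obs=int(kv["n_obs"]),
        restriction=kv.get("restriction", "full"),
    )


# ---------------------------------------------------------------------------
# likelihood


def cond_means(model: JointModel, lfp_hist, spk_hist):
    """Conditional means given most-recent-first length-``p`` histories.

    Returns ``(mu_y, eta_x)``; the spike marginal probability is
    ``Phi(eta_x)``.
    """
    lfp_hist = np.asarray(lfp_hist, dtype=float)
    spk_hist = np.asarray(spk_hist, dtype=float)
    if lfp_hist.shape != (model.p,) or spk_hist.shape != (model.p,):
        raise ValueError(
            f"histories must have length p={model.p}, got "
            f"{lfp_hist.shape} and {spk_hist.shape}"
        )
    mu_y = model.c_y + lfp_hist @ model.a + spk_hist @ model.b
    eta_x = model.c_x + spk_hist @ model.d + lfp_hist @ model.e
    return float(mu_y), float(eta_x)


def _loglik_parts(y, x, mu, eta, sigma, rho):
    """Per-observation continuous and conditional-binary log terms."""
    z = (y - mu) / sigma
    ll_y = -0.5 * z * z - math.log(sigma) - 0.5 * _LOG_2PI
    g = (eta + rho * z) / math.sqrt(1.0 - rho * rho)
    s = 2.0 * x - 1.0
    ll_x = log_ndtr(s * g)
    return ll_y, ll_x


def mixed_pair_loglik(model: JointModel, x_t: int, y_t: float, lfp_hist, spk_hist) -> float:
    """Log joint density of one (binary, continuous) pair given histories.

    Equals ``log f(y_t) + log P(X = x_t | y_t)`` where the conditional spike
    probability comes from the Gaussian-copula latent-threshold construction.
    """
    if x_t not in (0, 1):
        raise ValueError(f"x_t must be 0 or 1, got {x_t}")
    mu, eta = cond_means(model, lfp_hist, spk_hist)
    ll_y, ll_x = _loglik_parts(
        float(y_t), float(x_t), mu, eta, model.sigma, model.rho
    )
    return float(ll_y + ll_x)


def _design(ts, p: int, t_start: int | None = None):
    """Stack per-trial lagged regressors for t = t_start .. n_bins-1.

    ``t_start`` defaults to ``p`` (condition on the first ``p`` bins); order
    selection passes the largest candidate order so every candidate's
    likelihood is evaluated on the same observations.  Returns
    ``(y, x, Yh, Xh)`` where ``Yh[:, i-1]`` / ``Xh[:, i-1]`` hold the
    lag-``i`` values (most-recent-first), rows ordered trial-major.
    """
    t_start = p if t_start is None else int(t_start)
    if t_start < p:
        raise ValueError(f"t_start {t_start} smaller than order {p}")
    lfp = ts.lfp
    spk = ts.spikes.astype(float)
    n_bins = ts.n_bins
    if n_bins < t_start + 1:
        raise ValueError(
            f"need at least t_start+1={t_start + 1} bins per trial, got {n_bins}"
        )
    y = lfp[:, t_start:].ravel()
    x = spk[:, t_start:].ravel()
    Yh = np.empty((y.size, p))
    Xh = np.empty((y.size, p))
    for i in range(1, p + 1):
        Yh[:, i - 1] = lfp[:, t_start - i : n_bins - i].ravel()
        Xh[:, i - 1] = spk[:, t_start - i : n_bins - i].ravel()
    return y, x, Yh, Xh


def _check_binary(ts):
    if not ts.is_binary:
        raise ValueError("binary model requires spikes in {0, 1}")


def _eval_terms(model: JointModel, ts):
    y, x, Yh, Xh = _design(ts, model.p)
    mu = model.c_y + Yh @ model.a + Xh @ model.b
    eta = model.c_x + Xh @ model.d + Yh @ model.e
    z = (y - mu) / model.sigma
    ll_y = -0.5 * z * z - math.log(model.sigma) - 0.5 * _LOG_2PI
    g = (eta + model.rho * z) / math.sqrt(1.0 - model.rho * model.rho)
    s = 2.0 * x - 1.0
    ll_x = log_ndtr(s * g)
    return ll_y, ll_x


def joint_loglik(model: JointModel, ts) -> float:
    """Joint conditional log-likelihood over all trials.

    The first ``p`` bins of each trial are conditioning-only.
    """
    _check_binary(ts)
    ll_y, ll_x = _eval_terms(model, ts)
    return float(ll_y.sum() + ll_x.sum())


def continuous_loglik(model: JointModel, ts) -> float:
    """Gaussian AR-with-cross-history margin log-likelihood alone."""
    _check_binary(ts)
    ll_y, _ = _eval_terms(model, ts)
    return float(ll_y.sum())


def discrete_loglik(model: JointModel, ts) -> float:
    """Conditional binary-margin log-likelihood (includes the copula term)."""
    _check_binary(ts)
    _, ll_x = _eval_terms(model, ts)
    return float(ll_x.sum())


# ---------------------------------------------------------------------------
# fitting


class _Problem:
    """Packs free parameters and evaluates the negative log-likelihood with
    its analytic gradient on the unconstrained scale (log sigma, atanh rho)."""

    def __init__(self, ts, p: int, restriction: str, t_start: int | None = None):
        if restriction not in RESTRICTIONS:
            raise ValueError(f"unknown restriction {restriction!r}")
        _check_binary(ts)
        self.p = p
        self.restriction = restriction
        self.y, self.x, self.Yh, self.Xh = _design(ts, p, t_start)
        self.n_obs = self.y.size
        self.use_b = restriction != "no_spike_to_lfp"
        self.use_e = restriction != "no_lfp_to_spike"
        self.s = 2.0 * self.x - 1.0
        # free-parameter count: c_y, a, (b), log sigma, c_x, d, (e), atanh rho
        self.k = 2 + 2 * p + 2 + (p if self.use_b else 0) + (p if self.use_e else 0)

    def pack(self, model: JointModel) -> np.ndarray:
        parts = [np.array([model.c_y]), model.a]
        if self.use_b:
            parts.append(model.b)
        parts.append(np.array([math.log(model.sigma), model.c_x]))
        parts.append(model.d)
        if self.use_e:
            parts.append(model.e)
        parts.append(np.array([math.atanh(model.rho)]))
        return np.concatenate(parts)

    def unpack(self, theta: np.ndarray) -> JointModel:
        p = self.p
        i = 0
        c_y = theta[i]; i += 1
        a = theta[i : i + p]; i += p
        if self.use_b:
            b = theta[i : i + p]; i += p
        else:
            b = np.zeros(p)
        sigma = math.exp(theta[i]); i += 1
        c_x = theta[i]; i += 1
        d = theta[i : i + p]; i += p
        if self.use_e:
            e = theta[i : i + p]; i += p
        else:
            e = np.zeros(p)
        rho = math.tanh(theta[i])
        return JointModel(p=p, c_y=c_y, a=a, b=b, sigma=sigma, c_x=c_x, d=d, e=e, rho=rho)

    def neg_loglik_grad(self, theta: np.ndarray):
        p = self.p
        i = 0
        c_y = theta[i]; i += 1
        a = theta[i : i + p]; i += p
        if self.use_b:
            b = theta[i : i + p]; i += p
        else:
            b = None
        log_sigma = theta[i]; i += 1
        sigma = math.exp(log_sigma)
        c_x = theta[i]; i += 1
        d = theta[i : i + p]; i += p
        if self.use_e:
            e = theta[i : i + p]; i += p
        else:
            e = None
        r = theta[i]
        rho = math.tanh(r)

        y, x, Yh, Xh, s = self.y, self.x, self.Yh, self.Xh, self.s
        mu = c_y + Yh @ a
        if b is not None:
            mu += Xh @ b
        eta = c_x + Xh @ d
        if e is not None:
            eta += Yh @ e

        z = (y - mu) / sigma
        denom = math.sqrt(1.0 - rho * rho)
        g = (eta + rho * z) / denom
        sg = s * g
        log_cdf = log_ndtr(sg)
        ll = (-0.5 * (z * z) - log_sigma - 0.5 * _LOG_2PI + log_cdf).sum()

        # w = d log Phi(s g) / d g  (signed inverse Mills ratio)
        log_pdf = -0.5 * sg * sg - 0.5 * _LOG_2PI
        w = s * np.exp(log_pdf - log_cdf)

        dmu = z / sigma - w * (rho / (denom * sigma))
        deta = w / denom
        grad = np.empty_like(theta)
        i = 0
        grad[i] = dmu.sum(); i += 1
        grad[i : i + p] = Yh.T @ dmu; i += p
        if b is not None:
            grad[i : i + p] = Xh.T @ dmu; i += p
        # d ll / d log sigma
        grad[i] = ((z * z - 1.0) - w * (rho / denom) * z).sum(); i += 1
        grad[i] = deta.sum(); i += 1
        grad[i : i + p] = Xh.T @ deta; i += p
        if e is not None:
            grad[i : i + p] = Yh.T @ deta; i += p
        # d ll / d atanh(rho) = w * (z * denom + rho * g)
        grad[i] = (w * (z * denom + rho * g)).sum()
        return -ll, -grad


def _warm_start(problem: _Problem) -> JointModel:
    """Least squares for the continuous margin, probit Newton for the binary
    margin, rho = 0."""
    p = problem.p
    y, x, Yh, Xh = problem.y, problem.x, problem.Yh, problem.Xh
    cols_y = [np.ones((y.size, 1)), Yh] + ([Xh] if problem.use_b else [])
    Dy = np.hstack(cols_y)
    beta_y, *_ = np.linalg.lstsq(Dy, y, rcond=None)
    resid = y - Dy @ beta_y
    sigma = max(float(np.sqrt(np.mean(resid**2))), 1e-3)
    c_y = beta_y[0]
    a = beta_y[1 : 1 + p]
    b = beta_y[1 + p : 1 + 2 * p] if problem.use_b else np.zeros(p)

    cols_x = [np.ones((y.size, 1)), Xh] + ([Yh] if problem.use_e else [])
    Dx = np.hstack(cols_x)
    beta_x = _probit_newton(Dx, x)
    c_x = beta_x[0]
    d = beta_x[1 : 1 + p]
    e = beta_x[1 + p : 1 + 2 * p] if problem.use_e else np.zeros(p)
    return JointModel(
        p=p, c_y=c_y, a=a, b=b, sigma=sigma, c_x=c_x, d=d, e=e, rho=0.0
    )


def _probit_newton(D: np.ndarray, x: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Damped Newton maximization of the probit log-likelihood."""
    beta = np.zeros(D.shape[1])
    s = 2.0 * x - 1.0
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = D @ beta
        sg = s * eta
        log_cdf = log_ndtr(sg)
        ll = log_cdf.sum()
        w = s * np.exp(-0.5 * sg * sg - 0.5 * _LOG_2PI - log_cdf)
        grad = D.T @ w
        # observed-information weights: lambda (lambda + eta), lambda = s*mills
        h = w * (w + eta)
        H = D.T @ (D * h[:, None]) + 1e-8 * np.eye(D.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking to keep the likelihood monotone
        t = 1.0
        for _ in range(20):
            cand = beta + t * step
            ll_new = log_ndtr(s * (D @ cand)).sum()
            if ll_new >= ll:
                beta = cand
                break
            t *= 0.5
        if abs(ll_new - ll_old) < 1e-10 * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    return beta


def fit(
    ts,
    p: int,
    restriction: str = "full",
    x0: JointModel | None = None,
    compute_se: bool = False,
    maxiter: int = 300,
    t_start: int | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the joint model at order ``p``.

    ``restriction`` fixes a cross-history block to zero: ``no_spike_to_lfp``
    drops ``b`` and ``no_lfp_to_spike`` drops ``e`` (the nested reduced models
    used for directional Granger causality).  ``x0`` optionally warm-starts
    the optimizer (e.g. from a previous fit); the default warm start is least
    squares + probit Newton at ``rho = 0``.  Non-convergence is reported via
    the ``converged`` flag, never silently.
    """
    problem = _Problem(ts, p, restriction, t_start)
    spikes_used = ts.spikes[:, t_start if t_start is not None else p :]
    if np.all(spikes_used == 0) or np.all(spikes_used >= 1):
        raise ValueError(
            "degenerate spike channel: all bins are "
            + ("0" if np.all(spikes_used == 0) else "1")
            + "; the binary margin is not identifiable"
        )
    if problem.n_obs < 10 * problem.k:
        warnings.warn(
            f"only {problem.n_obs} observations for {problem.k} free parameters "
            f"(< 10 per parameter); estimates may be unstable",
            stacklevel=2,
        )
    if x0 is not None:
        m0 = x0
        if m0.p != p:
            raise ValueError(f"x0 has order {m0.p}, expected {p}")
        if not problem.use_b and np.any(m0.b):
            m0 = replace(m0, b=np.zeros(p))
        if not problem.use_e and np.any(m0.e):
            m0 = replace(m0, e=np.zeros(p))
        starts = [m0]
    else:
        starts = [_warm_start(problem)]

    best = None
    for si, start in enumerate(starts):
        theta0 = problem.pack(start)
        res = optimize.minimize(
            problem.neg_loglik_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        # fall back to the default warm start only if the supplied start failed
        if si == 0 and x0 is not None and not res.success:
            starts.append(_warm_start(problem))
    model = problem.unpack(best.x)
    fr = FitResult(
        model=model,
        loglik=-float(best.fun),
        k=problem.k,
        converged=bool(best.success),
        n_obs=problem.n_obs,
        restriction=restriction,
        message=str(best.message),
    )
    if compute_se:
        fr.se = _standard_errors(problem, best.x)
    return fr


def _standard_errors(problem: _Problem, theta: np.ndarray) -> dict:
    """SEs from the inverse observed information (finite differences of the
    analytic gradient on the unconstrained scale, delta method for sigma/rho).
    Diagnostics only."""
    k = theta.size
    H = np.empty((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(k):
        tp = theta.copy(); tp[j] += h[j]
        tm = theta.copy(); tm[j] -= h[j]
        _, gp = problem.neg_loglik_grad(tp)
        _, gm = problem.neg_loglik_grad(tm)
        H[:, j] = (gp - gm) / (2.0 * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
    p = problem.p
    model = problem.unpack(theta)
    out: dict[str, object] = {}
    i = 0
    out["c_y"] = se_t[i]; i += 1
    out["a"] = se_t[i : i + p]; i += p
    if problem.use_b:
        out["b"] = se_t[i : i + p]; i += p
    out["sigma"] = model.sigma * se_t[i]; i += 1  # delta: sigma = exp(.)
    out["c_x"] = se_t[i]; i += 1
    out["d"] = se_t[i : i + p]; i += p
    if problem.use_e:
        out["e"] = se_t[i : i + p]; i += p
    out["rho"] = (1.0 - model.rho**2) * se_t[i]  # delta: rho = tanh(.)
    return out


def aic(fr: FitResult) -> float:
    """Akaike information criterion of a converged fit."""
    if not fr.converged:
        raise ValueError("AIC requested for a non-converged fit")
    return -2.0 * fr.loglik + 2.0 * fr.k


def select_order(ts, candidates, restriction: str = "full"):
    """Fit each candidate order and pick the AIC minimizer.

    All candidates condition on ``max(candidates)`` initial bins per trial so
    their likelihoods are evaluated on identical observations (AIC values are
    otherwise incomparable across orders).  Ties break toward the smaller
    order; non-converged candidates appear in the table as ``None`` and are
    never selected.  Returns ``(best_order, {order: aic_or_None})``.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("candidates must be nonempty")
    p_max = max(candidates)
    table: dict[int, float | None] = {}
    for p in candidates:
        try:
            fr = fit(ts, p, restriction=restriction, t_start=p_max)
        except ValueError:
            table[p] = None
            continue
        table[p] = aic(fr) if fr.converged else None
    valid = [(p, v) for p, v in table.items() if v is not None]
    if not valid:
        raise RuntimeError("no candidate order converged")
    best = min(valid, key=lambda pv: (pv[1], pv[0]))[0]
    return best, table
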