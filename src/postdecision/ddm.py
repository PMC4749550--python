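"""One-choice drift-diffusion model of self-initiated error detection.

The model assumes that after an erroneous action, noisy evidence that an
error has occurred accumulates at a trial-specific drift rate ``u`` drawn
from ``Normal(v, eta)``.  Detection is signalled when the accumulated
evidence first reaches a single bound ``a``; accumulation is abandoned if
the bound has not been reached by a per-subject deadline, producing an
undetected error.  Non-accumulation latencies (encoding, motor execution)
are collected in a non-decision time ``t_nd`` so that the detection
response time is ``rt_d = T + t_nd`` with ``T`` the first-passage time.
Within-trial noise has standard deviation ``s`` per unit time, fixed at
0.1 by convention to scale the remaining parameters.

The module provides first-passage simulation (Euler-Maruyama random
walk), inverse-Gaussian closed-form oracles for the eta = 0 special case,
the defective-quantile chi-square objective used to fit the model to
detection accuracy and RT_d quantiles simultaneously, a particle-swarm
optimizer for that objective, and reconstruction of bin-averaged decision
variable trajectories from fitted parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SubjectParams",
    "QuantileFit",
    "FirstPassageLaw",
    "FitConfig",
    "simulate_fpt",
    "first_passage_times",
    "fpt_closed_form",
    "estimate_deadline",
    "defective_quantile_bins",
    "expected_counts",
    "chi2_from_counts",
    "chi2_objective",
    "fit_pso",
    "simulate_decision_variable",
]

#: conventional within-trial noise scale (evidence units per sqrt-second)
DEFAULT_NOISE_SCALE = 0.1

#: portion of the non-decision time allotted to post-threshold response
#: preparation when reconstructing decision-variable trajectories (s)
MOTOR_TIME = 0.090

#: duration of the linear decay back to baseline after the bound (s)
DECAY_TIME = 0.300

#: quantiles defining the defective RT_d bins
FIT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class SubjectParams:
    """Parameters of the one-choice diffusion model for one subject.

    Parameters
    ----------
    a : float
        Decision bound (evidence units), > 0.
    v : float
        Mean drift rate across trials (evidence units / s).
    eta : float
        Across-trial standard deviation of the drift rate, >= 0.
    t_nd : float
        Non-decision time (s), >= 0.
    deadline : float
        Latest admissible detection report, measured from the erroneous
        action (s).  Must exceed ``t_nd``.
    s : float
        Within-trial noise scale, fixed at 0.1 unless the whole parameter
        set is deliberately rescaled.
    """

    a: float
    v: float
    eta: float
    t_nd: float
    deadline: float = np.inf
    s: float = DEFAULT_NOISE_SCALE

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"bound a must be positive, got {self.a}")
        if self.eta < 0:
            raise ValueError(f"drift s.d. eta must be >= 0, got {self.eta}")
        if self.t_nd < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t_nd}")
        if not self.s > 0:
            raise ValueError(f"noise scale s must be positive, got {self.s}")
        if not self.deadline > self.t_nd:
            raise ValueError(
                f"deadline ({self.deadline}) must exceed t_nd ({self.t_nd})"
            )

    @property
    def drift_ratio(self) -> float:
        """v/eta, the identifiable evidence-quality index (NaN if eta = 0)."""
        return self.v / self.eta if self.eta > 0 else float("nan")


@dataclass
class FirstPassageLaw:
    """Closed-form first-passage law for a fixed drift (eta = 0)."""

    p_absorb: float
    mean_t: float
    cdf: Callable[[np.ndarray], np.ndarray]
    #: True when the mean is undefined/infinite (zero or negative drift)
    mean_undefined: bool = False


def fpt_closed_form(u: float, a: float, s: float = DEFAULT_NOISE_SCALE) -> FirstPassageLaw:
    """Closed-form absorption probability and first-passage law.

    For a single absorbing bound at ``a`` and fixed drift ``u``:

    * ``u > 0``: absorption is certain and the first-passage time is
      inverse-Gaussian with mean ``a/u`` and shape ``a**2 / s**2``.
    * ``u < 0``: absorption occurs with probability ``exp(2*u*a/s**2)``;
      conditional on absorption the first-passage time is inverse-Gaussian
      with mean ``a/|u|`` and the same shape.  The returned ``cdf`` is the
      *defective* distribution (it saturates at ``p_absorb``).
    * ``u == 0``: absorption is certain but the mean is infinite;
      ``P(T <= t) = 2 * Phi(-a / (s*sqrt(t)))``.
    """
    if not a > 0:
        raise ValueError("bound a must be positive")
    if not s > 0:
        raise ValueError("noise scale s must be positive")
    lam = a * a / (s * s)
    if u > 0:
        mu = a / u
        law = stats.invgauss(mu / lam, scale=lam)
        return FirstPassageLaw(1.0, mu, law.cdf)
    if u < 0:
        p = float(np.exp(2.0 * u * a / (s * s)))
        mu = a / abs(u)
        law = stats.invgauss(mu / lam, scale=lam)
        return FirstPassageLaw(
            p, float("inf"), lambda t: p * law.cdf(t), mean_undefined=True
        )

    def _cdf_zero(t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            z = a / (s * np.sqrt(t))
        return np.where(t > 0, 2.0 * stats.norm.sf(z), 0.0)

    return FirstPassageLaw(1.0, float("inf"), _cdf_zero, mean_undefined=True)


def first_passage_times(
    u: np.ndarray,
    a: float,
    s: float,
    dt: float,
    horizon: float,
    rng: np.random.Generator,
    chunk_steps: int = 4096,
) -> np.ndarray:
    """Euler-Maruyama first-passage times for per-trial drifts ``u``.

    Paths start at 0 and are advanced in steps ``x += u*dt + s*sqrt(dt)*z``
    until they reach ``a`` or the time ``horizon`` expires.  Returns one
    first-passage time per trial (NaN when the bound is not reached).
    Chunked over time so that long horizons do not blow up memory.
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    n_steps = int(np.ceil(horizon / dt))
    out = np.full(n, np.nan)
    alive = np.arange(n)
    x = np.zeros(n)
    sqdt = s * np.sqrt(dt)
    step0 = 0
    while step0 < n_steps and alive.size:
        m = min(chunk_steps, n_steps - step0)
        incr = u[alive, None] * dt + sqdt * rng.standard_normal((alive.size, m))
        paths = x[alive, None] + np.cumsum(incr, axis=1)
        hit = paths >= a
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        idx = alive[any_hit]
        out[idx] = (step0 + first[any_hit] + 1) * dt
        x[alive] = paths[:, -1]
        alive = alive[~any_hit]
        step0 += m
    return out


def simulate_fpt(
    params: SubjectParams,
    n_trials: int,
    dt: float = 1e-3,
    seed: int | np.random.Generator = 0,
    drifts: np.ndarray | None = None,
    horizon: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate detection outcomes and detection RTs for error trials.

    Each trial draws a drift ``u ~ Normal(v, eta)`` (or uses ``drifts`` if
    given) and runs a random-walk approximation of the diffusion at step
    size ``dt``.  A trial counts as detected iff the bound is reached at a
    first-passage time ``T`` with ``T + t_nd <= deadline``; its detection
    RT is ``rt_d = T + t_nd``.

    Returns
    -------
    detected : bool array (n_trials,)
    rt_d : float array (n_trials,), NaN on undetected trials
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.isfinite(params.deadline) and dt >= params.deadline:
        raise ValueError(f"dt ({dt}) must be smaller than the deadline")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if drifts is None:
        u = rng.normal(params.v, params.eta, n_trials)
    else:
        u = np.asarray(drifts, dtype=float)
        if u.size != n_trials:
            raise ValueError("drifts must have length n_trials")
    if horizon is None:
        if not np.isfinite(params.deadline):
            raise ValueError("an explicit horizon is required when deadline is infinite")
        horizon = params.deadline - params.t_nd
    T = first_passage_times(u, params.a, params.s, dt, horizon, rng)
    rt_d = T + params.t_nd
    detected = np.isfinite(T) & (rt_d <= params.deadline)
    rt_d[~detected] = np.nan
    return detected, rt_d


def estimate_deadline(rt_d: Sequence[float], n_sd: float = 3.5) -> float:
    """Empirical detection deadline from a subject's detection RTs.

    Values exceeding ``mean + n_sd * s.d.`` are trimmed in a single pass
    and the deadline is the slowest remaining RT.
    """
    x = np.asarray(rt_d, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("at least 2 detected trials are required")
    sd = x.std(ddof=1)
    keep = x <= x.mean() + n_sd * sd
    if not keep.any():
        raise ValueError("outlier trim removed every detection RT")
    return float(x[keep].max())


def defective_quantile_bins(
    rt_d_detected: Sequence[float],
    n_total_errors: int,
    quantiles: Sequence[float] = FIT_QUANTILES,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed counts of the defective RT_d distribution in 7 bins.

    The five quantiles (default 0.1/0.3/0.5/0.7/0.9) of the detected RT_d
    distribution divide the detected trials into six bins whose expected
    occupancies are the fixed proportions (.1, .2, .2, .2, .2, .1) of the
    *detected* count; the seventh bin collects the undetected errors.  The
    counts therefore sum to the total error count, so the same bins
    constrain detection accuracy and RT simultaneously.

    Returns
    -------
    q : the RT quantile values (s)
    O : observed counts over the 7 bins
    """
    x = np.asarray(rt_d_detected, dtype=float)
    x = x[np.isfinite(x)]
    n_det = x.size
    if n_det < 10:
        raise ValueError(
            f"need >= 10 detected trials to resolve quantile bins, got {n_det}"
        )
    if n_total_errors < n_det:
        raise ValueError("n_total_errors cannot be smaller than the detected count")
    q = np.quantile(x, quantiles)  # linear interpolation between order stats
    probs = np.diff(np.concatenate([[0.0], quantiles, [1.0]]))
    O = np.concatenate([probs * n_det, [n_total_errors - n_det]])
    return q, O


def expected_counts(
    rt_d_sim: np.ndarray,
    detected_sim: np.ndarray,
    quantiles: np.ndarray,
    n_total: int,
    floor_frac: float = 1e-4,
) -> np.ndarray:
    """Model-expected counts in the 7 defective-quantile bins.

    Simulated detected RTs are tallied between the *observed* quantiles,
    undetected trials fill the last bin, and proportions are scaled to
    ``n_total``.  Bins are floored at ``floor_frac * n_total`` to keep the
    chi-square denominator strictly positive.
    """
    n_sim = detected_sim.size
    edges = np.concatenate([[-np.inf], quantiles, [np.inf]])
    counts, _ = np.histogram(rt_d_sim[detected_sim], bins=edges)
    props = np.concatenate([counts, [np.count_nonzero(~detected_sim)]]) / n_sim
    return np.maximum(props * n_total, floor_frac * n_total)


def chi2_from_counts(O: np.ndarray, E: np.ndarray) -> float:
    """Pearson statistic sum((O - E)**2 / E)."""
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected counts must be strictly positive")
    return float(np.sum((O - E) ** 2 / E))


class _CrnSimulator:
    """Common-random-numbers first-passage simulator for one fit.

    A fixed matrix of standard-normal drift deviates and a fixed
    pre-accumulated noise path are shared by every objective evaluation,
    so the chi-square surface is a deterministic function of the
    parameters and PSO optimizes a smooth(er) landscape.
    """

    def __init__(self, n_sim: int, horizon: float, dt: float, seed: int,
                 s: float = DEFAULT_NOISE_SCALE):
        rng = np.random.default_rng(seed)
        self.dt = dt
        self.s = s
        self.n_steps = int(np.ceil(horizon / dt))
        self.z_u = rng.standard_normal(n_sim)
        W = rng.standard_normal((n_sim, self.n_steps))
        np.cumsum(W, axis=1, out=W)
        W *= s * np.sqrt(dt)
        self.W = W
        self.t_grid = dt * np.arange(1, self.n_steps + 1)

    def run(self, a: float, v: float, eta: float, t_nd: float, deadline: float
            ) -> tuple[np.ndarray, np.ndarray]:
        u = v + eta * self.z_u
        X = u[:, None] * self.t_grid[None, :] + self.W
        hit = X >= a
        any_hit = hit.any(axis=1)
        T = (np.argmax(hit, axis=1) + 1) * self.dt
        rt_d = T + t_nd
        detected = any_hit & (rt_d <= deadline)
        rt_d = np.where(detected, rt_d, np.nan)
        return detected, rt_d


def chi2_objective(
    params: SubjectParams,
    quantiles: np.ndarray,
    O: np.ndarray,
    n_total: int,
    n_sim: int = 15_000,
    seed: int = 0,
    dt: float = 1e-3,
    simulator: _CrnSimulator | None = None,
) -> float:
    """Defective-quantile chi-square between observed and model counts.

    With a fixed ``seed`` the same random numbers are reused on every
    call, so the value is a deterministic function of the parameters.
    """
    if simulator is None:
        simulator = _CrnSimulator(n_sim, params.deadline - 0.0, dt, seed, params.s)
    detected, rt_d = simulator.run(
        params.a, params.v, params.eta, params.t_nd, params.deadline
    )
    E = expected_counts(rt_d, detected, quantiles, n_total)
    return chi2_from_counts(O, E)


@dataclass
class FitConfig:
    """Particle-swarm settings for the defective-quantile fit."""

    n_sim: int = 15_000
    dt: float = 1e-3
    n_particles: int = 30
    n_iter: int = 100
    seed: int = 0
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    #: iterations without improvement before the fit is flagged
    patience: int | None = None
    bounds: dict = field(default_factory=lambda: {
        "a": (0.01, 1.0),
        "v": (-1.0, 2.0),
        "eta": (0.0, 1.5),
        "t_nd": (0.05, None),  # upper bound filled in from the deadline
    })


@dataclass
class QuantileFit:
    """Result of fitting the one-choice model to defective-quantile counts."""

    params: SubjectParams
    quantiles: np.ndarray
    O: np.ndarray
    E: np.ndarray
    chi2: float
    df: int
    drift_ratio: float
    n_sim: int
    seed: int
    converged: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        for k in ("quantiles", "O", "E"):
            d[k] = np.asarray(d[k]).tolist()
        return d


def fit_pso(
    O: np.ndarray,
    quantiles: np.ndarray,
    n_total: int,
    deadline: float,
    config: FitConfig | None = None,
) -> QuantileFit:
    """Fit (a, v, eta, t_nd) by particle-swarm chi-square minimization.

    Thirty particles (by default) start at pseudorandom positions inside
    reflecting box bounds and follow standard constriction dynamics
    (inertia 0.72, cognitive/social weights 1.49).  ``s`` stays fixed and
    the deadline is supplied empirically, so the statistic has
    ``df = (7 - 1) - (4 + 1) = 1``.

    The chi-square surface is evaluated with common random numbers (one
    noise realization shared by all evaluations), making the fit a
    deterministic function of ``(O, quantiles, n_total, deadline, config)``.
    """
    cfg = config or FitConfig()
    rng = np.random.default_rng(cfg.seed)
    sim = _CrnSimulator(cfg.n_sim, deadline, cfg.dt, cfg.seed + 1)

    b = dict(cfg.bounds)
    lo_t, hi_t = b["t_nd"]
    if hi_t is None:
        hi_t = deadline - cfg.dt
    names = ("a", "v", "eta", "t_nd")
    lo = np.array([b["a"][0], b["v"][0], b["eta"][0], lo_t])
    hi = np.array([b["a"][1], b["v"][1], b["eta"][1], hi_t])

    def objective(p: np.ndarray) -> float:
        detected, rt_d = sim.run(p[0], p[1], p[2], p[3], deadline)
        E = expected_counts(rt_d, detected, quantiles, n_total)
        return chi2_from_counts(O, E)

    n_p = cfg.n_particles
    pos = lo + (hi - lo) * rng.random((n_p, 4))
    vel = 0.1 * (hi - lo) * (rng.random((n_p, 4)) - 0.5)
    pbest = pos.copy()
    pbest_val = np.array([objective(p) for p in pos])
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    since_improved = 0
    for _ in range(cfg.n_iter):
        r1 = rng.random((n_p, 4))
        r2 = rng.random((n_p, 4))
        vel = (cfg.inertia * vel
               + cfg.cognitive * r1 * (pbest - pos)
               + cfg.social * r2 * (gbest - pos))
        pos = pos + vel
        # reflect at the box bounds
        for _bounce in range(2):
            under = pos < lo
            pos[under] = (2 * lo - pos)[under]
            vel[under] *= -1
            over = pos > hi
            pos[over] = (2 * hi - pos)[over]
            vel[over] *= -1
        pos = np.clip(pos, lo, hi)
        vals = np.array([objective(p) for p in pos])
        better = vals < pbest_val
        pbest[better] = pos[better]
        pbest_val[better] = vals[better]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val - 1e-12:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
            since_improved = 0
        else:
            since_improved += 1
        if cfg.patience is not None and since_improved >= cfg.patience:
            break

    converged = True
    if cfg.patience is not None and since_improved >= cfg.patience:
        converged = False
        warnings.warn("PSO stopped without improvement; returning best-so-far")

    best = SubjectParams(*[float(x) for x in gbest], deadline=deadline)
    detected, rt_d = sim.run(best.a, best.v, best.eta, best.t_nd, deadline)
    E = expected_counts(rt_d, detected, quantiles, n_total)
    n_free = 4
    df = (len(O) - 1) - (n_free + 1)
    return QuantileFit(
        params=best,
        quantiles=np.asarray(quantiles, dtype=float),
        O=np.asarray(O, dtype=float),
        E=E,
        chi2=chi2_from_counts(O, E),
        df=df,
        drift_ratio=best.drift_ratio,
        n_sim=cfg.n_sim,
        seed=cfg.seed,
        converged=converged,
    )


@dataclass
class DecisionTrajectories:
    """Bin-averaged simulated decision-variable trajectories."""

    times: np.ndarray                 # s relative to the erroneous action
    detected: list[np.ndarray]        # one average per RT_d bin (fast -> slow)
    undetected: np.ndarray
    bin_mean_rt: np.ndarray
    n_per_bin: np.ndarray
    n_undetected: int


def simulate_decision_variable(
    params: SubjectParams,
    rt_bins: int = 3,
    n_sim: int = 5_000,
    seed: int = 0,
    dt: float = 1e-3,
    t_max: float | None = None,
) -> DecisionTrajectories:
    """Reconstruct average decision-variable trajectories from parameters.

    90 ms of the non-decision time is allotted to post-threshold response
    preparation; the residual delays accumulation onset relative to the
    erroneous action.  After the bound is reached the trajectory decays
    linearly to baseline over 300 ms.  Detected trials are sorted into
    ``rt_bins`` equal-sized RT_d bins and averaged error-aligned;
    undetected trials (bound not reached by the deadline) are averaged
    separately, holding their terminal value after accumulation stops.
    """
    if not np.isfinite(params.deadline):
        raise ValueError("trajectory reconstruction requires a finite deadline")
    motor = MOTOR_TIME
    if params.t_nd < MOTOR_TIME:
        warnings.warn(
            "t_nd below the 90 ms motor allotment; truncating the allotment"
        )
        motor = params.t_nd
    onset = params.t_nd - motor
    budget = params.deadline - params.t_nd  # accumulation time available
    if t_max is None:
        t_max = params.deadline + DECAY_TIME
    rng = np.random.default_rng(seed)
    u = rng.normal(params.v, params.eta, n_sim)
    n_acc = int(np.ceil(budget / dt))
    incr = u[:, None] * dt + params.s * np.sqrt(dt) * rng.standard_normal((n_sim, n_acc))
    paths = np.cumsum(incr, axis=1)
    hit = paths >= params.a
    any_hit = hit.any(axis=1)
    first = np.argmax(hit, axis=1)
    T = (first + 1) * dt
    detected = any_hit  # T + t_nd <= deadline holds by construction of budget

    times = np.arange(0.0, t_max + dt / 2, dt)
    n_t = times.size

    def trajectory(i: int) -> np.ndarray:
        traj = np.zeros(n_t)
        k_on = np.searchsorted(times, onset)
        if detected[i]:
            k_cross = first[i] + 1
            seg = paths[i, :k_cross]
            stop = min(k_on + k_cross, n_t)
            traj[k_on:stop] = np.minimum(seg[: stop - k_on], params.a)
            t_cross = onset + T[i]
            decay_mask = (times >= t_cross) & (times < t_cross + DECAY_TIME)
            traj[decay_mask] = params.a * (1 - (times[decay_mask] - t_cross) / DECAY_TIME)
            traj[times >= t_cross + DECAY_TIME] = 0.0
        else:
            stop = min(k_on + n_acc, n_t)
            traj[k_on:stop] = paths[i, : stop - k_on]
            if stop < n_t:
                traj[stop:] = paths[i, -1]
        return traj

    rt_d = T + params.t_nd
    det_idx = np.flatnonzero(detected)
    order = det_idx[np.argsort(rt_d[det_idx], kind="stable")]
    n_det = order.size
    base, rem = divmod(n_det, rt_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(rt_bins)]
    averages, mean_rt, n_per = [], [], []
    start = 0
    for size in sizes:
        members = order[start:start + size]
        start += size
        if size == 0:
            averages.append(np.zeros(n_t))
            mean_rt.append(np.nan)
            n_per.append(0)
            continue
        acc = np.zeros(n_t)
        for i in members:
            acc += trajectory(i)
        averages.append(acc / size)
        mean_rt.append(float(rt_d[members].mean()))
        n_per.append(size)

    undet_idx = np.flatnonzero(~detected)
    undet = np.zeros(n_t)
    for i in undet_idx:
        undet += trajectory(i)
    if undet_idx.size:
        undet /= undet_idx.size

    return DecisionTrajectories(
        times=times,
        detected=averages,
        undetected=undet,
        bin_mean_rt=np.asarray(mean_rt),
        n_per_bin=np.asarray(n_per),
        n_undetected=int(undet_idx.size),
    )
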