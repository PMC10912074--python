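"""Two-tissue compartment model (2TCM): forward model, nonlinear fitting,
and AIC-based reversible-vs-irreversible model comparison.

The 2TCM describes tracer exchange between parent plasma (Cp), a free
tissue compartment C1 and a bound compartment C2:

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

with measured signal C(t) = C1 + C2 + vB*Cwb, where vB is the fractional
blood volume.  Irreversible binding corresponds to k4 = 0, in which case
the net influx rate Ki = K1*k3/(k2+k3) is the macro-parameter of interest
(and the Patlak slope).

The forward model is evaluated in closed form: the tissue response is a
sum of two exponentials convolved with Cp, computed exactly for a
piecewise-linear Cp sampled on a uniform fine grid, then averaged over each
acquisition frame (composite Simpson).  Degenerate (equal) eigenvalues are
handled by the analytic limit, which introduces a t*exp(-a*t) kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .input_function import InputFunctionSet
from .schedule import FrameSchedule
from .tac import TimeActivityCurve

__all__ = [
    "KineticParams",
    "FitResult",
    "ModelComparison",
    "model_tac",
    "fit_2tcm",
    "aic",
    "compare_models",
    "macro_ki",
    "FitError",
]

#: Internal evaluation grid [min]: 0.25 s steps up to the early/late
#: breakpoint (resolves the bolus peak), 1 s afterwards.  Both steps divide
#: every frame boundary of the default schedule.
GRID_DT_EARLY = 1.0 / 240.0
GRID_DT_LATE = 1.0 / 60.0
GRID_BREAK = 6.0


class FitError(RuntimeError):
    """Raised when no multi-start attempt converges; carries the best attempt."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class KineticParams:
    """2TCM rate constants.

    K1 [mL·cm⁻³·min⁻¹] plasma→tissue transport; k2, k3, k4 [min⁻¹];
    vB fractional blood volume in [0, 1].  ``k4 = 0`` is the irreversible
    model.
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    vB: float = 0.05

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4", "vB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.vB > 1:
            raise ValueError("vB must be in [0, 1]")

    @property
    def irreversible(self) -> bool:
        return self.k4 == 0.0


def macro_ki(kp: KineticParams) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3); 0 when k2+k3 = 0."""
    denom = kp.k2 + kp.k3
    if denom == 0.0:
        return 0.0
    return kp.K1 * kp.k3 / denom


@dataclass
class FitResult:
    """Outcome of a bounded nonlinear 2TCM fit."""

    params: KineticParams
    fixed: tuple[str, ...]
    rss: float
    n_frames: int
    n_free_params: int
    aic: float
    std_errors: dict[str, float]
    ki: float
    converged: bool
    mode: str = "irreversible"

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "params": {
                k: getattr(self.params, k) for k in ("K1", "k2", "k3", "k4", "vB")
            },
            "fixed": list(self.fixed),
            "rss": self.rss,
            "n_frames": self.n_frames,
            "n_free_params": self.n_free_params,
            "aic": self.aic,
            "std_errors": self.std_errors,
            "ki": self.ki,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class ModelComparison:
    """AIC comparison of the reversible vs irreversible 2TCM.

    ``delta_aic = AIC(reversible) - AIC(irreversible)``; positive values
    favour the irreversible model (lower AIC wins) and |ΔAIC| > 2 is taken
    as a significant difference.
    """

    aic_reversible: float
    aic_irreversible: float

    @property
    def delta_aic(self) -> float:
        return self.aic_reversible - self.aic_irreversible

    @property
    def preferred(self) -> str:
        return "irreversible" if self.delta_aic > 0 else "reversible"

    @property
    def significant(self) -> bool:
        return abs(self.delta_aic) > 2.0


def aic(rss: float, n: int, p: int) -> float:
    """Akaike information criterion, AIC = n*ln(rss/n) + 2p.

    The least-squares form without small-sample correction, the common
    convention in kinetic modelling.  ``rss = 0`` returns -inf with a
    warning.
    """
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        warnings.warn("rss is zero; AIC is -inf", RuntimeWarning, stacklevel=2)
        return -np.inf
    return n * np.log(rss / n) + 2 * p


def compare_models(fit_rev: FitResult, fit_irr: FitResult) -> ModelComparison:
    """Build the ΔAIC comparison from two fits of the same data."""
    if fit_rev.n_frames != fit_irr.n_frames:
        raise ValueError(
            f"fits use different frame counts: {fit_rev.n_frames} vs {fit_irr.n_frames}"
        )
    return ModelComparison(aic_reversible=fit_rev.aic, aic_irreversible=fit_irr.aic)


# ---------------------------------------------------------------------------
# exact exponential convolution with piecewise-linear input on a uniform grid


def _exp_coeffs(alpha: float, dt: float) -> tuple[float, float, float, float]:
    """Segment constants e=exp(-a*dt), G0=∫e^{-av}dv, H=∫v e^{-av}dv,
    J=∫v² e^{-av}dv over [0, dt], with series forms for small a*dt."""
    x = alpha * dt
    e = np.exp(-x)
    if x < 1e-4:  # series forms avoid cancellation
        g0 = dt * (1.0 - x / 2.0 + x * x / 6.0 - x**3 / 24.0)
        h = dt * dt * (0.5 - x / 3.0 + x * x / 8.0 - x**3 / 30.0)
        j = dt**3 * (1.0 / 3.0 - x / 4.0 + x * x / 10.0 - x**3 / 36.0)
    else:
        g0 = (1.0 - e) / alpha
        h = (1.0 - e * (1.0 + x)) / (alpha * alpha)
        j = (2.0 - e * (x * x + 2.0 * x + 2.0)) / alpha**3
    return e, g0, h, j


Segments = tuple[tuple[int, int, float], ...]  # (first idx, last idx, dt)


def _expconv(alpha: float, t: np.ndarray, segments: Segments, c: np.ndarray) -> np.ndarray:
    """E(t_i) = ∫_0^{t_i} exp(-alpha*(t_i - s)) * c(s) ds, c piecewise linear.

    The grid is piecewise uniform (``segments``); the linear recurrence
    E_i = e*E_{i-1} + seg_i is evaluated per segment with the previous
    segment's end value carried as the filter's initial condition.
    """
    if alpha == 0.0:
        seg = (c[1:] + c[:-1]) / 2.0 * np.diff(t)
        return np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty_like(c)
    out[0] = 0.0
    prev = 0.0
    for i0, i1, dt in segments:
        e, g0, h, _ = _exp_coeffs(alpha, dt)
        c0, c1 = c[i0:i1], c[i0 + 1 : i1 + 1]
        seg = c0 * g0 + (c1 - c0) / dt * (dt * g0 - h)
        y, zf = lfilter([1.0], [1.0, -e], seg, zi=np.array([e * prev]))
        out[i0 + 1 : i1 + 1] = y
        prev = y[-1]
    return out


def _expconv_t(
    alpha: float, t: np.ndarray, segments: Segments, c: np.ndarray, e_arr: np.ndarray
) -> np.ndarray:
    """F(t_i) = ∫_0^{t_i} (t_i - s) exp(-alpha*(t_i - s)) c(s) ds.

    Needs E(alpha) precomputed (``e_arr``); used only for the degenerate
    equal-eigenvalue limit.
    """
    if alpha == 0.0:
        # F = t*∫c - ∫s*c
        dt_arr = np.diff(t)
        cum_c = np.concatenate([[0.0], np.cumsum((c[1:] + c[:-1]) / 2.0 * dt_arr)])
        sc = t * c
        cum_sc = np.concatenate([[0.0], np.cumsum((sc[1:] + sc[:-1]) / 2.0 * dt_arr)])
        return t * cum_c - cum_sc
    out = np.empty_like(c)
    out[0] = 0.0
    prev = 0.0
    for i0, i1, dt in segments:
        e, _, h, j = _exp_coeffs(alpha, dt)
        c0, c1 = c[i0:i1], c[i0 + 1 : i1 + 1]
        # ∫_0^dt v e^{-alpha v} c(t+dt-v) dv with c linear on the segment
        seg = c1 * h + (c0 - c1) / dt * j
        drive = e * dt * e_arr[i0:i1] + seg
        y, zf = lfilter([1.0], [1.0, -e], drive, zi=np.array([e * prev]))
        out[i0 + 1 : i1 + 1] = y
        prev = y[-1]
    return out


def _tissue_response(
    kp: KineticParams, t: np.ndarray, segments: Segments, cp: np.ndarray
) -> np.ndarray:
    """C1(t) + C2(t) on the grid, by bi-exponential convolution with Cp."""
    s = kp.k2 + kp.k3 + kp.k4
    disc_sq = s * s - 4.0 * kp.k2 * kp.k4
    disc = np.sqrt(max(disc_sq, 0.0))
    a1 = (s - disc) / 2.0
    a2 = (s + disc) / 2.0
    if kp.k4 == 0.0:
        a1 = 0.0  # exact: eigenvalues are 0 and k2+k3
        a2 = s
    beta = kp.k3 + kp.k4
    if disc > 1e-9:
        b1 = (beta - a1) / (a2 - a1)
        b2 = (a2 - beta) / (a2 - a1)
        ct = kp.K1 * (
            b1 * _expconv(a1, t, segments, cp) + b2 * _expconv(a2, t, segments, cp)
        )
    else:
        # analytic limit a2 -> a1: B1*E1 + B2*E2 -> E(a) + (beta - a)*F(a)
        a = (a1 + a2) / 2.0
        e_arr = _expconv(a, t, segments, cp)
        f_arr = _expconv_t(a, t, segments, cp, e_arr)
        ct = kp.K1 * (e_arr + (beta - a) * f_arr)
    return ct


class ModelContext:
    """Precomputed grid quantities shared across repeated forward evaluations
    of the same (input function, schedule) pair — the hot path of fitting."""

    def __init__(self, inp: InputFunctionSet, schedule: FrameSchedule):
        self.schedule = schedule
        t_end = float(schedule.ends[-1])
        brk = min(GRID_BREAK, t_end)
        n1 = int(round(brk / GRID_DT_EARLY))
        n2 = int(np.ceil((t_end - brk) / GRID_DT_LATE - 1e-9)) if t_end > brk else 0
        t_early = np.arange(n1 + 1) * GRID_DT_EARLY
        t_late = brk + np.arange(1, n2 + 1) * GRID_DT_LATE
        self.t = np.concatenate([t_early, t_late])
        segments = [(0, n1, GRID_DT_EARLY)]
        if n2:
            segments.append((n1, n1 + n2, GRID_DT_LATE))
        self.segments: Segments = tuple(segments)
        self.cp = np.asarray(inp.parent_plasma(self.t), dtype=float)
        self.cwb = np.asarray(inp.whole_blood(self.t), dtype=float)
        self._frame_weights = self._build_frame_weights()
        self.cwb_frames = self._frame_weights @ self.cwb

    def _grid_index(self, time: float) -> int:
        idx = int(np.searchsorted(self.t, time - 1e-9))
        if abs(self.t[idx] - time) > 1e-9:
            raise ValueError(f"time {time} min not aligned to the evaluation grid")
        return idx

    def _build_frame_weights(self) -> np.ndarray:
        """Per-frame composite-Simpson averaging weights over the grid.

        Frames never straddle the early/late grid breakpoint in the default
        schedule; a frame that does is averaged by trapezoid instead.
        """
        w = np.zeros((len(self.schedule), self.t.size))
        for i, (a, b) in enumerate(self.schedule.frames):
            ia = self._grid_index(a)
            ib = self._grid_index(b)
            m = ib - ia
            dts = np.diff(self.t[ia : ib + 1])
            uniform = np.allclose(dts, dts[0], rtol=1e-9, atol=0)
            if uniform and m >= 2 and m % 2 == 0:
                ws = np.ones(m + 1)
                ws[1:-1:2] = 4.0
                ws[2:-1:2] = 2.0
                ws *= dts[0] / 3.0
            else:  # trapezoid fallback
                ws = np.zeros(m + 1)
                ws[:-1] += dts / 2.0
                ws[1:] += dts / 2.0
            w[i, ia : ib + 1] = ws / (b - a)
        return w

    def frame_average(self, curve: np.ndarray) -> np.ndarray:
        return self._frame_weights @ curve

    def forward(self, kp: KineticParams) -> np.ndarray:
        """Frame-averaged measured signal C = C1 + C2 + vB*Cwb."""
        ct = _tissue_response(kp, self.t, self.segments, self.cp)
        return self.frame_average(ct) + kp.vB * self.cwb_frames


def model_tac(
    kp: KineticParams,
    inp: InputFunctionSet,
    schedule: FrameSchedule,
    context: ModelContext | None = None,
) -> TimeActivityCurve:
    """Noiseless frame-averaged 2TCM tissue curve.

    Solves the 2TCM in closed form (bi-exponential convolution with the
    parent-plasma curve, exact for piecewise-linear Cp on a 1 s grid), adds
    the fractional blood-volume signal vB*Cwb, and averages over each frame.
    """
    ctx = context if context is not None else ModelContext(inp, schedule)
    vals = ctx.forward(kp)
    return TimeActivityCurve(
        mid_times=schedule.mid_times, durations=schedule.durations, activity=vals
    )


# ---------------------------------------------------------------------------
# fitting

_DEFAULT_BOUNDS = {
    "K1": (0.0, 2.0),
    "k2": (0.0, 2.0),
    "k3": (0.0, 2.0),
    "k4": (0.0, 1.0),
    "vB": (0.0, 0.5),
}
_DEFAULT_INIT = KineticParams(K1=0.1, k2=0.1, k3=0.05, k4=0.01, vB=0.05)


def fit_2tcm(
    tac: TimeActivityCurve,
    inp: InputFunctionSet,
    schedule: FrameSchedule,
    mode: str = "irreversible",
    weights: np.ndarray | str | None = None,
    init: KineticParams | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    context: ModelContext | None = None,
) -> FitResult:
    """Bounded nonlinear least-squares 2TCM fit with multi-start.

    Parameters
    ----------
    mode
        ``"irreversible"`` fixes k4 = 0 (4 free parameters: K1, k2, k3, vB);
        ``"reversible"`` frees k4 (5 free parameters).
    weights
        Per-frame weights w_i in sum w_i*(y_i - yhat_i)^2.  ``None`` =
        uniform; ``"duration"`` = frame durations.
    n_starts
        One default initialisation plus ``n_starts - 1`` seeded log-uniform
        draws within bounds.  Ties are broken by lowest RSS, then lowest K1.

    Raises
    ------
    FitError
        If no start converges; the error carries the best attempt.
    """
    if mode not in ("irreversible", "reversible"):
        raise ValueError(f"mode must be 'irreversible' or 'reversible', got {mode!r}")
    y = np.asarray(tac.activity, dtype=float)
    if len(tac) != len(schedule):
        raise ValueError("TAC and schedule are not aligned")
    ctx = context if context is not None else ModelContext(inp, schedule)

    if weights is None:
        w = np.ones_like(y)
    elif isinstance(weights, str):
        if weights != "duration":
            raise ValueError(f"unknown weights scheme {weights!r}")
        w = schedule.durations.copy()
    else:
        w = np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    free = ["K1", "k2", "k3", "vB"] if mode == "irreversible" else ["K1", "k2", "k3", "k4", "vB"]
    fixed = ("k4",) if mode == "irreversible" else ()
    bnds = dict(_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[p][0] for p in free])
    hi = np.array([bnds[p][1] for p in free])

    def to_params(x: np.ndarray) -> KineticParams:
        d = dict(zip(free, x))
        d.setdefault("k4", 0.0)
        return KineticParams(**d)

    def residual(x: np.ndarray) -> np.ndarray:
        return sw * (ctx.forward(to_params(x)) - y)

    init_kp = init if init is not None else _DEFAULT_INIT
    x0_default = np.clip([getattr(init_kp, p) for p in free], lo, hi)
    starts = [x0_default]
    rng = np.random.default_rng(seed)
    log_lo = np.log(np.maximum(lo, 1e-3))
    log_hi = np.log(np.maximum(hi, 2e-3))
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.exp(rng.uniform(log_lo, log_hi)))

    best: tuple[float, float] | None = None
    best_sol = None
    any_ok = False
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        key = (rss, float(sol.x[0]))
        if best is None or key < best:
            best, best_sol = key, sol
        any_ok = any_ok or sol.success

    if best_sol is None:
        raise FitError("all multi-start fits failed", best=None)

    kp = to_params(best_sol.x)
    rss = best[0]
    n = y.size
    p = len(free)
    aic_val = aic(rss, n, p) if rss > 0 else -np.inf

    # standard errors from the Gauss-Newton approximation of the covariance
    se = {name: np.nan for name in ("K1", "k2", "k3", "k4", "vB")}
    try:
        jac = best_sol.jac
        jtj = jac.T @ jac
        cov = np.linalg.inv(jtj) * rss / max(n - p, 1)
        for name, v in zip(free, np.sqrt(np.maximum(np.diag(cov), 0.0))):
            se[name] = float(v)
    except np.linalg.LinAlgError:
        pass

    result = FitResult(
        params=kp,
        fixed=fixed,
        rss=rss,
        n_frames=n,
        n_free_params=p,
        aic=aic_val,
        std_errors=se,
        ki=macro_ki(kp),
        converged=any_ok,
        mode=mode,
    )
    if not any_ok:
        raise FitError("no multi-start attempt converged", best=result)
    return result
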