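"""Exponential fitting of stopped-flow traces and secondary k_obs fits.

The extraction ladder mirrors standard transient-kinetics practice: a
single- or double-exponential fit of each trace yields observed rates
``k_obs``; a series of ``k_obs`` against ligand concentration is then fit
linearly (sub-saturating regime: slope = second-order binding constant,
intercept = release rate) or hyperbolically (saturating regime:
``k_obs = k_max·[S]/(K_half + [S])``, whose low-concentration slope
``k_max/K_half`` is the effective second-order constant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .observables import SignalTrace

__all__ = [
    "Phase",
    "ExpFitResult",
    "KobsSeries",
    "LinearFit",
    "HyperbolicFit",
    "FitError",
    "fit_exponential",
    "fit_kobs_linear",
    "fit_kobs_hyperbolic",
]


class FitError(RuntimeError):
    """Raised when a fit cannot produce a usable estimate."""


@dataclass(frozen=True)
class Phase:
    amplitude: float
    k_obs: float


@dataclass
class ExpFitResult:
    """Result of a multi-exponential fit, phases ordered by descending rate."""

    phases: list[Phase]
    offset: float
    residual_norm: float
    noise_sd: float
    covariance: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)
    #: phases whose amplitude fell below the reporting threshold
    suppressed: list[Phase] = field(default_factory=list)

    @property
    def k_obs(self) -> float:
        """Rate of the dominant (largest-amplitude) reported phase."""
        if not self.phases:
            raise FitError(f"no reportable phase; flags: {self.flags}")
        return max(self.phases, key=lambda p: abs(p.amplitude)).k_obs

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        y = np.full_like(np.asarray(t, dtype=float), self.offset)
        for p in self.phases + self.suppressed:
            y = y + p.amplitude * np.exp(-p.k_obs * np.asarray(t, dtype=float))
        return y


def _exp_model(t: np.ndarray, params: np.ndarray, n: int) -> np.ndarray:
    y = np.full_like(t, params[-1])
    for i in range(n):
        y = y + params[2 * i] * np.exp(-params[2 * i + 1] * t)
    return y


def _start_values(t: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Log-linear regression of the tail-subtracted signal for k starts."""
    offset = float(np.mean(y[max(len(y) - max(len(y) // 10, 3), 1):]))
    d = y - offset
    a0 = d[0] if d[0] != 0 else (np.max(np.abs(d)) or 1.0)
    mask = np.abs(d) > 0.05 * np.max(np.abs(d)) if np.max(np.abs(d)) > 0 else np.ones_like(d, bool)
    mask &= t > t[0]
    if mask.sum() >= 2:
        slope, intercept, *_ = stats.linregress(t[mask], np.log(np.abs(d[mask])))
        k0 = max(-slope, 1e-3 / (t[-1] - t[0]))
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-9)
    if n == 1:
        return np.array([a0, k0, offset])
    # two phases: bracket the single-exponential estimate
    return np.array([a0 * 0.5, k0 * 5.0, a0 * 0.5, k0 * 0.3, offset])


def _fit_once(t, y, p0, n):
    def resid(p):
        return _exp_model(t, p, n) - y

    lower = np.full(len(p0), -np.inf)
    upper = np.full(len(p0), np.inf)
    for i in range(n):
        lower[2 * i + 1] = 1e-12  # rates stay positive
    res = optimize.least_squares(resid, p0, bounds=(lower, upper),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return res


def fit_exponential(
    trace: SignalTrace,
    n_phases: int = 1,
    window: tuple[float, float] | None = None,
    amplitude_threshold: float = 3.0,
    merge_ratio: float = 1.5,
) -> ExpFitResult:
    """Nonlinear least-squares fit of 1 or 2 exponential phases.

    A phase whose |amplitude| falls below ``amplitude_threshold`` × the
    residual noise is suppressed (kept in ``suppressed`` with a flag rather
    than reported).  Two phases whose rates differ by less than
    ``merge_ratio`` are merged into a single-phase fit.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    tr = trace if window is None else trace.window(*window)
    t = tr.times
    y = tr.signal
    if len(t) < 10:
        raise FitError(f"need >= 10 samples in window, got {len(t)}")

    p0 = _start_values(t, y, n_phases)
    flags: list[str] = []
    best = None
    for scale in (1.0, 0.1, 10.0, 0.01, 100.0):
        p_try = p0.copy()
        for i in range(n_phases):
            p_try[2 * i + 1] = p0[2 * i + 1] * scale
        try:
            res = _fit_once(t, y, p_try, n_phases)
        except Exception:
            continue
        if best is None or res.cost < best.cost * (1 - 1e-12):
            best = res
        if best.cost <= 1e-30 or (best.success and scale == 1.0):
            break
    if best is None:
        raise FitError("exponential fit failed from all start values")
    if not best.success:
        flags.append(f"non-convergence: {best.message}")

    p = best.x
    phases = sorted(
        (Phase(float(p[2 * i]), float(p[2 * i + 1])) for i in range(n_phases)),
        key=lambda ph: -ph.k_obs,
    )

    if n_phases == 2 and phases[1].k_obs > 0 and \
            phases[0].k_obs / phases[1].k_obs < merge_ratio:
        flags.append(
            f"phases merged (rate ratio "
            f"{phases[0].k_obs / phases[1].k_obs:.2f} < {merge_ratio})"
        )
        merged = fit_exponential(tr, 1, None, amplitude_threshold)
        merged.flags = flags + merged.flags
        return merged

    resid = _exp_model(t, p, n_phases) - y
    dof = max(len(t) - len(p), 1)
    noise_sd = float(np.sqrt(np.sum(resid**2) / dof))

    reported, suppressed = [], []
    for ph in phases:
        if noise_sd > 0 and abs(ph.amplitude) < amplitude_threshold * noise_sd:
            suppressed.append(ph)
            flags.append(
                f"phase k={ph.k_obs:.4g}/s suppressed: |amplitude| "
                f"{abs(ph.amplitude):.3g} < {amplitude_threshold}x noise "
                f"{noise_sd:.3g}"
            )
        else:
            reported.append(ph)

    try:
        jac = best.jac
        cov = np.linalg.inv(jac.T @ jac) * noise_sd**2
    except np.linalg.LinAlgError:
        cov = None
        flags.append("singular covariance")

    return ExpFitResult(
        phases=reported,
        offset=float(p[-1]),
        residual_norm=float(np.linalg.norm(resid)),
        noise_sd=noise_sd,
        covariance=cov,
        flags=flags,
        suppressed=suppressed,
    )


@dataclass
class KobsSeries:
    """Observed rates against ligand concentration for secondary fits."""

    ligand: str
    concentrations: np.ndarray
    k_obs: np.ndarray
    sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.concentrations.shape != self.k_obs.shape:
            raise ValueError("concentrations and k_obs must match in length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if len(np.unique(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be distinct")


@dataclass(frozen=True)
class LinearFit:
    slope: float       # second-order on-rate, µM⁻¹s⁻¹
    intercept: float   # off-rate, s⁻¹
    slope_se: float
    intercept_se: float


@dataclass(frozen=True)
class HyperbolicFit:
    k_max: float       # s⁻¹
    K_half: float      # µM
    k_max_se: float
    K_half_se: float
    warnings: tuple[str, ...] = ()

    @property
    def second_order(self) -> float:
        """Low-concentration slope k_max/K_half (µM⁻¹s⁻¹)."""
        return self.k_max / self.K_half


def fit_kobs_linear(series: KobsSeries) -> LinearFit:
    """OLS fit of the sub-saturating regime: k_obs = slope·[S] + intercept."""
    if len(np.unique(series.concentrations)) < 2:
        raise FitError("need >= 2 distinct concentrations for a linear fit")
    r = stats.linregress(series.concentrations, series.k_obs)
    return LinearFit(
        slope=float(r.slope),
        intercept=float(r.intercept),
        slope_se=float(r.stderr) if np.isfinite(r.stderr) else 0.0,
        intercept_se=float(r.intercept_stderr)
        if np.isfinite(r.intercept_stderr) else 0.0,
    )


def fit_kobs_hyperbolic(series: KobsSeries) -> HyperbolicFit:
    """Fit k_obs = k_max·[S]/(K_half + [S]) to a saturating series."""
    if len(series.concentrations) < 4:
        raise FitError("need >= 4 points for a hyperbolic fit")
    s, k = series.concentrations, series.k_obs
    kmax0 = float(np.max(k)) or 1.0
    khalf0 = float(np.median(s[s > 0])) if np.any(s > 0) else 1.0

    def model(x, kmax, khalf):
        return kmax * x / (khalf + x)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(
            model, s, k, p0=(kmax0, khalf0),
            bounds=((0, 0), (np.inf, np.inf)), maxfev=10000,
        )
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    warns = []
    kmax, khalf = float(popt[0]), float(popt[1])
    if np.max(s) < khalf:
        warns.append(
            f"concentrations do not span K_half={khalf:.3g} µM; wide CI"
        )
    if np.max(s) < 2 * khalf:
        warns.append("saturation not approached; estimates have wide CIs")
    return HyperbolicFit(kmax, khalf, float(se[0]), float(se[1]),
                         tuple(warns))
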