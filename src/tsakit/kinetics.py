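"""Michaelis–Menten fitting and progress-curve inhibition analysis.

Two routes to kinetic constants:

* initial rates at several substrate concentrations -> nonlinear MM fit
  (``fit_michaelis_menten``) giving k_cat and K_M;
* full progress curves with/without inhibitor -> the integrated-rate
  linearization ``t/ln(s0/s)`` vs ``(s0-s)/ln(s0/s)`` whose intercept is the
  apparent K_M/V_max, followed by the competitive-inhibition line
  ``(K_M/V_max)app = (K_M/V_max)0 (1 + I/K_I)`` giving K_I.

The closed-form solution of the integrated Michaelis–Menten law (via the
Wright omega function, a numerically robust Lambert-W evaluation) serves as
both simulator backbone and analytic oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import wrightomega

from .errors import DataError, FitError, NoInhibitionError

#: peptide-bond molar absorption coefficient at 225 nm, M^-1 cm^-1
EPSILON_225 = 376.0


def absorbance_to_rate(dA_dt: float, epsilon: float = EPSILON_225,
                       path_length: float = 1.0) -> float:
    """Convert an absorbance slope (AU/s) to a hydrolysis rate (M/s).

    Hydrolysis consumes peptide-bond absorbance, so a decreasing trace
    (negative slope) maps to a positive rate.
    """
    if epsilon <= 0 or path_length <= 0:
        raise DataError("epsilon and path_length must be positive")
    return abs(dA_dt) / (epsilon * path_length)


@dataclass
class MMParams:
    """Fitted (or true) Michaelis–Menten parameters."""

    Vmax: float  # M/s
    KM: float  # M
    enzyme_conc: Optional[float] = None  # M
    Vmax_se: Optional[float] = None
    KM_se: Optional[float] = None
    km_ill_conditioned: bool = False

    def __post_init__(self) -> None:
        if self.Vmax <= 0 or self.KM <= 0:
            raise ValueError("Vmax and KM must be positive")
        if self.enzyme_conc is not None and self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")

    @property
    def kcat(self) -> Optional[float]:
        if self.enzyme_conc is None:
            return None
        return self.Vmax / self.enzyme_conc

    @property
    def kcat_over_KM(self) -> Optional[float]:
        if self.enzyme_conc is None:
            return None
        return self.kcat / self.KM

    def rate(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.Vmax * s / (self.KM + s)


@dataclass
class ProgressCurve:
    """One substrate-depletion time course at a fixed inhibitor level."""

    s0: float  # M
    inhibitor_conc: float  # M
    times: np.ndarray  # s
    substrate: np.ndarray  # M
    absorbance: Optional[np.ndarray] = None
    epsilon: Optional[float] = None
    path_length: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.substrate = np.asarray(self.substrate, dtype=float)
        if self.s0 <= 0:
            raise DataError("s0 must be positive")
        if self.inhibitor_conc < 0:
            raise DataError("inhibitor concentration must be >= 0")
        if self.times.ndim != 1 or self.times.shape != self.substrate.shape:
            raise DataError("times and substrate must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0) or self.times[0] < 0:
            raise DataError("times must be strictly increasing and >= 0")
        if np.any(self.substrate <= 0) or np.any(self.substrate > self.s0 * (1 + 1e-9)):
            raise DataError("substrate values must lie in (0, s0]")

    def check_monotone(self, window: int = 5, tol_frac: float = 0.02) -> bool:
        """Moving-average smoothed series must not increase by > tol_frac*s0."""
        if len(self.substrate) < window:
            return True
        kernel = np.ones(window) / window
        smooth = np.convolve(self.substrate, kernel, mode="valid")
        return bool(np.all(np.diff(smooth) <= tol_frac * self.s0))


def closed_form_progress(s0: float, Vmax: float, KM: float, t,
                         KM_scale: float = 1.0) -> np.ndarray:
    """Substrate concentration s(t) solving Vmax*t = KM'*ln(s0/s) + (s0 - s).

    KM' = KM * KM_scale, with KM_scale = 1 + I/K_I for a competitively
    inhibited curve.  Uses s = KM' * omega(ln(s0/KM') + (s0 - Vmax t)/KM'),
    where omega is the Wright omega function (W(e^x) on the real line),
    avoiding overflow for KM' << s0.
    """
    t = np.asarray(t, dtype=float)
    if s0 <= 0 or Vmax <= 0 or KM <= 0 or KM_scale < 1.0:
        raise DataError("s0, Vmax, KM must be positive and KM_scale >= 1")
    if np.any(t < 0):
        raise DataError("time must be non-negative")
    km_eff = KM * KM_scale
    arg = np.log(s0 / km_eff) + (s0 - Vmax * t) / km_eff
    # clamp the ulp-level overshoot of omega at t = 0 so s(0) == s0 exactly
    s = np.minimum(km_eff * np.real(wrightomega(arg)), s0)
    return s if s.shape else float(s)


@dataclass
class LinearizationResult:
    """OLS line through the integrated-rate coordinates of one curve."""

    km_over_vmax: float  # s (intercept) = apparent K_M/V_max
    inv_vmax: float  # s/M (slope) = 1/V_max
    km_over_vmax_se: float
    inv_vmax_se: float
    r_squared: float
    n_points: int
    inhibitor_conc: float

    def __post_init__(self) -> None:
        if self.km_over_vmax <= 0 or self.inv_vmax <= 0:
            raise FitError(
                "linearization produced non-positive intercept or slope "
                f"({self.km_over_vmax:.3g}, {self.inv_vmax:.3g})"
            )


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Plain least squares; returns slope, intercept, their SEs, covariance, R^2."""
    n = len(x)
    design = np.column_stack([x, np.ones(n)])
    coef, residual_ss, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = coef
    fitted = design @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = n - 2
    sigma2 = ss_res / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return slope, intercept, np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1]), cov, r_squared


def linearize_and_fit(curve: ProgressCurve,
                      conversion_bounds: tuple[float, float] = (0.05, 0.95)
                      ) -> LinearizationResult:
    """Fit t/ln(s0/s) = (K_M/V_max)app + (1/V_max) * (s0-s)/ln(s0/s).

    Points with fractional conversion outside ``conversion_bounds`` are
    excluded before fitting (the transform divides by ln(s0/s), which blows
    up at the start of the curve).
    """
    lo, hi = conversion_bounds
    conversion = (curve.s0 - curve.substrate) / curve.s0
    keep = (conversion >= lo) & (conversion <= hi)
    s = curve.substrate[keep]
    t = curve.times[keep]
    if len(s) < 5:
        raise DataError(f"only {len(s)} usable points after conversion filter")
    if np.any(s >= curve.s0):
        raise DataError("retained point with s >= s0; ln(s0/s) undefined")
    log_ratio = np.log(curve.s0 / s)
    x = (curve.s0 - s) / log_ratio
    y = t / log_ratio
    slope, intercept, slope_se, intercept_se, _, r2 = _ols_line(x, y)
    return LinearizationResult(
        km_over_vmax=float(intercept), inv_vmax=float(slope),
        km_over_vmax_se=float(intercept_se), inv_vmax_se=float(slope_se),
        r_squared=float(r2), n_points=int(len(s)),
        inhibitor_conc=curve.inhibitor_conc,
    )


@dataclass
class InhibitionResult:
    """Competitive K_I from the apparent-(K_M/V_max) line."""

    K_I: float  # M
    K_I_se: float
    km_over_vmax_0: float  # s
    km_over_vmax_0_se: float
    slope: float  # s/M, = (K_M/V_max)0 / K_I
    slope_se: float
    r_squared: float
    apparent: list[tuple[float, float]]  # (I, (K_M/V_max)app)


def fit_inhibition(apparent: Sequence[tuple[float, float]]) -> InhibitionResult:
    """OLS of (K_M/V_max)app on I; K_I = intercept/slope.

    Raises :class:`NoInhibitionError` when the slope is non-positive within
    its standard error (no measurable inhibition, K_I not determinable).
    """
    pts = [(float(i), float(v)) for i, v in apparent]
    if len(pts) < 3:
        raise DataError("need >= 3 inhibitor concentrations")
    inhibitor = np.array([p[0] for p in pts])
    app = np.array([p[1] for p in pts])
    if len(np.unique(inhibitor)) < 3:
        raise DataError("need >= 3 distinct inhibitor concentrations")
    if not np.any(inhibitor == 0):
        raise DataError("an uninhibited (I = 0) reference is required")
    slope, intercept, slope_se, intercept_se, cov, r2 = _ols_line(inhibitor, app)
    if slope <= slope_se or slope <= 0:
        raise NoInhibitionError(
            f"slope {slope:.3g} +- {slope_se:.3g} is not positive; "
            "K_I not determinable"
        )
    if intercept <= 0:
        raise FitError(f"non-positive uninhibited intercept {intercept:.3g}")
    k_i = intercept / slope
    # first-order propagation: var(b0/b1)
    grad = np.array([-intercept / slope**2, 1.0 / slope])  # d/d(slope), d/d(intercept)
    k_i_var = float(grad @ cov @ grad)
    return InhibitionResult(
        K_I=float(k_i), K_I_se=float(np.sqrt(max(k_i_var, 0.0))),
        km_over_vmax_0=float(intercept), km_over_vmax_0_se=float(intercept_se),
        slope=float(slope), slope_se=float(slope_se), r_squared=float(r2),
        apparent=pts,
    )


def fit_inhibition_from_curves(curves: Sequence[ProgressCurve],
                               conversion_bounds: tuple[float, float] = (0.05, 0.95)
                               ) -> InhibitionResult:
    """Full progress-curve route: linearize each curve, then fit the K_I line."""
    apparent = []
    for curve in curves:
        lin = linearize_and_fit(curve, conversion_bounds)
        apparent.append((curve.inhibitor_conc, lin.km_over_vmax))
    return fit_inhibition(apparent)


def fit_michaelis_menten(substrate_concs: Sequence[float],
                         rates: Sequence[float],
                         enzyme_conc: Optional[float] = None) -> MMParams:
    """Nonlinear least-squares fit of v = Vmax*s/(KM + s)."""
    s = np.asarray(substrate_concs, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(np.unique(s)) < 4:
        raise DataError("need >= 4 distinct substrate concentrations")
    if np.any(s <= 0) or np.any(v < 0):
        raise DataError("substrate must be positive, rates non-negative")

    def model(s_, vmax, km):
        return vmax * s_ / (km + s_)

    p0 = [1.2 * float(v.max()), float(np.median(s))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, s, v, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    if vmax <= 0 or km <= 0:
        raise FitError(f"inadmissible fit Vmax={vmax:.3g}, KM={km:.3g}")
    perr = np.sqrt(np.diag(pcov))
    ill = bool(s.min() > 10.0 * km)  # all points saturating; KM barely constrained
    return MMParams(
        Vmax=float(vmax), KM=float(km), enzyme_conc=enzyme_conc,
        Vmax_se=float(perr[0]), KM_se=float(perr[1]), km_ill_conditioned=ill,
    )


# --------------------------------------------------------------------------
# Curve file I/O (delimited text, one curve per file)
# --------------------------------------------------------------------------

def read_progress_curve(path: str | Path) -> ProgressCurve:
    """Read ``time_s`` + (``substrate_M`` | ``absorbance_AU``) columns.

    Metadata header lines: ``#s0=``, ``#I=``, and for absorbance traces
    ``#epsilon=`` and ``#path_cm=`` (substrate = A / (epsilon * path)).
    """
    path = Path(path)
    meta: dict[str, float] = {}
    header: list[str] = []
    data_rows: list[list[float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = float(value)
            continue
        cells = line.replace(",", "\t").split("\t")
        cells = [c for c in cells if c]
        if not header:
            header = cells
            continue
        data_rows.append([float(c) for c in cells])
    if "s0" not in meta:
        raise DataError(f"{path}: missing #s0= header")
    data = np.array(data_rows)
    columns = {name: data[:, i] for i, name in enumerate(header)}
    if "time_s" not in columns:
        raise DataError(f"{path}: missing time_s column")
    s0 = meta["s0"]
    inhibitor = meta.get("I", 0.0)
    if "substrate_M" in columns:
        substrate = columns["substrate_M"]
        absorbance, epsilon, path_cm = None, meta.get("epsilon"), meta.get("path_cm")
    elif "absorbance_AU" in columns:
        epsilon = meta.get("epsilon", EPSILON_225)
        path_cm = meta.get("path_cm", 1.0)
        absorbance = columns["absorbance_AU"]
        substrate = absorbance / (epsilon * path_cm)
    else:
        raise DataError(f"{path}: need substrate_M or absorbance_AU column")
    return ProgressCurve(
        s0=s0, inhibitor_conc=inhibitor, times=columns["time_s"],
        substrate=substrate, absorbance=absorbance,
        epsilon=epsilon, path_length=path_cm, meta=dict(meta),
    )


def write_progress_curve(curve: ProgressCurve, path: str | Path) -> None:
    lines = [f"#s0={float(curve.s0)!r}", f"#I={float(curve.inhibitor_conc)!r}"]
    if curve.epsilon is not None:
        lines.append(f"#epsilon={float(curve.epsilon)!r}")
    if curve.path_length is not None:
        lines.append(f"#path_cm={float(curve.path_length)!r}")
    lines.append("time_s\tsubstrate_M")
    for t, s in zip(curve.times, curve.substrate):
        lines.append(f"{float(t)!r}\t{float(s)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
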