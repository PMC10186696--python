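"""Circular (time-of-day) samples and periodic density estimation.

Observation clock times are treated as angles on the unit circle
(24 h = 2*pi rad).  Two density estimators are provided:

* :func:`kde_circular` — a von Mises kernel density estimate with a plug-in
  bandwidth (the standard prescription in the activity-overlap literature:
  the kernel concentration is chosen from the sample's estimated von Mises
  concentration and the sample size).
* :func:`fit_trig_sum` — a maximum-likelihood nonnegative trigonometric-sum
  density (a squared trigonometric polynomial), with the polynomial order
  selected by AIC.

Both return a :class:`DensityCurve` evaluated on an equally spaced angular
grid and normalised to integrate to one over the circle.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import ive

from .errors import EstimationError, InputError

__all__ = [
    "CircularSample",
    "DensityCurve",
    "time_to_angle",
    "hours_to_angle",
    "angle_to_hours",
    "kde_circular",
    "fit_trig_sum",
    "vonmises_concentration",
]

TWO_PI = 2.0 * np.pi
HOURS_PER_DAY = 24.0


def hours_to_angle(hours):
    """Map clock hours in [0, 24) to radians in [0, 2*pi)."""
    return (np.asarray(hours, dtype=float) % HOURS_PER_DAY) * (TWO_PI / HOURS_PER_DAY)


def angle_to_hours(angle):
    """Inverse of :func:`hours_to_angle`."""
    return (np.asarray(angle, dtype=float) % TWO_PI) * (HOURS_PER_DAY / TWO_PI)


def time_to_angle(t) -> float:
    """Convert a single clock time to an angle in radians.

    Accepts fractional hours (e.g. ``6.5``), ``"HH:MM"`` / ``"HH:MM:SS"``
    strings, ISO 8601 timestamp strings, and ``datetime``/``time`` objects.
    Only the time of day is used; the date part of a timestamp is ignored.
    """
    if isinstance(t, (int, float, np.floating, np.integer)):
        hours = float(t)
        if not np.isfinite(hours):
            raise InputError(f"non-finite time value: {t!r}")
    elif isinstance(t, _dt.datetime):
        hours = t.hour + t.minute / 60.0 + (t.second + t.microsecond / 1e6) / 3600.0
    elif isinstance(t, _dt.time):
        hours = t.hour + t.minute / 60.0 + (t.second + t.microsecond / 1e6) / 3600.0
    elif isinstance(t, str):
        s = t.strip()
        try:
            if "T" in s or " " in s or "-" in s.lstrip("-"):
                return time_to_angle(_dt.datetime.fromisoformat(s))
            parts = s.split(":")
            if len(parts) == 1:
                hours = float(parts[0])
            else:
                h = float(parts[0])
                m = float(parts[1])
                sec = float(parts[2]) if len(parts) > 2 else 0.0
                hours = h + m / 60.0 + sec / 3600.0
        except ValueError as exc:
            raise InputError(f"unparseable time: {t!r}") from exc
    else:
        raise InputError(f"unsupported time type: {type(t).__name__}")
    return float(hours_to_angle(hours))


@dataclass(frozen=True)
class CircularSample:
    """Time-of-day observations as angles on the circle.

    Parameters
    ----------
    angles : array-like of float
        Angles in radians; wrapped into ``[0, 2*pi)`` on construction.
    site : str
        Study-site label.
    role : str
        One of ``"prey"``, ``"predator"``, ``"potential"`` (or empty).
    """

    angles: np.ndarray
    site: str = ""
    role: str = ""

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if a.ndim != 1 or a.size < 1:
            raise InputError("angles must be a non-empty 1-d array")
        if not np.all(np.isfinite(a)):
            raise InputError("angles contain non-finite values")
        object.__setattr__(self, "angles", np.mod(a, TWO_PI))

    @property
    def n(self) -> int:
        return int(self.angles.size)

    @property
    def hours(self) -> np.ndarray:
        return angle_to_hours(self.angles)

    def rotated(self, delta: float) -> "CircularSample":
        """Sample with all angles shifted by ``delta`` radians (wrapped)."""
        return replace(self, angles=np.mod(self.angles + delta, TWO_PI))

    @classmethod
    def from_hours(cls, hours, site: str = "", role: str = "") -> "CircularSample":
        return cls(angles=hours_to_angle(hours), site=site, role=role)


@dataclass(frozen=True)
class DensityCurve:
    """A periodic density evaluated on an equally spaced angular grid.

    ``grid`` holds ``m`` angles ``0, h, 2h, ...`` with ``h = 2*pi/m``; the
    value at ``2*pi`` is the value at ``0`` (periodicity).  The circular
    trapezoid integral therefore reduces to ``h * values.sum()``.
    """

    grid: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if g.shape != v.shape or g.ndim != 1 or g.size < 8:
            raise InputError("grid and values must be matching 1-d arrays (m >= 8)")
        if np.any(v < -1e-12):
            raise EstimationError("density values must be nonnegative")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", np.maximum(v, 0.0))

    @property
    def m(self) -> int:
        return int(self.grid.size)

    @property
    def step(self) -> float:
        return TWO_PI / self.m

    def integral(self) -> float:
        """Trapezoid integral over the full circle (periodic closure)."""
        return float(self.step * self.values.sum())

    def normalized(self) -> "DensityCurve":
        total = self.integral()
        if total <= 0:
            raise EstimationError("cannot normalise an all-zero density")
        return replace(self, values=self.values / total)

    def interpolate(self, angles) -> np.ndarray:
        """Periodic linear interpolation of the curve at arbitrary angles."""
        a = np.mod(np.asarray(angles, dtype=float), TWO_PI)
        gx = np.concatenate([self.grid, [TWO_PI]])
        gy = np.concatenate([self.values, [self.values[0]]])
        return np.interp(a, gx, gy)

    def rotated(self, delta: float) -> "DensityCurve":
        """Curve of the density rotated by ``delta`` (evaluated on the same grid)."""
        return replace(self, values=self.interpolate(self.grid - delta))


def _grid(m: int) -> np.ndarray:
    return np.arange(m) * (TWO_PI / m)


def vonmises_concentration(angles: np.ndarray, kappa_max: float = 500.0) -> float:
    """Estimate a von Mises concentration from the mean resultant length.

    Uses Fisher's series/rational approximations to invert ``A(kappa) = R``.
    The estimate is capped at ``kappa_max`` so that degenerate samples (all
    points identical, R -> 1) stay numerically usable.
    """
    z = np.exp(1j * np.asarray(angles, dtype=float))
    r = float(np.abs(z.mean()))
    if r < 1e-10:
        raise EstimationError(
            "mean resultant length is zero: concentration is unidentifiable"
        )
    r = min(r, 1.0 - 1e-9)
    if r < 0.53:
        kappa = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        kappa = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    return float(min(kappa, kappa_max))


def _plugin_kernel_concentration(kappa_hat: float, n: int) -> float:
    """Plug-in kernel concentration for a von Mises reference density.

    nu = [3 n kappa^2 I2(2 kappa) / (4 sqrt(pi) I0(kappa)^2)]^(2/5), with the
    Bessel ratio computed from exponentially scaled functions for stability.
    """
    # I2(2k)/I0(k)^2 = ive(2, 2k) / ive(0, k)^2  (the e^{2k} factors cancel)
    ratio = ive(2, 2.0 * kappa_hat) / ive(0, kappa_hat) ** 2
    nu = (3.0 * n * kappa_hat**2 * ratio / (4.0 * np.sqrt(np.pi))) ** 0.4
    return float(max(nu, 1e-3))


def _vm_kernel_matrix(grid: np.ndarray, angles: np.ndarray, nu: float) -> np.ndarray:
    # exp(nu(cos d - 1)) / (2 pi I0(nu) e^{-nu}) is stable for large nu
    d = grid[:, None] - angles[None, :]
    return np.exp(nu * (np.cos(d) - 1.0)) / (TWO_PI * ive(0, nu))


def kde_circular(
    sample: CircularSample,
    bandwidth_adjust: float = 1.0,
    grid_size: int = 512,
) -> DensityCurve:
    """von Mises kernel density estimate of a circular sample.

    The kernel concentration is the plug-in value divided by
    ``bandwidth_adjust``: values above 1 smooth more (the maximum of the
    curve can only decrease as ``bandwidth_adjust`` grows).
    """
    if sample.n < 2:
        raise EstimationError("kernel density estimation needs n >= 2")
    if not (bandwidth_adjust > 0):
        raise InputError("bandwidth_adjust must be positive")
    kappa_hat = vonmises_concentration(sample.angles)
    nu = _plugin_kernel_concentration(kappa_hat, sample.n) / bandwidth_adjust
    grid = _grid(grid_size)
    values = _vm_kernel_matrix(grid, sample.angles, nu).mean(axis=1)
    curve = DensityCurve(
        grid=grid,
        values=values,
        meta={
            "estimator": "vonmises_kde",
            "kernel_concentration": nu,
            "kappa_hat": kappa_hat,
            "bandwidth_adjust": float(bandwidth_adjust),
            "n": sample.n,
        },
    )
    return curve.normalized()


# ---------------------------------------------------------------------------
# Nonnegative trigonometric-sum densities
#
# f(theta) = |sum_{k=0}^{M} c_k e^{i k theta}|^2 with sum |c_k|^2 = 1/(2 pi)
# is nonnegative and integrates to one for any complex coefficient vector c.
# Maximum likelihood is run on the unconstrained real/imaginary parts (the
# normalisation is applied inside the likelihood); order M is picked by AIC
# over 0..max_order, with 2M free parameters per order (norm and global phase
# are not identified).
# ---------------------------------------------------------------------------


def _nnts_nll(v: np.ndarray, E: np.ndarray) -> float:
    c = v[0::2] + 1j * v[1::2]
    norm2 = float(np.real(np.vdot(c, c)))
    if norm2 <= 0:
        return np.inf
    g2 = np.abs(E @ c) ** 2
    if np.any(g2 <= 0):
        return np.inf
    n = E.shape[0]
    return float(-np.log(g2).sum() + n * np.log(TWO_PI * norm2))


def _nnts_fit_order(theta: np.ndarray, order: int, rng: np.random.Generator):
    """ML fit at a fixed order; returns (coef, nll)."""
    n = theta.size
    k = np.arange(order + 1)
    E = np.exp(1j * np.outer(theta, k))
    if order == 0:
        c = np.array([1.0 / np.sqrt(TWO_PI)], dtype=complex)
        return c, n * np.log(TWO_PI)

    # spectral-factorisation style init: sqrt of the (clipped) empirical
    # Fourier density, truncated to degree `order`
    m_init = 256
    grid = _grid(m_init)
    a = np.array([np.exp(-1j * kk * theta).mean() for kk in range(order + 1)])
    f_emp = np.real(
        a[0] + 2.0 * np.sum(a[1:, None] * np.exp(1j * np.outer(k[1:], grid)), axis=0)
    ) / TWO_PI
    root = np.sqrt(np.clip(f_emp, 1e-6, None))
    c0 = np.fft.ifft(root)[: order + 1]

    starts = [c0]
    for _ in range(2):
        starts.append(c0 + 0.1 * (rng.standard_normal(order + 1)
                                  + 1j * rng.standard_normal(order + 1)))
    best = None
    for cs in starts:
        v0 = np.empty(2 * (order + 1))
        v0[0::2], v0[1::2] = cs.real, cs.imag
        nrm = np.linalg.norm(v0)
        if nrm == 0:
            continue
        res = minimize(_nnts_nll, v0 / nrm, args=(E,), method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError(f"trigonometric-sum fit failed at order {order}")
    c = best.x[0::2] + 1j * best.x[1::2]
    c = c / (np.linalg.norm(c) * np.sqrt(TWO_PI))
    return c, float(best.fun)


def fit_trig_sum(
    sample: CircularSample,
    max_order: int = 4,
    grid_size: int = 512,
) -> DensityCurve:
    """Maximum-likelihood nonnegative trigonometric-sum density.

    Orders 0..``max_order`` are fitted (an order needs ``n >= 2*order + 2``)
    and the order with the smallest AIC is returned.  The sample is rotated
    so its circular mean sits at zero before fitting and the fitted curve is
    rotated back, which makes the estimator exactly equivariant under
    rotation of the data.
    """
    if sample.n < 2:
        raise EstimationError("trigonometric-sum fitting needs n >= 2")
    if max_order < 0:
        raise InputError("max_order must be >= 0")
    z = np.exp(1j * sample.angles).mean()
    mu_hat = float(np.angle(z)) if np.abs(z) > 1e-10 else 0.0
    theta = np.mod(sample.angles - mu_hat, TWO_PI)
    rng = np.random.default_rng(0)

    best = None  # (aic, order, coef)
    errors = []
    for order in range(0, max_order + 1):
        if order > 0 and sample.n < 2 * order + 2:
            break
        try:
            c, nll = _nnts_fit_order(theta, order, rng)
        except EstimationError as exc:
            errors.append(exc)
            continue
        aic = 2.0 * nll + 2.0 * (2 * order)
        if best is None or aic < best[0] - 1e-9:
            best = (aic, order, c)
    if best is None:
        raise EstimationError(
            "no trigonometric-sum order could be fitted: " + "; ".join(map(str, errors))
        )
    aic, order, c = best
    grid = _grid(grid_size)
    k = np.arange(order + 1)
    g = np.exp(1j * np.outer(grid - mu_hat, k)) @ c
    values = np.abs(g) ** 2
    curve = DensityCurve(
        grid=grid,
        values=values,
        meta={"estimator": "trig_sum", "order": order, "aic": aic, "n": sample.n},
    )
    return curve.normalized()
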