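"""Pearson distribution system fitted by moment matching.

The Pearson system classifies continuous distributions by the squared
skewness (beta1) and kurtosis (beta2) of the data and fits the selected
family so that its first moments reproduce the sample moments.  Every member
solves the Pearson differential equation for the centred variable y:

    f'(y) / f(y) = -(y + a) / (b0 + b1*y + b2*y**2)

whose coefficients follow directly from the sample moments
(mu2 = variance, g1 = skewness, b2k = kurtosis; D = 10*b2k - 12*g1^2 - 18):

    b0 = mu2 * (4*b2k - 3*g1^2) / D
    a  = b1 = sqrt(mu2) * g1 * (b2k + 3) / D
    b2 = (2*b2k - 3*g1^2 - 6) / D

The root structure of the denominator decides the family: real roots of
opposite sign give a four-parameter beta (type I), complex roots give
type IV, real roots of equal sign give a beta-prime (type VI); the
boundaries are the gamma (type III, b2 = 0), the scaled Student t
(type VII), the symmetric beta (type II) and the normal limit.

Because the classification statistic is itself estimated from data, the
boundary families are selected whenever the statistic is within sampling
uncertainty of the boundary (3 block-subsampled standard errors, with an
absolute floor of 1e-6).  Interior types (I, IV, VI) match all four sample
moments exactly; a collapsed boundary family matches as many moments as it
has free parameters (e.g. the gamma matches mean, variance and skewness,
and its kurtosis is then within noise of the sample's).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate, stats

from .errors import EstimationError

__all__ = ["ThermalPreferenceFit", "fit_pearson", "sample_moments", "BOUNDARY_TOL"]

BOUNDARY_TOL = 1e-6


def sample_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, kurtosis) by plain moment estimators.

    Variance is the second central moment (divisor n); skewness is
    m3/m2^1.5 and kurtosis the non-excess m4/m2^2, the conventions the
    Pearson classification criterion is written in.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    d = x - mu
    m2 = np.mean(d**2)
    if m2 <= 0:
        raise EstimationError("sample variance is zero: no distribution to fit")
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    return float(mu), float(m2), float(m3 / m2**1.5), float(m4 / m2**2)


@dataclass(frozen=True)
class ThermalPreferenceFit:
    """A Pearson-system density summarising selected body temperatures.

    ``family`` is one of ``"normal"``, ``"II"``, ``"III"``, ``"IV"``,
    ``"V"``, ``"VI"``, ``"VII"``, ``"I"``; ``parameters`` holds the
    family-specific parameters; ``fitted_moments`` the sample
    (mean, variance, skewness, kurtosis) the fit was matched to;
    ``support`` the density's support in the data's units (degrees C here).
    """

    family: str
    parameters: dict
    fitted_moments: tuple[float, float, float, float]
    support: tuple[float, float]
    _pdf: Callable[[np.ndarray], np.ndarray]

    def pdf(self, x) -> np.ndarray:
        """Density evaluated at ``x`` (zero outside the support)."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        inside = (x > lo) & (x < hi)
        out = np.zeros_like(x, dtype=float)
        if np.any(inside):
            out[inside] = self._pdf(x[inside])
        return out

    def numeric_moments(self) -> tuple[float, float, float, float]:
        """(mean, var, skew, kurt) of the fitted density by quadrature."""
        lo, hi = self.support
        mu_ref = self.fitted_moments[0]

        def raw(k):
            val, _ = integrate.quad(
                lambda t: (t - mu_ref) ** k * float(self.pdf(np.array([t]))[0]),
                lo, hi, limit=400, epsabs=1e-12, epsrel=1e-11,
            )
            return val

        m0 = raw(0)
        m1 = raw(1) / m0
        mu = mu_ref + m1
        c2 = raw(2) / m0 - m1**2
        m3c, _ = integrate.quad(
            lambda t: (t - mu) ** 3 * float(self.pdf(np.array([t]))[0]),
            lo, hi, limit=400, epsabs=1e-12, epsrel=1e-11,
        )
        m4c, _ = integrate.quad(
            lambda t: (t - mu) ** 4 * float(self.pdf(np.array([t]))[0]),
            lo, hi, limit=400, epsabs=1e-12, epsrel=1e-11,
        )
        m3c /= m0
        m4c /= m0
        return float(mu), float(c2), float(m3c / c2**1.5), float(m4c / c2**2)


def _block_se(x: np.ndarray, statistic, n_blocks: int = 20) -> float:
    """SE of a moment statistic by balanced block subsampling.

    The sorted data are dealt into ``n_blocks`` interleaved blocks through a
    fixed random permutation, so the estimate is deterministic and invariant
    to the input order while the blocks stay exchangeable.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    b = min(n_blocks, n // 4)
    if b < 2:
        return np.inf
    perm = np.random.default_rng(20170715).permutation(n)
    xs = x[perm]
    vals = []
    for i in range(b):
        block = xs[i::b]
        try:
            vals.append(statistic(block))
        except EstimationError:
            return np.inf
    vals = np.asarray(vals)
    return float(vals.std(ddof=1) / np.sqrt(b))


def _frozen_pdf(dist):
    return lambda x: dist.pdf(x)


def _reflected(dist, about: float):
    """Density of ``2*about - X`` for a scipy frozen distribution."""
    return lambda x: dist.pdf(2.0 * about - x)


def fit_pearson(tb, boundary_se_factor: float = 3.0) -> ThermalPreferenceFit:
    """Fit a Pearson-system distribution to body temperatures by moments.

    Parameters
    ----------
    tb : array-like
        Observed selected body temperatures (n >= 4, nonzero variance).
    boundary_se_factor : float
        How many subsampled standard errors of the classification statistic
        count as "on the boundary" (see module docstring).

    Raises
    ------
    EstimationError
        For degenerate samples or moment combinations outside the
        realisable region (kurtosis <= skewness**2 + 1).
    """
    x = np.asarray(tb, dtype=float)
    if x.size < 4:
        raise EstimationError("Pearson fitting needs n >= 4")
    if not np.all(np.isfinite(x)):
        raise EstimationError("body temperatures contain non-finite values")
    mu, m2, g1, b2k = sample_moments(x)
    beta1 = g1**2
    if b2k <= beta1 + 1.0 + 1e-12:
        raise EstimationError(
            f"moments outside the realisable region: kurtosis {b2k:.4g} <= "
            f"skewness^2 + 1 = {beta1 + 1:.4g}"
        )
    moments = (mu, m2, g1, b2k)
    sd = np.sqrt(m2)

    # block-subsampled SEs adapt to the data's tails, but the block estimate
    # itself is noisy; floor it with the normal-theory asymptotic SE
    n = x.size
    se_g1 = max(_block_se(x, lambda b: sample_moments(b)[2]), np.sqrt(6.0 / n))
    se_b2 = max(_block_se(x, lambda b: sample_moments(b)[3]), np.sqrt(24.0 / n))
    se_d3 = max(
        _block_se(
            x,
            lambda b: 2 * sample_moments(b)[3] - 3 * sample_moments(b)[2] ** 2 - 6,
        ),
        np.sqrt(96.0 / n),
    )
    tol_g1 = max(BOUNDARY_TOL, boundary_se_factor * se_g1)
    tol_b2 = max(BOUNDARY_TOL, boundary_se_factor * se_b2)
    tol_d3 = max(BOUNDARY_TOL, boundary_se_factor * se_d3)
    # a finite-n sample of a symmetric parent should collapse, but a clearly
    # skewed parent must not, however noisy the subsample skewnesses are
    tol_g1 = min(tol_g1, 0.5)
    tol_b2 = min(tol_b2, 1.0)
    tol_d3 = min(tol_d3, 2.0)

    if abs(g1) <= tol_g1:
        if abs(b2k - 3.0) <= tol_b2:
            dist = stats.norm(loc=mu, scale=sd)
            return ThermalPreferenceFit(
                family="normal",
                parameters={"mean": mu, "sd": sd},
                fitted_moments=moments,
                support=(-np.inf, np.inf),
                _pdf=_frozen_pdf(dist),
            )
        if b2k < 3.0:
            # symmetric beta: excess kurtosis of Beta(alpha, alpha) is
            # -6/(2*alpha+3); width from the variance
            alpha = 3.0 * (b2k - 1.0) / (2.0 * (3.0 - b2k))
            if alpha <= 0:
                raise EstimationError("kurtosis too small for a type II fit")
            width = np.sqrt(4.0 * (2.0 * alpha + 1.0) * m2)
            lo = mu - width / 2.0
            dist = stats.beta(alpha, alpha, loc=lo, scale=width)
            return ThermalPreferenceFit(
                family="II",
                parameters={"alpha": alpha, "lo": lo, "hi": lo + width},
                fitted_moments=moments,
                support=(lo, lo + width),
                _pdf=_frozen_pdf(dist),
            )
        # scaled Student t (type VII): df from the kurtosis
        df = 4.0 + 6.0 / (b2k - 3.0)
        scale = np.sqrt(m2 * (df - 2.0) / df)
        dist = stats.t(df=df, loc=mu, scale=scale)
        return ThermalPreferenceFit(
            family="VII",
            parameters={"df": df, "loc": mu, "scale": scale},
            fitted_moments=moments,
            support=(-np.inf, np.inf),
            _pdf=_frozen_pdf(dist),
        )

    delta3 = 2.0 * b2k - 3.0 * beta1 - 6.0
    if abs(delta3) <= tol_d3:
        # gamma (type III): matches mean, variance, skewness exactly
        shape = 4.0 / beta1
        scale = sd * abs(g1) / 2.0
        if g1 > 0:
            loc = mu - shape * scale
            dist = stats.gamma(shape, loc=loc, scale=scale)
            pdf, support = _frozen_pdf(dist), (loc, np.inf)
        else:
            hi = mu + shape * scale
            dist = stats.gamma(shape, loc=0.0, scale=scale)
            pdf, support = (lambda t: dist.pdf(hi - t)), (-np.inf, hi)
        return ThermalPreferenceFit(
            family="III",
            parameters={"shape": shape, "scale": scale, "skew_sign": np.sign(g1)},
            fitted_moments=moments,
            support=support,
            _pdf=pdf,
        )

    denom = 10.0 * b2k - 12.0 * beta1 - 18.0
    if abs(denom) < 1e-12:
        raise EstimationError("degenerate Pearson coefficients (10*b2-12*b1-18 = 0)")
    b0 = m2 * (4.0 * b2k - 3.0 * beta1) / denom
    a = sd * g1 * (b2k + 3.0) / denom
    b2c = delta3 / denom
    disc = a**2 - 4.0 * b2c * b0

    if disc < 0:
        # complex roots -> type IV
        lam = -a / (2.0 * b2c)
        a2 = b0 / b2c - lam**2
        if a2 <= 0:
            raise EstimationError("inconsistent type IV geometry")
        aa = np.sqrt(a2)
        mexp = 1.0 / (2.0 * b2c)
        nu = (lam + a) / (b2c * aa)

        def unnorm(y):
            u = (y - lam) / aa
            return (1.0 + u**2) ** (-mexp) * np.exp(-nu * np.arctan(u))

        norm, _ = integrate.quad(unnorm, -np.inf, np.inf, limit=400,
                                 epsabs=1e-13, epsrel=1e-12)
        if not np.isfinite(norm) or norm <= 0:
            raise EstimationError("type IV normalisation failed")
        return ThermalPreferenceFit(
            family="IV",
            parameters={"m": mexp, "nu": nu, "a": aa, "lam": mu + lam},
            fitted_moments=moments,
            support=(-np.inf, np.inf),
            _pdf=lambda t: unnorm(np.asarray(t) - mu) / norm,
        )

    r1 = (-a - np.sqrt(disc)) / (2.0 * b2c)
    r2 = (-a + np.sqrt(disc)) / (2.0 * b2c)
    r1, r2 = min(r1, r2), max(r1, r2)
    # exponents of |y - r1| and |y - r2| from partial fractions
    m1 = -(r1 + a) / (b2c * (r1 - r2))
    m2e = -(r2 + a) / (b2c * (r2 - r1))

    if r1 < 0.0 < r2:
        # type I: four-parameter beta on (r1, r2) around the mean
        p, q = m1 + 1.0, m2e + 1.0
        if p <= 0 or q <= 0:
            raise EstimationError("type I exponents not integrable")
        lo, hi = mu + r1, mu + r2
        dist = stats.beta(p, q, loc=lo, scale=hi - lo)
        return ThermalPreferenceFit(
            family="I",
            parameters={"a": p, "b": q, "lo": lo, "hi": hi},
            fitted_moments=moments,
            support=(lo, hi),
            _pdf=_frozen_pdf(dist),
        )

    if abs(disc) <= 1e-12 * max(abs(a) ** 2, 1e-30):
        # double root -> type V (inverse gamma); vanishingly rare in practice
        r = -a / (2.0 * b2c)
        shape = 1.0 / b2c - 1.0
        scl = -(r + a) / b2c
        if r < 0 and scl > 0:
            dist = stats.invgamma(shape, loc=mu + r, scale=scl)
            pdf, support = _frozen_pdf(dist), (mu + r, np.inf)
        elif r > 0 and scl < 0:
            dist = stats.invgamma(shape, loc=0.0, scale=-scl)
            pdf = lambda t: dist.pdf((mu + r) - np.asarray(t))  # noqa: E731
            support = (-np.inf, mu + r)
        else:
            raise EstimationError("inconsistent type V geometry")
        return ThermalPreferenceFit(
            family="V",
            parameters={"shape": shape, "scale": abs(scl)},
            fitted_moments=moments,
            support=support,
            _pdf=pdf,
        )

    # real roots on the same side of the mean -> type VI (beta prime)
    if r2 < 0.0:
        # support (r2, inf): z = (y - r2)/(r2 - r1) is beta-prime
        aa_bp = m2e + 1.0
        bb_bp = -(m1 + m2e) - 1.0  # so the (1+z) exponent is m1
        scalebp = r2 - r1
        if aa_bp <= 0 or bb_bp <= 0 or scalebp <= 0:
            raise EstimationError("type VI exponents not integrable")
        dist = stats.betaprime(aa_bp, bb_bp, loc=mu + r2, scale=scalebp)
        return ThermalPreferenceFit(
            family="VI",
            parameters={"a": aa_bp, "b": bb_bp, "root": mu + r2, "scale": scalebp},
            fitted_moments=moments,
            support=(mu + r2, np.inf),
            _pdf=_frozen_pdf(dist),
        )
    # mirror case: support (-inf, r1)
    aa_bp = m1 + 1.0
    bb_bp = -(m1 + m2e) - 1.0
    scalebp = r2 - r1
    if aa_bp <= 0 or bb_bp <= 0 or scalebp <= 0:
        raise EstimationError("type VI exponents not integrable")
    dist = stats.betaprime(aa_bp, bb_bp, loc=0.0, scale=scalebp)
    edge = mu + r1
    return ThermalPreferenceFit(
        family="VI",
        parameters={"a": aa_bp, "b": bb_bp, "root": edge, "scale": scalebp},
        fitted_moments=moments,
        support=(-np.inf, edge),
        _pdf=lambda t: dist.pdf(edge - np.asarray(t)),
    )
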