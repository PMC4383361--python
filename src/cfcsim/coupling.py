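"""Theta-to-gamma coupling: envelopes, gamma construction, and exact moments.

The fast component is a product ``gamma_t = e_t * x_t`` of an independent
band-limited latent process ``x`` with an envelope ``e_t`` driven by the
(lagged) slow oscillation:

* ``sinusoidal``:  e_t = theta_{t+tau}
* ``pulsatile``:   e_t = sum_k w_k * theta_{t+tau}^k      (one pulse per cycle)
* ``biphasic``:    e_t = sum_k w_k * (theta_{t+tau}^2)^k  (two pulses per cycle)

Because theta and x are jointly Gaussian and independent, the second-order
theory of gamma is exact: the envelope's raw cross moment
``M_e(tau') = E{e_t e_{t+tau'}}`` follows from Isserlis/Wick calculus and
``r^gamma_{tau'} = M_e(tau') * r^x_{tau'}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial
from typing import NamedTuple

import numpy as np
import scipy.signal

from .sampling import SamplePath
from .spectra import AcvSeq

__all__ = [
    "DEFAULT_WEIGHTS",
    "COUPLING_KINDS",
    "CouplingSpec",
    "PreferredPhase",
    "envelope",
    "make_gamma",
    "gaussian_cross_moment",
    "envelope_acv_theory",
    "envelope_moment_polynomial",
    "gamma_acv_theory",
    "preferred_phase",
    "harmonic_spacing",
]

#: order-4 polynomial weights of the pulsatile / biphasic envelopes
DEFAULT_WEIGHTS = (0.4783, 0.2625, 0.0933, 0.0292, 0.0058)

COUPLING_KINDS = ("sinusoidal", "pulsatile", "biphasic")


@dataclass
class CouplingSpec:
    """Coupling type, lag and polynomial weights.

    ``tau`` is an integer lag in samples.  ``weights`` are ignored by the
    sinusoidal kind.  ``f_theta`` is the slow-oscillation center frequency,
    carried for preferred-phase reporting.
    """

    kind: str = "pulsatile"
    tau: int = 0
    weights: tuple = DEFAULT_WEIGHTS
    f_theta: float = 6.0

    def __post_init__(self) -> None:
        if self.kind not in COUPLING_KINDS:
            raise ValueError(f"kind must be one of {COUPLING_KINDS}, got {self.kind!r}")
        if int(self.tau) != self.tau:
            raise ValueError("tau must be an integer number of samples")
        self.tau = int(self.tau)
        self.weights = tuple(float(w) for w in self.weights)
        if not self.weights or not all(np.isfinite(self.weights)):
            raise ValueError("weights must be a nonempty tuple of finite floats")
        if self.f_theta <= 0:
            raise ValueError("f_theta must be positive")

    @property
    def K(self) -> int:
        """Polynomial order (number of weights minus one)."""
        return len(self.weights) - 1

    @property
    def is_polynomial(self) -> bool:
        return self.kind in ("pulsatile", "biphasic")

    def powers(self) -> np.ndarray:
        """Exponent of theta attached to each weight."""
        k = np.arange(len(self.weights))
        return 2 * k if self.kind == "biphasic" else k


# ---------------------------------------------------------------------------
# sample-path operations
# ---------------------------------------------------------------------------


def _shifted(values: np.ndarray, tau: int) -> tuple[np.ndarray, np.ndarray]:
    """``values[t + tau]`` with out-of-range samples marked invalid (no wrap)."""
    n = values.size
    if abs(tau) >= n:
        raise ValueError(f"|tau| = {abs(tau)} must be smaller than n = {n}")
    out = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    if tau >= 0:
        out[: n - tau] = values[tau:]
        valid[: n - tau] = True
    else:
        out[-tau:] = values[: n + tau]
        valid[-tau:] = True
    return out, valid


def envelope(
    theta: SamplePath, spec: CouplingSpec, theta_var: float | None = None
) -> SamplePath:
    """Coupling envelope ``e_t`` evaluated on a theta sample path.

    For the polynomial kinds theta is first normalized to unit variance
    (``theta_var`` if given, else the path's sample variance), the scale at
    which the printed weights produce the intended pulse shape.  Boundary
    samples shifted out of range by ``tau`` are flagged in ``valid``.
    """
    shifted, valid = _shifted(theta.values, spec.tau)
    if spec.kind == "sinusoidal":
        vals = shifted.copy()
    else:
        if theta_var is None:
            sv = float(np.var(theta.values[valid]))
            theta_var = sv if sv > 0 else 1.0
        if theta_var <= 0:
            raise ValueError("theta_var must be positive")
        z = shifted / np.sqrt(theta_var)
        vals = np.polynomial.polynomial.polyval(
            z * z if spec.kind == "biphasic" else z, np.asarray(spec.weights)
        )
        vals = np.where(valid, vals, 0.0)
    return SamplePath(
        vals,
        theta.delta,
        label=f"envelope[{spec.kind}]",
        seed=theta.seed,
        valid=None if valid.all() else valid,
    )


def make_gamma(
    theta: SamplePath,
    x: SamplePath,
    spec: CouplingSpec,
    theta_var: float | None = None,
) -> SamplePath:
    """``gamma_t = e_t * x_t`` (x must be independent of theta by construction)."""
    if theta.n != x.n or not np.isclose(theta.delta, x.delta):
        raise ValueError("theta and x must share n and delta")
    env = envelope(theta, spec, theta_var=theta_var)
    vals = env.values * x.values
    valid = env.valid_mask & x.valid_mask
    return SamplePath(
        vals,
        theta.delta,
        label="gamma",
        seed=(theta.seed, x.seed),
        valid=None if valid.all() else valid,
    )


# ---------------------------------------------------------------------------
# exact Gaussian moment calculus
# ---------------------------------------------------------------------------


def _double_factorial(m: int) -> int:
    # (-1)!! = 1 by convention
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


def gaussian_cross_moment(j: int, k: int, r0: float, r_tau: float) -> float:
    """``E{a^j b^k}`` for zero-mean jointly Gaussian a, b.

    Both variables have variance ``r0`` and covariance ``r_tau``.  Closed-form
    Wick summation over pairings: ``m`` cross pairs contribute ``r_tau**m``,
    the remaining within-variable pairs contribute powers of ``r0``; the count
    of pairings with exactly m cross pairs is
    ``C(j,m) C(k,m) m! (j-m-1)!! (k-m-1)!!``.
    """
    if j < 0 or k < 0 or int(j) != j or int(k) != k:
        raise ValueError("exponents must be nonnegative integers")
    j, k = int(j), int(k)
    if (j + k) % 2 == 1:
        return 0.0
    total = 0.0
    for m in range(min(j, k) + 1):
        if (j - m) % 2 or (k - m) % 2:
            continue
        count = (
            comb(j, m)
            * comb(k, m)
            * factorial(m)
            * _double_factorial(j - m - 1)
            * _double_factorial(k - m - 1)
        )
        total += count * (r_tau**m) * (r0 ** ((j + k - 2 * m) // 2))
    return total


def envelope_moment_polynomial(spec: CouplingSpec) -> np.ndarray:
    """Coefficients c_m of ``M_e(rho) = sum_m c_m rho^m`` for unit-variance theta.

    ``rho`` is the lag-``tau'`` correlation of theta.  Exposing the polynomial
    lets the lag-domain moment sequence be evaluated in one vectorized pass.
    """
    if not spec.is_polynomial:
        raise ValueError("moment polynomial defined for polynomial kinds only")
    powers = spec.powers()
    max_m = int(powers.max())
    coeffs = np.zeros(max_m + 1)
    for wk, p in zip(spec.weights, powers):
        for wl, q in zip(spec.weights, powers):
            if (p + q) % 2:
                continue
            for m in range(min(p, q) + 1):
                if (p - m) % 2 or (q - m) % 2:
                    continue
                count = (
                    comb(p, m)
                    * comb(q, m)
                    * factorial(m)
                    * _double_factorial(p - m - 1)
                    * _double_factorial(q - m - 1)
                )
                coeffs[m] += wk * wl * count
    return coeffs


def envelope_acv_theory(
    acv_theta: AcvSeq, spec: CouplingSpec
) -> tuple[float, AcvSeq]:
    """Envelope mean and raw second-moment sequence ``M_e(tau')``.

    Returns the *raw* cross moment (not mean-centered): the gamma covariance
    factorizes through ``E{e_t e_{t+tau'}} * E{x_t x_{t+tau'}}`` and gamma is
    mean-zero regardless because ``E{x} = 0``.  Sinusoidal coupling reduces to
    ``M_e = r^theta`` with zero mean.  Polynomial kinds are evaluated for
    theta normalized to unit variance, mirroring :func:`envelope`.
    """
    if spec.kind == "sinusoidal":
        return 0.0, AcvSeq(acv_theta.values.copy(), acv_theta.delta, "envelope")
    r0 = acv_theta.values[0]
    if r0 <= 0:
        raise ValueError("theta variance must be positive")
    rho = acv_theta.values / r0
    mean = float(
        sum(
            w * _double_factorial(int(p) - 1)
            for w, p in zip(spec.weights, spec.powers())
            if p % 2 == 0
        )
    )
    coeffs = envelope_moment_polynomial(spec)
    moments = np.polynomial.polynomial.polyval(rho, coeffs)
    # M_e is a raw moment sequence, not a covariance: |M_e(tau)| can exceed
    # nothing it shouldn't, but AcvSeq's Cauchy-Schwarz check applies to it
    # legitimately since it is the acv of the (uncentered) envelope process.
    return mean, AcvSeq(moments, acv_theta.delta, f"envelope[{spec.kind}]")


def gamma_acv_theory(
    acv_theta: AcvSeq, acv_x: AcvSeq, spec: CouplingSpec
) -> AcvSeq:
    """Exact autocovariance ``r^gamma_{tau'} = M_e(tau') * r^x_{tau'}``."""
    if not np.isclose(acv_theta.delta, acv_x.delta):
        raise ValueError("acv_theta and acv_x must share delta")
    _, m_e = envelope_acv_theory(acv_theta, spec)
    L = min(m_e.values.size, acv_x.values.size)
    return AcvSeq(m_e.values[:L] * acv_x.values[:L], acv_x.delta, "gamma")


# ---------------------------------------------------------------------------
# phase and harmonic diagnostics
# ---------------------------------------------------------------------------


class PreferredPhase(NamedTuple):
    """The two published/conventional forms of the preferred phase.

    ``tau_over_two_pi_f`` is the printed formula tau / (2 pi f_theta);
    ``radians`` is the conventional phase 2 pi f_theta tau delta.  They are
    dimensionally inconsistent with one another, so both are reported.
    """

    tau_over_two_pi_f: float
    radians: float


def preferred_phase(spec: CouplingSpec, delta: float) -> PreferredPhase:
    if spec.f_theta <= 0:
        raise ValueError("f_theta must be positive")
    return PreferredPhase(
        tau_over_two_pi_f=spec.tau / (2.0 * np.pi * spec.f_theta),
        radians=2.0 * np.pi * spec.f_theta * spec.tau * delta,
    )


def harmonic_spacing(
    est,
    prominence_frac: float = 0.005,
    min_separation_bins: int = 2,
) -> float:
    """Median spacing in Hz between successive harmonic peaks of a spectrum.

    ``est`` is a :class:`~cfcsim.spectral_estimation.SpectrumEstimate` of an
    envelope path.  Peaks are detected above ``prominence_frac`` of the
    largest off-DC peak; fewer than two detected peaks raises.  The default
    prominence (0.5%) sits below the second-harmonic power of the default
    order-4 weights (1-6% of the fundamental, biphasic being the weakest)
    while staying above the Hann-taper sidelobe floor (~0.26%).
    """
    power = np.asarray(est.power, dtype=float)
    freqs = np.asarray(est.freqs, dtype=float)
    ref = power[1:].max() if power.size > 1 else 0.0
    if ref <= 0:
        raise ValueError("spectrum has no off-DC power")
    peaks, _ = scipy.signal.find_peaks(
        power, prominence=prominence_frac * ref, distance=min_separation_bins
    )
    peaks = peaks[peaks > 0]
    if peaks.size < 2:
        raise ValueError(
            f"found {peaks.size} harmonic peak(s); need at least 2 to measure spacing"
        )
    return float(np.median(np.diff(freqs[peaks])))
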