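"""Component power spectra and their autocovariance duals.

Spectra are two-sided densities on a uniform frequency grid spanning
``[-f_N, +f_N]`` with ``f_N = 1/(2*delta)``.  The discrete-time
Wiener-Khintchine convention used throughout is

    r_tau = integral_{-f_N}^{+f_N} S(f) exp(+i 2 pi f tau delta) df
    S(f)  = delta * sum_tau r_tau exp(-i 2 pi f tau delta)

so that the process variance is ``r_0 = integral S(f) df`` and a white
process of variance ``sigma**2`` has the constant density ``sigma**2 * delta``.
This is the convention under which the product/convolution duality
``r_a * r_b  <->  (S_a (*) S_b)(f)`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectrumSpec",
    "AcvSeq",
    "NyquistError",
    "frequency_grid",
    "make_theta_spectrum",
    "make_noise_spectrum",
    "make_band_spectrum",
    "spectrum_to_acv",
    "acv_to_spectrum",
    "convolve_spectra",
]

#: relative tolerance for the even-symmetry check of a spectrum
SYMMETRY_RTOL = 1e-9


class NyquistError(ValueError):
    """A requested spectral feature does not fit below the Nyquist frequency."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SpectrumSpec:
    """A two-sided power spectral density sampled on a symmetric grid.

    Parameters
    ----------
    freqs
        Uniform frequency grid in Hz spanning ``[-f_N, +f_N]``; contains 0.
    power
        Nonnegative spectral density at each grid frequency (variance * s).
    delta
        Sample period in seconds.
    label
        Component name (``"theta"``, ``"eta"``, ``"x"``, ...).
    params
        Builder provenance (free-form, serialized to the JSON sidecar).
    """

    freqs: np.ndarray
    power: np.ndarray
    delta: float
    label: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.delta)

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def n_grid(self) -> int:
        return self.freqs.size

    def variance(self) -> float:
        """Process variance ``r_0 = integral S(f) df`` (trapezoid rule)."""
        return float(np.trapezoid(self.power, self.freqs))

    # -- checks -------------------------------------------------------------

    def validate(self) -> None:
        f, p = self.freqs, self.power
        if f.ndim != 1 or f.shape != p.shape:
            raise ValueError("freqs and power must be 1-D arrays of equal size")
        if f.size < 3 or f.size % 2 == 0:
            raise ValueError("grid must have an odd number of points (>= 3)")
        steps = np.diff(f)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("frequency grid must be uniform")
        if not (np.isclose(-f[0], self.nyquist) and np.isclose(f[-1], self.nyquist)):
            raise ValueError("grid must span [-f_N, +f_N]")
        if abs(f[f.size // 2]) > 1e-12 * self.nyquist:
            raise ValueError("grid must contain f = 0")
        scale = p.max(initial=0.0)
        if np.any(p < -1e-12 * scale):
            raise ValueError("spectral density must be nonnegative")
        if np.any(np.abs(p - p[::-1]) > SYMMETRY_RTOL * max(scale, 1e-300) + 1e-300):
            raise ValueError("spectral density must be even in frequency")

    def same_grid(self, other: "SpectrumSpec") -> bool:
        return (
            self.n_grid == other.n_grid
            and np.isclose(self.delta, other.delta)
            and np.allclose(self.freqs, other.freqs)
        )


@dataclass
class AcvSeq:
    """One-sided autocovariance sequence ``r_0 .. r_L`` of a real WSS process.

    Storage is one-sided; the sequence is interpreted as two-sided through the
    even symmetry ``r_{-tau} = r_tau``.
    """

    values: np.ndarray
    delta: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    @property
    def max_lag(self) -> int:
        return self.values.size - 1

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.values.size)

    @property
    def lag_times(self) -> np.ndarray:
        return self.lags * self.delta

    def validate(self) -> None:
        v = self.values
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a nonempty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("autocovariance values must be finite")
        if v[0] < 0:
            raise ValueError("r_0 must be nonnegative")
        # Cauchy-Schwarz with a little numerical headroom.
        if v.size > 1 and np.max(np.abs(v[1:])) > v[0] * (1.0 + 1e-9) + 1e-300:
            raise ValueError("|r_tau| cannot exceed r_0")

    def truncated(self, max_lag: int) -> "AcvSeq":
        if max_lag >= self.values.size:
            raise ValueError("cannot truncate beyond available lags")
        return AcvSeq(self.values[: max_lag + 1].copy(), self.delta, self.label)


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------


def frequency_grid(delta: float, n_grid: int = 8192) -> np.ndarray:
    """Uniform symmetric grid over ``[-f_N, +f_N]`` containing 0.

    An even ``n_grid`` is promoted to ``n_grid + 1`` points so that 0 and both
    endpoints lie exactly on the grid.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if n_grid < 16:
        raise ValueError("n_grid too small")
    m = n_grid + 1 if n_grid % 2 == 0 else n_grid
    f_n = 1.0 / (2.0 * delta)
    return np.linspace(-f_n, f_n, m)


def _normalized(shape: np.ndarray, freqs: np.ndarray, variance: float) -> np.ndarray:
    total = np.trapezoid(shape, freqs)
    if total <= 0:
        raise ValueError("degenerate spectral shape (zero mass)")
    return shape * (variance / total)


# ---------------------------------------------------------------------------
# spectrum builders
# ---------------------------------------------------------------------------


def make_theta_spectrum(
    center_f: float,
    peak_width: float,
    variance: float,
    delta: float = 0.001,
    n_grid: int = 8192,
) -> SpectrumSpec:
    """Spectrum of the slow oscillation: Gaussian peaks at ``+-center_f``.

    ``peak_width`` is the full width at half maximum of each peak; the
    two-sided density integrates to ``variance``.
    """
    if center_f <= 0 or peak_width <= 0 or variance <= 0:
        raise ValueError("center_f, peak_width and variance must be positive")
    freqs = frequency_grid(delta, n_grid)
    f_n = 1.0 / (2.0 * delta)
    if center_f + peak_width / 2.0 >= f_n:
        raise NyquistError(
            f"theta peak at {center_f} Hz (width {peak_width} Hz) exceeds "
            f"Nyquist f_N = {f_n} Hz"
        )
    sigma = peak_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    shape = np.exp(-0.5 * ((freqs - center_f) / sigma) ** 2)
    shape = shape + shape[::-1]  # mirror peak at -center_f
    power = _normalized(shape, freqs, variance)
    return SpectrumSpec(
        freqs,
        power,
        delta,
        label="theta",
        params={
            "builder": "theta",
            "center_f_hz": center_f,
            "peak_width_hz": peak_width,
            "variance": variance,
        },
    )


def make_noise_spectrum(
    alpha: float,
    variance: float,
    floor_f: float = 0.5,
    delta: float = 0.001,
    n_grid: int = 8192,
) -> SpectrumSpec:
    """``1/|f|**alpha`` background-noise spectrum, flattened below ``floor_f``.

    The power law is not integrable at the origin; below ``floor_f`` the
    density is held constant at the power law's value there, giving a finite
    ``r_0``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive (alpha = 0 is white noise, rejected)")
    if variance <= 0:
        raise ValueError("variance must be positive")
    freqs = frequency_grid(delta, n_grid)
    f_n = 1.0 / (2.0 * delta)
    if not 0 < floor_f < f_n:
        raise ValueError("floor_f must lie strictly between 0 and f_N")
    af = np.maximum(np.abs(freqs), floor_f)
    shape = af ** (-alpha)
    power = _normalized(shape, freqs, variance)
    return SpectrumSpec(
        freqs,
        power,
        delta,
        label="eta",
        params={
            "builder": "noise",
            "alpha": alpha,
            "floor_f_hz": floor_f,
            "variance": variance,
        },
    )


def make_band_spectrum(
    f_lo: float,
    f_hi: float,
    variance: float,
    edge_width: float = 4.0,
    delta: float = 0.001,
    n_grid: int = 8192,
) -> SpectrumSpec:
    """Band-limited spectrum for the latent fast process: tapered boxcar.

    Density is flat on ``+-[f_lo, f_hi]`` and rolls off to zero over
    ``edge_width`` Hz with a raised-cosine taper on each edge.
    ``edge_width = 0`` gives an exact boxcar.
    """
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    if variance <= 0 or edge_width < 0:
        raise ValueError("variance must be positive, edge_width nonnegative")
    freqs = frequency_grid(delta, n_grid)
    f_n = 1.0 / (2.0 * delta)
    if f_hi >= f_n:
        raise NyquistError(f"f_hi = {f_hi} Hz is not below Nyquist f_N = {f_n} Hz")
    af = np.abs(freqs)
    if edge_width == 0:
        shape = ((af >= f_lo) & (af <= f_hi)).astype(float)
    else:
        shape = np.zeros_like(af)
        core = (af >= f_lo) & (af <= f_hi)
        shape[core] = 1.0
        lo_ramp = (af >= f_lo - edge_width) & (af < f_lo)
        shape[lo_ramp] = 0.5 * (1.0 + np.cos(np.pi * (f_lo - af[lo_ramp]) / edge_width))
        hi_ramp = (af > f_hi) & (af <= f_hi + edge_width)
        shape[hi_ramp] = 0.5 * (1.0 + np.cos(np.pi * (af[hi_ramp] - f_hi) / edge_width))
    # exact symmetrization (guards against float asymmetry of |f| at +-f grid)
    shape = 0.5 * (shape + shape[::-1])
    power = _normalized(shape, freqs, variance)
    return SpectrumSpec(
        freqs,
        power,
        delta,
        label="x",
        params={
            "builder": "band",
            "f_lo_hz": f_lo,
            "f_hi_hz": f_hi,
            "edge_width_hz": edge_width,
            "variance": variance,
        },
    )


# ---------------------------------------------------------------------------
# Wiener-Khintchine transforms
# ---------------------------------------------------------------------------


def spectrum_to_acv(spec: SpectrumSpec, max_lag: int) -> AcvSeq:
    """Autocovariance ``r_tau = integral S(f) exp(i 2 pi f tau delta) df``.

    The quadrature is the uniform periodic sum over one period of the
    frequency domain (equivalent to the trapezoid rule here, because the two
    endpoint densities coincide by evenness), which for integer lags reduces
    to an inverse DFT of the sampled density.
    """
    m = spec.n_grid - 1  # periodic points, dropping the duplicate +f_N sample
    if max_lag < 0:
        raise ValueError("max_lag must be nonnegative")
    if max_lag > m // 2:
        raise ValueError(
            f"max_lag = {max_lag} exceeds the grid resolution limit {m // 2}; "
            "increase n_grid"
        )
    per = spec.power[:-1]
    r_full = (m * spec.df) * np.fft.ifft(per)
    tau = np.arange(max_lag + 1)
    # grid starts at -f_N, which shifts the DFT by half a period: factor (-1)^tau
    r = r_full[: max_lag + 1] * np.where(tau % 2 == 0, 1.0, -1.0)
    r0 = float(np.real(r[0]))
    imag = float(np.max(np.abs(np.imag(r))))
    if imag > 1e-10 * max(r0, 1e-300):
        raise ValueError("imaginary residual too large; spectrum not symmetric")
    return AcvSeq(np.real(r), spec.delta, spec.label)


def acv_to_spectrum(
    acv: AcvSeq, n_grid: int = 8192, clip_negative: bool = True
) -> SpectrumSpec:
    """Discrete-time Fourier transform of the symmetrized sequence.

    ``S(f) = delta * (r_0 + 2 sum_{tau>=1} r_tau cos(2 pi f tau delta))``.
    Small negative excursions from truncating the lag sequence are clipped to
    zero (fraction recorded in ``params``).
    """
    freqs = frequency_grid(acv.delta, n_grid)
    power = np.full(freqs.size, acv.values[0], dtype=float)
    # chunked accumulation keeps memory bounded for long lag sequences
    block = 2048
    for start in range(1, acv.values.size, block):
        tau = np.arange(start, min(start + block, acv.values.size))
        power += 2.0 * (
            np.cos(2.0 * np.pi * np.outer(freqs, tau) * acv.delta) @ acv.values[tau]
        )
    power *= acv.delta
    power = 0.5 * (power + power[::-1])
    neg = power < 0
    clipped_frac = float(np.mean(neg))
    if clip_negative:
        power = np.where(neg, 0.0, power)
    return SpectrumSpec(
        freqs,
        power,
        acv.delta,
        label=acv.label,
        params={"builder": "acv_dtft", "clipped_fraction": clipped_frac},
    )


def convolve_spectra(a: SpectrumSpec, b: SpectrumSpec) -> SpectrumSpec:
    """Circular convolution ``(S_a (*) S_b)(f)`` on the periodic domain.

    This is the frequency-domain dual of the lag-domain product
    ``r^a_tau * r^b_tau`` and gives the spectrum of a product of independent
    zero-mean processes.
    """
    if not a.same_grid(b):
        raise ValueError("spectra must share the same frequency grid and delta")
    m = a.n_grid - 1
    half = m // 2
    pa = a.power[:-1]
    # align b so index arithmetic matches f_k - f_j on the [-f_N, f_N) period
    pb = np.roll(b.power[:-1], -half)
    conv = np.fft.ifft(np.fft.fft(pa) * np.fft.fft(pb)).real * a.df
    conv = np.append(conv, conv[0])
    conv = 0.5 * (conv + conv[::-1])
    conv = np.maximum(conv, 0.0)
    label = f"{a.label}*{b.label}" if a.label and b.label else "convolution"
    return SpectrumSpec(a.freqs, conv, a.delta, label=label, params={"builder": "convolution"})
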