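"""Exact simulation of WSS Gaussian sample paths.

Two independent exact samplers are provided:

* the Toeplitz covariance square-root method (``covariance_sqrt`` +
  ``draw_path``): form the n x n Toeplitz covariance ``R`` from the
  autocovariance sequence, take its symmetric eigendecomposition square root
  and multiply an IID standard-normal vector, ``path = R^{1/2} v``;
* circulant embedding (``circulant_draw``): embed the autocovariance in a
  circulant matrix diagonalized by the DFT and synthesize in the frequency
  domain.

The first is the reference method; the second serves as an independent
cross-check and as the practical sampler for long paths, where an O(n^3)
eigendecomposition is out of reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .spectra import AcvSeq, SpectrumSpec, spectrum_to_acv

__all__ = [
    "CovFactor",
    "SamplePath",
    "Ensemble",
    "toeplitz_covariance",
    "covariance_sqrt",
    "draw_path",
    "draw_ensemble",
    "component_factor",
    "simulate_component",
    "simulate_ensemble",
    "circulant_draw",
    "circulant_ensemble",
]


@dataclass
class SamplePath:
    """One length-n realization of a named component."""

    values: np.ndarray
    delta: float
    label: str = ""
    seed: object = None
    #: boolean mask; False marks boundary samples invalidated by lagging
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("a sample path is 1-D")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask must match values")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("sample-path values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.n, dtype=bool)
        return self.valid

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.delta


@dataclass
class Ensemble:
    """Many realizations of one component with shared n and delta."""

    paths: list
    base_seed: object = None

    def __post_init__(self) -> None:
        if not self.paths:
            raise ValueError("ensemble cannot be empty")
        n0, d0 = self.paths[0].n, self.paths[0].delta
        for p in self.paths:
            if p.n != n0 or not np.isclose(p.delta, d0):
                raise ValueError("all ensemble members must share n and delta")

    @property
    def size(self) -> int:
        return len(self.paths)

    @property
    def n(self) -> int:
        return self.paths[0].n

    @property
    def delta(self) -> float:
        return self.paths[0].delta

    @property
    def label(self) -> str:
        return self.paths[0].label

    def as_matrix(self) -> np.ndarray:
        """(n, size) matrix: rows = time, columns = realizations."""
        return np.column_stack([p.values for p in self.paths])

    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        for p in self.paths:
            mask &= p.valid_mask
        return mask


@dataclass
class CovFactor:
    """Symmetric square root of an n x n Toeplitz covariance matrix."""

    factor: np.ndarray
    delta: float
    clip_count: int = 0
    label: str = ""
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.factor.shape[0]


# ---------------------------------------------------------------------------
# Toeplitz square-root sampler
# ---------------------------------------------------------------------------


def _extend_acv(acv: AcvSeq, n: int) -> np.ndarray:
    """First column of the covariance: zero-extend beyond available lags."""
    col = np.zeros(n)
    k = min(n, acv.values.size)
    col[:k] = acv.values[:k]
    return col


def toeplitz_covariance(acv: AcvSeq, n: int) -> np.ndarray:
    """The n x n covariance matrix ``R[t, t+tau] = r_tau`` (constant diagonals)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return scipy.linalg.toeplitz(_extend_acv(acv, n))


def covariance_sqrt(
    R: np.ndarray, clip_tol: float = 1e-10, delta: float = 1.0, label: str = ""
) -> CovFactor:
    """Symmetric matrix square root of ``R`` via eigendecomposition.

    Eigenvalues in ``[-clip_tol * lambda_max, 0)`` — numerical leakage from a
    truncated but valid autocovariance — are clipped to zero; anything more
    negative signals a genuinely non-PSD input and raises.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, rtol=1e-8, atol=1e-12 * max(abs(R).max(), 1.0)):
        raise ValueError("R must be symmetric")
    w, v = scipy.linalg.eigh(R)
    w_max = max(w[-1], 0.0)
    floor = -clip_tol * max(w_max, 1e-300)
    if w[0] < floor:
        raise ValueError(
            f"covariance is not positive semidefinite: min eigenvalue {w[0]:.3e} "
            f"< {floor:.3e}"
        )
    clip_count = int(np.sum(w < 0))
    w = np.maximum(w, 0.0)
    factor = (v * np.sqrt(w)) @ v.T
    factor = 0.5 * (factor + factor.T)
    return CovFactor(factor, delta, clip_count, label, params={"clip_tol": clip_tol})


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _generator(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def draw_path(factor: CovFactor, rng_seed) -> SamplePath:
    """One draw ``path = R^{1/2} v`` with ``v`` IID standard normal."""
    rng = _generator(rng_seed)
    v = rng.standard_normal(factor.n)
    return SamplePath(factor.factor @ v, factor.delta, factor.label, seed=rng_seed)


def draw_ensemble(factor: CovFactor, size: int, base_seed) -> Ensemble:
    """Ensemble of independent draws from per-realization spawned substreams."""
    if size < 1:
        raise ValueError("ensemble size must be >= 1")
    children = _seed_sequence(base_seed).spawn(size)
    v = np.column_stack(
        [np.random.default_rng(c).standard_normal(factor.n) for c in children]
    )
    values = factor.factor @ v  # one matmul for the whole ensemble
    paths = [
        SamplePath(values[:, j], factor.delta, factor.label, seed=children[j])
        for j in range(size)
    ]
    return Ensemble(paths, base_seed=base_seed)


def component_factor(spec: SpectrumSpec, n: int, clip_tol: float = 1e-10) -> CovFactor:
    """Spectrum -> autocovariance -> Toeplitz covariance -> symmetric root."""
    acv = spectrum_to_acv(spec, min(n - 1, (spec.n_grid - 1) // 2))
    R = toeplitz_covariance(acv, n)
    return covariance_sqrt(R, clip_tol=clip_tol, delta=spec.delta, label=spec.label)


def simulate_component(spec: SpectrumSpec, n: int, rng_seed) -> SamplePath:
    """Draw one exact path of the component defined by ``spec``."""
    return draw_path(component_factor(spec, n), rng_seed)


def simulate_ensemble(spec: SpectrumSpec, n: int, size: int, base_seed) -> Ensemble:
    return draw_ensemble(component_factor(spec, n), size, base_seed)


# ---------------------------------------------------------------------------
# circulant-embedding sampler (independent oracle; long-path workhorse)
# ---------------------------------------------------------------------------


def _circulant_eigenvalues(acv: AcvSeq, n: int, tol: float) -> np.ndarray:
    # the embedding period must cover both the requested path and the full
    # decay of the autocovariance, else wraparound injects negative eigenvalues
    need = 2 * max(n - 1, acv.max_lag, 1)
    m = 1
    while m < need:
        m *= 2
    half = m // 2
    col = np.zeros(m)
    k = min(half + 1, acv.values.size)
    col[:k] = acv.values[:k]
    col[m - k + 1 :] = acv.values[1:k][::-1]
    lam = np.fft.fft(col).real
    lam_max = max(lam.max(), 1e-300)
    if lam.min() < -tol * lam_max:
        raise ValueError(
            f"circulant embedding failed: eigenvalue {lam.min():.3e} below "
            f"-{tol:.1e} * lambda_max"
        )
    return np.maximum(lam, 0.0)


def circulant_draw(acv: AcvSeq, n: int, rng_seed, tol: float = 1e-8) -> SamplePath:
    """Stationary Gaussian path with autocovariance ``acv`` via circulant embedding.

    Independent of the Toeplitz-root pipeline: synthesis happens in the DFT
    domain of the embedding circulant.  Exact (up to eigenvalue clipping at
    ``tol``) and O(n log n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lam = _circulant_eigenvalues(acv, n, tol)
    m = lam.size
    rng = _generator(rng_seed)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.sqrt(2.0) * np.real(np.fft.ifft(np.sqrt(lam) * z * np.sqrt(m / 2.0)))
    return SamplePath(x[:n], acv.delta, acv.label, seed=rng_seed)


def circulant_ensemble(acv: AcvSeq, n: int, size: int, base_seed) -> Ensemble:
    children = _seed_sequence(base_seed).spawn(size)
    paths = [circulant_draw(acv, n, np.random.default_rng(c)) for c in children]
    for p, c in zip(paths, children):
        p.seed = c
    return Ensemble(paths, base_seed=base_seed)
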