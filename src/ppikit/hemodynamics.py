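"""Hemodynamic building blocks for PPI analysis.

The BOLD signal is modelled as the convolution of neuronal activity with a
canonical hemodynamic response function (HRF).  This module provides the
canonical double-gamma HRF, causal convolution on a scan grid, the discrete
cosine transform (DCT) high-pass basis used to model slow scanner drifts,
regularized deconvolution (estimation of the neuronal-level series ``z`` from
an observed BOLD series ``x`` under ``x = z * hrf + eps``), and a simple
periodogram for spectral diagnostics.

Deconvolution is a frequency-weighted ridge regression on a full cosine
basis: the penalty on basis column ``j`` is proportional to ``f_j**2`` where
``f_j`` is the column's frequency in Hz, so high-frequency components are
shrunk toward zero.  The ridge weight is chosen by generalized
cross-validation (GCV) by default and can be fixed explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import linalg
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HRFSpec",
    "BoldSeries",
    "NeuronalSeries",
    "DCTBasis",
    "canonical_hrf",
    "convolve_causal",
    "dct_highpass",
    "deconvolve",
    "reconvolve",
    "power_spectrum",
]


@dataclass(frozen=True)
class HRFSpec:
    """Parameters of the canonical double-gamma HRF.

    The kernel is the difference of two gamma densities: a positive response
    peaking near ``response_delay`` seconds and an undershoot peaking near
    ``undershoot_delay`` seconds, scaled down by ``undershoot_ratio``.
    ``dt`` is the sampling step at which the kernel is evaluated (normally
    the run's TR).
    """

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    kernel_length: float = 32.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "response_delay",
            "undershoot_delay",
            "response_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "dt",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"HRFSpec.{name} must be positive")
        if not self.kernel_length > self.response_delay:
            raise ValueError("kernel_length must exceed response_delay")

    def at_dt(self, dt: float) -> "HRFSpec":
        """Same response shape sampled at a different step (e.g. a run's TR)."""
        return dataclasses.replace(self, dt=dt)


@dataclass
class BoldSeries:
    """A sampled BOLD time series with its repetition time (TR)."""

    values: np.ndarray
    tr: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("BoldSeries.values must be one-dimensional")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BoldSeries contains non-finite values")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]


@dataclass
class NeuronalSeries:
    """A deconvolved (neuronal-level) series with its reconvolved fit.

    ``residual`` is the part of the source BOLD series not explained by the
    reconvolved estimate: ``source = reconvolved + residual``.
    """

    values: np.ndarray
    tr: float
    basis_order: int
    regularization: float
    residual: np.ndarray
    reconvolved: np.ndarray


@dataclass
class DCTBasis:
    """Discrete cosine drift basis; column 0 is the constant."""

    matrix: np.ndarray
    nominal_cutoff: float
    effective_cutoff: float
    n_drift: int

    @property
    def drift_columns(self) -> np.ndarray:
        return self.matrix[:, 1:]


def canonical_hrf(spec: HRFSpec) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a regular grid.

    Returns a kernel of length ``ceil(kernel_length / dt)`` evaluated at
    ``t = 0, dt, 2*dt, ...``.  The gamma shapes are delay/dispersion with
    scale equal to the dispersion, so the positive lobe peaks close to
    ``response_delay - response_dispersion`` (5 s with the defaults).
    """
    n = int(np.ceil(spec.kernel_length / spec.dt))
    t = np.arange(n) * spec.dt
    peak = gamma_dist.pdf(
        t, spec.response_delay / spec.response_dispersion, scale=spec.response_dispersion
    )
    under = gamma_dist.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    kernel = peak - under / spec.undershoot_ratio
    if not np.all(np.isfinite(kernel)):
        raise ValueError("HRF kernel evaluated to non-finite values")
    return kernel


def convolve_causal(x: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    """Causal discrete convolution truncated to ``len(x)``, scaled by ``dt``.

    The ``dt`` scaling makes the output approximate the continuous-time
    convolution integral, so amplitudes are comparable across runs sampled
    at different TRs.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    return dt * np.convolve(x, kernel)[: x.shape[0]]


def dct_highpass(n_scans: int, tr: float, nominal_cutoff: float = 128.0) -> DCTBasis:
    """DCT high-pass drift basis for a run of ``n_scans`` volumes at ``tr``.

    The number of retained columns is ``floor(2 * n_scans * tr /
    nominal_cutoff + 1)`` including the constant; the effective cutoff in Hz
    is ``n_drift / (2 * n_scans * tr)``.  For the study's two runs (225
    volumes at TR 0.645 s, 93 volumes at TR 1.4 s) with the conventional
    128 s cutoff this gives 0.0069 Hz and 0.0077 Hz.
    """
    if n_scans < 2:
        raise ValueError("n_scans must be at least 2")
    if not nominal_cutoff > 0:
        raise ValueError("nominal_cutoff must be positive")
    if nominal_cutoff < 2 * tr:
        raise ValueError(
            f"cutoff period {nominal_cutoff} s is shorter than 2*TR = {2 * tr} s; "
            "the drift basis would be degenerate"
        )
    total = 2.0 * n_scans * tr
    k = int(np.floor(total / nominal_cutoff + 1.0))
    k = max(k, 1)
    matrix = _cosine_columns(n_scans, k)
    n_drift = k - 1
    return DCTBasis(
        matrix=matrix,
        nominal_cutoff=nominal_cutoff,
        effective_cutoff=n_drift / total,
        n_drift=n_drift,
    )


def _cosine_columns(n_scans: int, k: int) -> np.ndarray:
    """First ``k`` orthonormal DCT-II basis columns (column 0 constant)."""
    n = np.arange(n_scans)
    j = np.arange(k)
    mat = np.cos(np.pi * (2.0 * n[:, None] + 1.0) * j[None, :] / (2.0 * n_scans))
    mat *= np.sqrt(2.0 / n_scans)
    mat[:, 0] = np.sqrt(1.0 / n_scans)
    return mat


# GCV grid for the ridge weight; spans effectively-unpenalized to heavily
# smoothed fits.  The weight multiplies f_j**2 with f_j in Hz.
_GCV_GRID = tuple(np.logspace(-6.0, 8.0, 29))


class _DeconvOperator:
    """Precomputed pieces of the penalized deconvolution for one scan grid.

    Holds the cosine basis D, its HRF-convolved version A, the Gram matrix
    and Cholesky factors of (A'A + w * P) for every grid weight, and the
    effective degrees of freedom tr(H(w)) used by GCV.  All of this depends
    only on (n_scans, tr, HRF spec, basis_order), never on the data, so it
    is cached and shared across series.
    """

    def __init__(self, n_scans: int, tr: float, spec: HRFSpec, basis_order: int):
        self.n_scans = n_scans
        self.tr = tr
        self.basis = _cosine_columns(n_scans, basis_order)
        kernel = canonical_hrf(spec.at_dt(tr))
        # column-wise causal convolution of the basis
        conv = np.empty_like(self.basis)
        for jcol in range(basis_order):
            conv[:, jcol] = convolve_causal(self.basis[:, jcol], kernel, tr)
        self.design = conv
        self.gram = conv.T @ conv
        freqs = np.arange(basis_order) / (2.0 * n_scans * tr)
        self.penalty = freqs**2
        self._factors: dict[float, np.ndarray] = {}
        self._edf: dict[float, float] = {}

    def _factor(self, weight: float) -> np.ndarray:
        f = self._factors.get(weight)
        if f is None:
            system = self.gram + weight * np.diag(self.penalty)
            try:
                f = linalg.cho_factor(system)
            except linalg.LinAlgError as exc:  # pragma: no cover - pathological
                raise np.linalg.LinAlgError(
                    f"penalized deconvolution system singular at weight {weight:g}; "
                    "increase the regularization weight"
                ) from exc
            self._factors[weight] = f
        return f

    def edf(self, weight: float) -> float:
        """Effective degrees of freedom tr(A (A'A + wP)^-1 A')."""
        e = self._edf.get(weight)
        if e is None:
            e = float(np.trace(linalg.cho_solve(self._factor(weight), self.gram)))
            self._edf[weight] = e
        return e

    def solve(self, x: np.ndarray, weight: float) -> np.ndarray:
        return linalg.cho_solve(self._factor(weight), self.design.T @ x)

    def gcv(self, x: np.ndarray, grid=_GCV_GRID) -> float:
        """Ridge weight at the first local minimum of the GCV curve.

        The curve is scanned from small weights upward and the first local
        minimum is returned.  For series without reliable smooth structure
        the curve is nearly flat at large weights and its global minimum
        sits at the fully-shrunk end (a degenerate constant fit); the first
        interior minimum is the standard guard against that.
        """
        n = self.n_scans
        scores = []
        for w in grid:
            coef = self.solve(x, w)
            rss = float(np.sum((x - self.design @ coef) ** 2))
            denom = n - self.edf(w)
            scores.append(n * rss / denom**2 if denom > 0 else np.inf)
        for i in range(len(grid)):
            left_ok = i == 0 or scores[i] <= scores[i - 1]
            right_ok = i == len(grid) - 1 or scores[i] <= scores[i + 1]
            if left_ok and right_ok:
                return grid[i]
        return grid[int(np.argmin(scores))]


@lru_cache(maxsize=16)
def _get_operator(n_scans: int, tr: float, spec: HRFSpec, basis_order: int) -> _DeconvOperator:
    return _DeconvOperator(n_scans, tr, spec, basis_order)


def deconvolve(
    x: BoldSeries,
    spec: HRFSpec | None = None,
    basis_order: int | None = None,
    reg_weight: float | None = None,
) -> NeuronalSeries:
    """Estimate the neuronal-level series behind a BOLD series.

    Solves ``x ~= (D @ w) * hrf`` for cosine-basis coefficients ``w`` by
    penalized least squares with penalty ``reg_weight * f_j**2`` on
    coefficient ``j`` (``f_j`` the basis frequency in Hz), so the estimate
    is smooth at high frequencies.  ``reg_weight=None`` selects the weight
    by generalized cross-validation.

    Parameters
    ----------
    x : BoldSeries
        Observed series.
    spec : HRFSpec, optional
        HRF shape; defaults to the canonical parameters.
    basis_order : int, optional
        Number of cosine columns; defaults to ``n_scans`` (full basis).
    reg_weight : float, optional
        Fixed ridge weight; ``None`` means GCV selection.
    """
    if spec is None:
        spec = HRFSpec()
    n = x.n_scans
    if basis_order is None:
        basis_order = n
    if basis_order > n:
        raise ValueError("basis_order cannot exceed the number of scans")
    op = _get_operator(n, x.tr, spec, basis_order)
    weight = op.gcv(x.values) if reg_weight is None else float(reg_weight)
    coef = op.solve(x.values, weight)
    fit = op.design @ coef
    return NeuronalSeries(
        values=op.basis @ coef,
        tr=x.tr,
        basis_order=basis_order,
        regularization=weight,
        residual=x.values - fit,
        reconvolved=fit,
    )


def reconvolve(z: NeuronalSeries | np.ndarray, spec: HRFSpec, tr: float) -> np.ndarray:
    """Convolve a neuronal-level series back to the BOLD level."""
    values = z.values if isinstance(z, NeuronalSeries) else np.asarray(z, dtype=float)
    return convolve_causal(values, canonical_hrf(spec.at_dt(tr)), tr)


def power_spectrum(x: BoldSeries) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of a mean-removed series.

    Returns frequencies from 0 to the Nyquist rate ``1/(2*tr)`` and power
    ``|X_k|**2 / n`` with the non-DC, non-Nyquist bins doubled, so the total
    power equals ``variance * n_scans``.
    """
    n = x.n_scans
    if n < 4:
        raise ValueError("power_spectrum needs at least 4 samples")
    centered = x.values - x.values.mean()
    spectrum = np.fft.rfft(centered)
    power = np.abs(spectrum) ** 2 / n
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=x.tr)
    return freqs, power


def band_power(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Total periodogram power inside a frequency band [lo, hi]."""
    mask = (freqs >= lo) & (freqs <= hi)
    return float(power[mask].sum())
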