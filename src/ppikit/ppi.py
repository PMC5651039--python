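"""Psychophysiological interaction (PPI) regressors, GLMs, and edge matrices.

A PPI effect is the regression interaction between a seed region's time
series (the physiological variable ``x_Physio``) and a task indicator (the
psychological variable ``z_Psych``).  Two constructions are in common use:

* non-deconvolution: the boxcar is convolved with the HRF, centered, and
  multiplied with the raw seed series — ``x_PPI = center(z * hrf) . x``;
* deconvolution: the seed series is deconvolved to the neuronal level, the
  interaction is formed there with the centered boxcar, and the product is
  convolved back — ``x_PPI = (center(z) . z_physio) * hrf``.

For a block design slower than the hemodynamic response the two terms are
nearly collinear; for fast designs they diverge, which is the reason the
choice matters.  Estimation is ordinary least squares throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import NuisanceSet, TaskDesign, sample_boxcar
from .hemodynamics import (
    BoldSeries,
    HRFSpec,
    canonical_hrf,
    convolve_causal,
    deconvolve,
)

__all__ = [
    "PPIDesign",
    "GLMResult",
    "EdgeMatrix",
    "eigenvariate",
    "build_ppi_regressors",
    "fit_glm",
    "edge_matrix",
    "symmetrize",
]

METHODS = ("deconv", "nondeconv")


@dataclass
class PPIDesign:
    """Assembled PPI regression design for one seed/run/method.

    Columns, in order: task (HRF-convolved centered boxcar), physiological
    (raw seed series), PPI term, optional covariates, constant.
    """

    psych_conv: np.ndarray
    physio: np.ndarray
    ppi: np.ndarray
    method: str
    covariates: np.ndarray | None = None
    include_constant: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        n = self.psych_conv.shape[0]
        if self.physio.shape[0] != n or self.ppi.shape[0] != n:
            raise ValueError("design columns differ in length")
        if self.covariates is not None and self.covariates.shape[0] != n:
            raise ValueError("covariates differ in length from design columns")

    def matrix(self) -> tuple[np.ndarray, list[str]]:
        cols = [self.psych_conv, self.physio, self.ppi]
        names = ["psych", "physio", "ppi"]
        if self.covariates is not None:
            for i in range(self.covariates.shape[1]):
                cols.append(self.covariates[:, i])
                names.append(f"cov{i + 1}")
        if self.include_constant:
            cols.append(np.ones_like(self.psych_conv))
            names.append("constant")
        return np.column_stack(cols), names


@dataclass
class GLMResult:
    """OLS fit summary: coefficients, standard errors, t statistics."""

    betas: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    r2: float
    names: list[str]

    def __getitem__(self, name: str) -> float:
        return float(self.betas[self.names.index(name)])

    def tstat(self, name: str) -> float:
        return float(self.t[self.names.index(name)])


@dataclass
class EdgeMatrix:
    """ROI x ROI matrix of PPI betas; diagonal is undefined (NaN)."""

    values: np.ndarray
    roi_labels: list[str]
    symmetrized: bool
    method: str = ""

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def n_unique(self) -> int:
        """Number of unique off-diagonal effects after symmetrization."""
        r = self.n_roi
        return r * (r - 1) // 2

    def unique_effects(self) -> np.ndarray:
        """Upper-triangle vector of the (symmetrized) matrix."""
        iu = np.triu_indices(self.n_roi, k=1)
        return self.values[iu]


def eigenvariate(
    roi_block: np.ndarray,
    adjust: NuisanceSet | np.ndarray | None = None,
    tr: float = 1.0,
    label: str = "roi",
) -> BoldSeries:
    """Summary time series of an ROI: first singular vector of its voxels.

    Nuisance effects (plus an intercept) are regressed out of every voxel
    first; the first left singular vector of the residual block is scaled by
    its singular value over ``sqrt(n_voxels)`` and sign-anchored so that its
    correlation with the ROI mean series is nonnegative.
    """
    block = np.asarray(roi_block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    if block.shape[1] < 1:
        raise ValueError("ROI block has no voxels")
    if not np.any(block):
        raise ValueError("ROI block is identically zero")
    n = block.shape[0]
    if adjust is not None:
        cols = adjust.columns if isinstance(adjust, NuisanceSet) else np.asarray(adjust, float)
        x = np.column_stack([np.ones(n), cols])
        beta, *_ = np.linalg.lstsq(x, block, rcond=None)
        block = block - x @ beta
    u, s, _ = np.linalg.svd(block, full_matrices=False)
    series = u[:, 0] * (s[0] / np.sqrt(block.shape[1]))
    mean_series = block.mean(axis=1)
    if np.dot(series - series.mean(), mean_series - mean_series.mean()) < 0:
        series = -series
    return BoldSeries(series, tr=tr, label=label)


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def build_ppi_regressors(
    seed: BoldSeries,
    design: TaskDesign,
    spec: HRFSpec | None = None,
    method: str = "nondeconv",
    covariates: np.ndarray | None = None,
    reg_weight: float | None = None,
) -> PPIDesign:
    """Construct the PPI design for one seed by either method.

    The psychological column is ``center(boxcar * hrf)`` and the
    physiological column is the raw seed series under both methods; only the
    interaction column differs.  Centering happens after convolution for the
    non-deconvolution method and at the neuronal (boxcar) level for the
    deconvolution method.
    """
    if spec is None:
        spec = HRFSpec()
    if abs(seed.tr - design.tr) > 1e-9:
        raise ValueError("seed series and task design are on different scan grids")
    if seed.n_scans != design.n_scans:
        raise ValueError("seed series and task design differ in scan count")
    kernel = canonical_hrf(spec.at_dt(design.tr))
    box = sample_boxcar(design)
    psych_conv = _center(convolve_causal(box, kernel, design.tr))
    if method == "nondeconv":
        ppi = psych_conv * seed.values
    elif method == "deconv":
        try:
            z = deconvolve(seed, spec, reg_weight=reg_weight)
        except Exception as exc:
            raise RuntimeError(
                f"deconvolution failed for seed '{seed.label}' (deconv method): {exc}"
            ) from exc
        ppi = convolve_causal(_center(box) * z.values, kernel, design.tr)
    else:
        raise ValueError(f"method must be one of {METHODS}")
    return PPIDesign(
        psych_conv=psych_conv,
        physio=seed.values.copy(),
        ppi=ppi,
        method=method,
        covariates=covariates,
    )


_T_SENTINEL = np.inf


def fit_glm(y: BoldSeries | np.ndarray, design: PPIDesign | np.ndarray, names=None) -> GLMResult:
    """Ordinary least squares fit of one series against a design.

    ``design`` may be a PPIDesign (a constant is appended per its flag) or a
    plain matrix with ``names``.  Raises on rank deficiency, naming the
    offending columns.  A perfect fit yields infinite t, reported as an
    ``inf`` sentinel with a warning rather than dropped.
    """
    yv = y.values if isinstance(y, BoldSeries) else np.asarray(y, dtype=float)
    if isinstance(design, PPIDesign):
        x, names = design.matrix()
    else:
        x = np.asarray(design, dtype=float)
        if names is None:
            names = [f"x{i + 1}" for i in range(x.shape[1])]
    n, p = x.shape
    if yv.shape[0] != n:
        raise ValueError("response and design differ in length")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise np.linalg.LinAlgError(
            "design is rank deficient; collinear columns: " + ", ".join(_collinear(x, names))
        )
    xtx_inv = np.linalg.inv(x.T @ x)
    betas = xtx_inv @ (x.T @ yv)
    resid = yv - x @ betas
    df = n - p
    rss = float(resid @ resid)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    sigma2 = rss / df if df > 0 else np.nan
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = betas / se
    if rss <= max(1e-12 * max(tss, 1.0), 0.0):
        warnings.warn("perfect fit: t statistics reported as inf sentinels", stacklevel=2)
        t = np.where(betas == 0, 0.0, np.sign(betas) * _T_SENTINEL)
    return GLMResult(betas=betas, se=se, t=t, df=df, r2=r2, names=list(names))


def _collinear(x: np.ndarray, names) -> list[str]:
    """Names of columns that add no rank to the preceding ones."""
    bad = []
    basis: list[np.ndarray] = []
    for i in range(x.shape[1]):
        resid = x[:, i].astype(float).copy()
        for b in basis:
            resid -= (resid @ b) * b
        norm = np.linalg.norm(resid)
        if norm < 1e-8 * max(1.0, np.linalg.norm(x[:, i])):
            bad.append(names[i])
        else:
            basis.append(resid / norm)
    return bad or list(names)


def symmetrize(values: np.ndarray) -> np.ndarray:
    """Average corresponding upper and lower off-diagonal elements."""
    sym = (values + values.T) / 2.0
    np.fill_diagonal(sym, np.nan)
    return sym


def edge_matrix(
    roi_series: list[BoldSeries],
    design: TaskDesign,
    spec: HRFSpec | None = None,
    method: str = "nondeconv",
    reg_weight: float | None = None,
    return_t: bool = False,
) -> EdgeMatrix | tuple[EdgeMatrix, np.ndarray]:
    """PPI betas between every ordered ROI pair, symmetrized.

    For seed ``i`` and target ``j != i`` the PPI beta comes from the OLS fit
    of the target on ``[psych, physio_i, ppi_i, constant]`` — covariates are
    omitted because nuisance effects are assumed already regressed out of
    the ROI series.  The (i, j) and (j, i) betas are averaged, giving
    ``R(R-1)/2`` unique effects (190 for 20 ROIs).

    All targets share the seed's design, so each seed is solved once with a
    multi-column right-hand side; the result matches per-pair ``fit_glm``
    calls to numerical precision.
    """
    r = len(roi_series)
    if r < 2:
        raise ValueError("edge_matrix needs at least two ROI series")
    n = roi_series[0].n_scans
    for s in roi_series:
        if s.n_scans != n or abs(s.tr - roi_series[0].tr) > 1e-9:
            raise ValueError("ROI series are not on a common scan grid")
    y_all = np.column_stack([s.values for s in roi_series])
    betas = np.full((r, r), np.nan)
    tvals = np.full((r, r), np.nan)
    for i in range(r):
        try:
            pdesign = build_ppi_regressors(
                roi_series[i], design, spec, method=method, reg_weight=reg_weight
            )
            x, names = pdesign.matrix()
            ppi_idx = names.index("ppi")
            rank = np.linalg.matrix_rank(x)
            if rank < x.shape[1]:
                raise np.linalg.LinAlgError(
                    "rank-deficient design; collinear columns: "
                    + ", ".join(_collinear(x, names))
                )
            xtx_inv = np.linalg.inv(x.T @ x)
            coefs = xtx_inv @ (x.T @ y_all)
            resid = y_all - x @ coefs
            df = n - x.shape[1]
            sigma2 = (resid**2).sum(axis=0) / df
            se = np.sqrt(np.maximum(sigma2 * xtx_inv[ppi_idx, ppi_idx], 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                trow = coefs[ppi_idx] / se
        except Exception as exc:
            raise RuntimeError(f"PPI fit failed for seed ROI index {i}: {exc}") from exc
        for j in range(r):
            if j == i:
                continue
            betas[i, j] = coefs[ppi_idx, j]
            tvals[i, j] = trow[j]
    labels = [s.label or f"roi{i + 1}" for i, s in enumerate(roi_series)]
    mat = EdgeMatrix(values=symmetrize(betas), roi_labels=labels, symmetrized=True, method=method)
    if return_t:
        return mat, symmetrize(tvals)
    return mat
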