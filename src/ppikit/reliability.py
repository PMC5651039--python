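"""Reproducibility and test-retest reliability between two runs.

Reproducibility is quantified as the Dice overlap of suprathreshold
statistical maps (under a common-t or a matched-percentile thresholding
strategy); reliability as the intraclass correlation (ICC) of per-subject
effects between runs; measurement error as a coefficient of variation
computed on the log scale (within-subject variance of the two log values,
averaged over subjects, back-transformed and expressed in percent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiceCurve",
    "dice",
    "dice_curves",
    "icc",
    "icc_map",
    "coefficient_of_variation",
    "DEFAULT_T_GRID",
    "DEFAULT_PERCENTILE_GRID",
]

# Common-t thresholds span roughly one-tailed p < 0.05 (t ~ 1.7 at df ~ 137)
# up to t = 7; percentile thresholds start at the 80th percentile.
DEFAULT_T_GRID = np.round(np.arange(1.7, 7.0 + 1e-9, 0.1), 10)
DEFAULT_PERCENTILE_GRID = np.round(np.arange(80.0, 99.5 + 1e-9, 0.5), 10)


@dataclass
class DiceCurve:
    thresholds: np.ndarray
    dice: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("threshold grid must be increasing")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); 0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks differ in shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)


def dice_curves(
    t_a: np.ndarray,
    t_b: np.ndarray,
    strategy: str = "t_threshold",
    grid: np.ndarray | None = None,
    sign: int = 1,
) -> DiceCurve:
    """Dice overlap of two t maps as a function of threshold.

    ``sign=-1`` examines negative effects (both maps are negated first).
    Under ``t_threshold`` both maps are cut at a common t value; under
    ``percentile`` each map is cut at its own percentile, so the
    suprathreshold counts match between maps up to ties.  NaN entries
    (e.g. matrix diagonals) never enter a mask.
    """
    a = sign * np.asarray(t_a, dtype=float)
    b = sign * np.asarray(t_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps differ in shape")
    if strategy not in ("t_threshold", "percentile"):
        raise ValueError("strategy must be 't_threshold' or 'percentile'")
    if grid is None:
        grid = DEFAULT_T_GRID if strategy == "t_threshold" else DEFAULT_PERCENTILE_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    finite = np.isfinite(a) & np.isfinite(b)
    coeffs = np.empty(grid.size)
    for k, g in enumerate(grid):
        if strategy == "t_threshold":
            mask_a = finite & (a >= g)
            mask_b = finite & (b >= g)
        else:
            thr_a = np.percentile(a[np.isfinite(a)], g)
            thr_b = np.percentile(b[np.isfinite(b)], g)
            mask_a = finite & (a >= thr_a)
            mask_b = finite & (b >= thr_b)
        coeffs[k] = dice(mask_a, mask_b)
    return DiceCurve(thresholds=grid, dice=coeffs, strategy=strategy)


def _icc_mean_squares(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Two-way ANOVA mean squares for a subjects x runs (x units) array."""
    n, k = x.shape[0], x.shape[1]
    grand = x.mean(axis=(0, 1))
    subj_means = x.mean(axis=1)
    run_means = x.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum(axis=0)
    ss_run = n * ((run_means - grand) ** 2).sum(axis=0)
    ss_total = ((x - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_subj - ss_run
    ms_subj = ss_subj / (n - 1)
    ms_run = ss_run / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_subj, ms_run, ms_err, n, k


def icc(x: np.ndarray, kind: str = "icc31") -> float:
    """Intraclass correlation of a subjects x runs matrix.

    ``icc31`` is the two-way mixed, single-measure, consistency form
    ICC(3,1) = (MS_subj - MS_err) / (MS_subj + (k-1) MS_err) — the standard
    choice for two-run test-retest data.  ``icc11`` is the one-way form
    ICC(1,1).  Zero total variance yields a NaN sentinel with a warning.
    """
    mat = np.asarray(x, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a subjects x runs matrix with at least 2 runs")
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(mat)):
        raise ValueError("matrix contains non-finite values")
    value = _icc_core(mat[:, :, None], kind)[0]
    if np.isnan(value):
        warnings.warn("zero total variance; ICC undefined (NaN sentinel)", stacklevel=2)
    return float(value)


def _icc_core(x: np.ndarray, kind: str) -> np.ndarray:
    ms_subj, ms_run, ms_err, n, k = _icc_mean_squares(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "icc31":
            num = ms_subj - ms_err
            den = ms_subj + (k - 1) * ms_err
        elif kind == "icc11":
            ms_within = (ms_run * (k - 1) + ms_err * (n - 1) * (k - 1)) / (n * (k - 1))
            num = ms_subj - ms_within
            den = ms_subj + (k - 1) * ms_within
        else:
            raise ValueError("kind must be 'icc31' or 'icc11'")
        out = num / den
    return np.where(den == 0, np.nan, out)


def icc_map(
    run_a: np.ndarray,
    run_b: np.ndarray,
    masks: dict[str, np.ndarray] | None = None,
    kind: str = "icc31",
    bins: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Elementwise ICC between two runs plus normalized histograms.

    ``run_a``/``run_b`` are subjects x units arrays with aligned subjects.
    Histograms (masses summing to 1) are returned for the whole domain and
    for every named mask, following the convention of comparing the ICC
    distribution inside significant units against the full map.
    """
    a = np.asarray(run_a, dtype=float)
    b = np.asarray(run_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("runs differ in shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    flat_a = a.reshape(a.shape[0], -1)
    flat_b = b.reshape(b.shape[0], -1)
    stacked = np.stack([flat_a, flat_b], axis=1)  # subjects x 2 x units
    values = _icc_core(stacked, kind).reshape(a.shape[1:])
    if bins is None:
        bins = np.linspace(-1.0, 1.0, 41)
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def _hist(sel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vals = values[sel] if sel is not None else values
        vals = vals[np.isfinite(vals)]
        counts, edges = np.histogram(np.clip(vals, bins[0], bins[-1]), bins=bins)
        mass = counts / counts.sum() if counts.sum() else counts.astype(float)
        return edges, mass

    hists["all"] = _hist(np.ones(values.shape, dtype=bool))
    for name, mask in (masks or {}).items():
        mask = np.asarray(mask).astype(bool)
        if mask.shape != values.shape:
            raise ValueError(f"mask '{name}' does not match the unit shape")
        hists[name] = _hist(mask)
    return values, hists


def coefficient_of_variation(x: np.ndarray, orient_sign: float = 1.0) -> float:
    """Within-subject between-run variation as a percentage of the mean.

    The two per-subject values are log-transformed; the within-subject
    variance of the two logs is averaged over subjects; the square root is
    back-transformed with ``exp`` and 1 is subtracted, giving a fraction of
    the mean that is returned in percent.  Because it operates on logs, the
    statistic is invariant to rescaling all values by a common factor.

    ``orient_sign`` flips the sign of all values first (set to -1 for
    negative effects such as reduced-connectivity betas); any remaining
    non-positive value raises, naming the offending subject.
    """
    mat = np.asarray(x, dtype=float) * orient_sign
    if mat.ndim != 2 or mat.shape[1] != 2:
        raise ValueError("need a subjects x 2 matrix")
    bad = np.nonzero(~(mat > 0).all(axis=1))[0]
    if bad.size:
        raise ValueError(
            f"non-positive value after orientation for subject index {int(bad[0])}; "
            "flip orient_sign or restrict to consistently signed effects"
        )
    logs = np.log(mat)
    within_var = logs.var(axis=1, ddof=1)  # variance of 2 values = (diff^2)/2
    s = np.sqrt(within_var.mean())
    return float((np.exp(s) - 1.0) * 100.0)
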