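"""Group-level statistics on per-subject beta maps or edge matrices.

One-sample t tests (one-tailed, either sign), t-distribution critical
values, Benjamini-Hochberg FDR over a vector of p values, and conjunction
counting of binary significance masks across analysis scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupStat",
    "one_sample_t",
    "critical_t",
    "bh_fdr",
    "conjunction_count",
]


@dataclass
class GroupStat:
    """One-sample t test result over subjects, per voxel/edge."""

    t: np.ndarray
    p_onetailed: np.ndarray
    df: int
    n_subjects: int
    contrast_sign: str

    def significant(self, p: float) -> np.ndarray:
        """Binary mask of units one-tailed significant at level ``p``."""
        return self.p_onetailed < p


def one_sample_t(betas: np.ndarray, contrast_sign: str = "+") -> GroupStat:
    """Per-unit one-sample t test across subjects (axis 0).

    ``contrast_sign`` selects the tail: "+" tests mean > 0, "-" tests
    mean < 0.  Zero-variance units get sentinel t values (0 when the mean is
    also 0, signed inf otherwise) with a warning.  NaN units (e.g. matrix
    diagonals) propagate as NaN.
    """
    if contrast_sign not in ("+", "-"):
        raise ValueError("contrast_sign must be '+' or '-'")
    b = np.asarray(betas, dtype=float)
    n = b.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    mean = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0) & np.isfinite(mean)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} unit(s) with zero variance; sentinel t reported",
            stacklevel=2,
        )
        t = np.where(degenerate & (mean == 0), 0.0, t)
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate & (mean != 0), np.sign(mean) * np.inf, t)
    signed = t if contrast_sign == "+" else -t
    with np.errstate(invalid="ignore"):
        p = stats.t.sf(signed, df)
    return GroupStat(t=t, p_onetailed=p, df=df, n_subjects=n, contrast_sign=contrast_sign)


def critical_t(p: float, df: int) -> float:
    """One-tailed critical t value at tail probability ``p``.

    E.g. at p = 0.001 with 137 degrees of freedom this is 3.1558 (3.15 after
    truncating to two decimals).
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    return float(stats.t.isf(p, df))


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up at level ``q``; returns a keep mask."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    below = ranked <= q * (np.arange(1, m + 1) / m)
    keep = np.zeros(m, dtype=bool)
    if below.any():
        cutoff = np.max(np.nonzero(below)[0])
        keep[order[: cutoff + 1]] = True
    return keep


def conjunction_count(masks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise count of overlapping binary masks.

    Returns ``(count, full)`` where ``count`` sums the masks and ``full`` is
    the full-conjunction mask (count equals the number of masks).
    """
    if not masks:
        raise ValueError("no masks given")
    shape = np.asarray(masks[0]).shape
    for mask in masks:
        if np.asarray(mask).shape != shape:
            raise ValueError("masks differ in shape")
    count = np.zeros(shape, dtype=int)
    for mask in masks:
        count += np.asarray(mask).astype(bool).astype(int)
    return count, count == len(masks)
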