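"""Task design sampling, nuisance regressors, and motion screening.

Covers the pieces of a task fMRI model that surround the effect of interest:
the psychological boxcar sampled on the scan grid, the 24-parameter
autoregressive motion expansion, white-matter/CSF nuisance columns, DCT
drift columns, frame-wise displacement and motion-based subject screening.

Timing convention: scan ``i`` of a retained run is stamped at
``i * tr + discard_leading`` seconds from the start of acquisition
(start-of-volume), and task blocks are half-open intervals
``[onset, onset + duration)`` in the same clock.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hemodynamics import dct_highpass

__all__ = [
    "TaskDesign",
    "MotionTrace",
    "NuisanceSet",
    "ScreenResult",
    "checkerboard_design",
    "discard_leading_volumes",
    "sample_boxcar",
    "friston24",
    "framewise_displacement",
    "screen_subject",
    "load_motion",
    "build_nuisance",
]


@dataclass(frozen=True)
class TaskDesign:
    """Block/event schedule plus the scan grid it is sampled on.

    ``discard_leading`` is the duration of dummy volumes dropped at the start
    of the run; onsets stay on the original acquisition clock.
    """

    onsets: tuple[float, ...]
    durations: tuple[float, ...]
    total_duration: float
    tr: float
    n_scans: int
    discard_leading: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "onsets", tuple(float(o) for o in self.onsets))
        object.__setattr__(self, "durations", tuple(float(d) for d in self.durations))
        if len(self.onsets) != len(self.durations):
            raise ValueError("onsets and durations differ in length")
        if any(o < 0 for o in self.onsets):
            raise ValueError("onsets must be nonnegative")
        if any(b <= a for a, b in zip(self.onsets, self.onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        if any(o + d > self.total_duration + 1e-9 for o, d in zip(self.onsets, self.durations)):
            raise ValueError("a block extends past total_duration")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        if self.discard_leading < 0:
            raise ValueError("discard_leading must be nonnegative")
        if self.discard_leading + self.n_scans * self.tr > self.total_duration + 1e-6:
            raise ValueError("scan grid extends past total_duration")

    @property
    def scan_times(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.tr + self.discard_leading


def checkerboard_design(tr: float, n_scans: int, discard_leading: float) -> TaskDesign:
    """The 20 s-off / 20 s-on x3 flickering-checkerboard layout.

    Three 20 s stimulation blocks at 20, 60 and 100 s, each preceded by a
    20 s fixation block, followed by a blank screen until the scan ends.
    """
    total = max(120.0, discard_leading + n_scans * tr)
    return TaskDesign(
        onsets=(20.0, 60.0, 100.0),
        durations=(20.0, 20.0, 20.0),
        total_duration=total,
        tr=tr,
        n_scans=n_scans,
        discard_leading=discard_leading,
    )


def discard_leading_volumes(n_acquired: int, tr: float, discard_s: float) -> tuple[int, int]:
    """Number of leading volumes to drop for ``discard_s`` seconds of settling.

    Returns ``(n_discard, n_retained)`` with ``n_discard = ceil(discard_s / tr)``.
    E.g. 239 volumes at TR 0.645 s with 9 s discarded -> (14, 225); 98 volumes
    at TR 1.4 s with 7 s discarded -> (5, 93).
    """
    if discard_s < 0:
        raise ValueError("discard_s must be nonnegative")
    if not tr > 0:
        raise ValueError("tr must be positive")
    n_discard = int(math.ceil(discard_s / tr - 1e-12))
    if n_discard >= n_acquired:
        raise ValueError(
            f"discarding {n_discard} volumes would empty a {n_acquired}-volume run"
        )
    return n_discard, n_acquired - n_discard


def sample_boxcar(design: TaskDesign) -> np.ndarray:
    """0/1 task indicator at each retained scan's acquisition time."""
    t = design.scan_times
    box = np.zeros(design.n_scans)
    for onset, dur in zip(design.onsets, design.durations):
        box[(t >= onset) & (t < onset + dur)] = 1.0
    return box


@dataclass
class MotionTrace:
    """Rigid-body motion parameters: 3 translations (mm), 3 rotations (deg)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be an n_scans x 6 array")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters contain non-finite values")

    @property
    def n_scans(self) -> int:
        return self.params.shape[0]


def load_motion(path: str | Path) -> MotionTrace:
    """Read a 6-column motion parameter file (whitespace- or comma-delimited)."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0]
    delim = "," if "," in first else None
    return MotionTrace(np.loadtxt(path, delimiter=delim))


def friston24(motion: MotionTrace) -> np.ndarray:
    """24-column autoregressive motion expansion.

    Columns are, per the standard expansion: the 6 parameters, the 6
    parameters lagged by one scan (leading row zero-padded), and the squares
    of both sets: ``[m, m_lag1, m**2, m_lag1**2]``.
    """
    m = motion.params
    lag = np.zeros_like(m)
    lag[1:] = m[:-1]
    out = np.hstack([m, lag, m**2, lag**2])
    assert out.shape == (motion.n_scans, 24)
    return out


def framewise_displacement(motion: MotionTrace) -> tuple[np.ndarray, np.ndarray]:
    """Per-volume frame-wise displacement, translations and rotations apart.

    ``trans_fd[i]`` is the sum of absolute scan-to-scan changes over the three
    translation axes (mm); ``rot_fd[i]`` likewise over the three rotation
    angles (degrees).  The first element of each is 0.
    """
    diffs = np.abs(np.diff(motion.params, axis=0))
    trans = np.concatenate([[0.0], diffs[:, :3].sum(axis=1)])
    rot = np.concatenate([[0.0], diffs[:, 3:].sum(axis=1)])
    return trans, rot


@dataclass(frozen=True)
class ScreenResult:
    keep: bool
    reason: str = ""


def screen_subject(
    motion_runs: list[MotionTrace] | tuple[MotionTrace, ...],
    thresh_mm: float = 1.5,
    thresh_deg: float = 1.5,
    run_labels: list[str] | None = None,
) -> ScreenResult:
    """Exclude a subject whose head moved too much in any run.

    A subject is excluded iff the maximum frame-wise displacement strictly
    exceeds ``thresh_mm`` (translations) or ``thresh_deg`` (rotations) in any
    run; a jump exactly at the threshold is kept.
    """
    if not (thresh_mm > 0 and thresh_deg > 0):
        raise ValueError("screening thresholds must be positive")
    labels = run_labels or [f"run {i + 1}" for i in range(len(motion_runs))]
    for trace, lab in zip(motion_runs, labels):
        trans, rot = framewise_displacement(trace)
        if trans.max() > thresh_mm:
            return ScreenResult(
                False, f"max translation FD {trans.max():.3g} mm > {thresh_mm} mm in {lab}"
            )
        if rot.max() > thresh_deg:
            return ScreenResult(
                False, f"max rotation FD {rot.max():.3g} deg > {thresh_deg} deg in {lab}"
            )
    return ScreenResult(True)


@dataclass
class NuisanceSet:
    """Assembled nuisance design: motion-24, WM/CSF series, drift columns."""

    columns: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        if self.columns.ndim != 2:
            raise ValueError("nuisance columns must form a matrix")
        if self.columns.shape[1] != len(self.column_labels):
            raise ValueError("label count does not match column count")


def build_nuisance(
    motion: MotionTrace | None = None,
    wm: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    n_scans: int | None = None,
    tr: float | None = None,
    drift_cutoff: float | None = 128.0,
) -> NuisanceSet:
    """Stack motion-24, WM/CSF eigenvariates and DCT drift columns.

    Constant or duplicate columns (beyond the basis constant, which is not
    included here) are dropped with their labels, so the result is full
    column rank for any sensible input.
    """
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    if motion is not None:
        blocks.append(friston24(motion))
        labels += [f"motion{i + 1}" for i in range(24)]
        n_scans = motion.n_scans
    for series, name in ((wm, "wm"), (csf, "csf")):
        if series is not None:
            arr = np.asarray(series, dtype=float).reshape(-1, 1)
            blocks.append(arr)
            labels.append(name)
            n_scans = arr.shape[0]
    if drift_cutoff is not None and n_scans is not None and tr is not None:
        basis = dct_highpass(n_scans, tr, drift_cutoff)
        if basis.n_drift:
            blocks.append(basis.drift_columns)
            labels += [f"drift{i + 1}" for i in range(basis.n_drift)]
    if not blocks:
        raise ValueError("no nuisance components supplied")
    mat = np.hstack(blocks)
    keep = _rank_screen(mat)
    return NuisanceSet(mat[:, keep], [labels[i] for i in keep])


def _rank_screen(mat: np.ndarray) -> list[int]:
    """Indices of columns to keep: drop constants and linearly dependent columns."""
    keep: list[int] = []
    basis: list[np.ndarray] = []
    for i in range(mat.shape[1]):
        col = mat[:, i]
        if np.ptp(col) == 0:
            continue
        resid = col.astype(float).copy()
        for b in basis:
            resid -= (resid @ b) * b
        norm = np.linalg.norm(resid)
        if norm < 1e-10 * max(1.0, np.linalg.norm(col)):
            continue
        basis.append(resid / norm)
        keep.append(i)
    return keep
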