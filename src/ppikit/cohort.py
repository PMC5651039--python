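"""Synthetic multi-subject two-run cohorts with known PPI ground truth.

Emulates the structure of a two-run checkerboard experiment — run A with 225
volumes at TR 0.645 s and run B with 93 volumes at TR 1.4 s, a 20 s-on /
20 s-off x3 block design, 20 visual ROIs — with a forward model in which
task-modulated connectivity is injected at the neuronal level and then
convolved with a per-subject hemodynamic response:

    neuronal_j = correlated innovations_j + activation_j * boxcar
                 + sum_pairs gamma_s * centered_boxcar * neuronal_i
    bold_j     = neuronal_j * hrf(subject)  + AR(1) noise + drift + nuisance leak

Because the interaction lives at the neuronal level, the deconvolution PPI
method is the generative model and the non-deconvolution method is its
block-design approximation.  Per-subject modulation strengths ``gamma_s``
are drawn around the designated pair effects with a between-subject SD, so
test-retest reliability of the fitted effects has a known driver.  The
ground truth is stored losslessly alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import MotionTrace, TaskDesign, checkerboard_design, sample_boxcar
from .hemodynamics import BoldSeries, HRFSpec, canonical_hrf, convolve_causal

__all__ = [
    "RunSpec",
    "CohortSpec",
    "RunData",
    "SubjectData",
    "SyntheticDataset",
    "default_roi_labels",
    "generate_cohort",
    "generate_motion",
    "render_volumes",
    "write_dataset",
]


def default_roi_labels() -> tuple[str, ...]:
    """Twenty visual ROIs: thalamus plus cytoarchitectonic visual areas, L/R."""
    areas = ("Tha", "OC1", "OC2", "OC3d", "OC3v", "OC4d", "OC4v", "OC5", "FG1", "FG2")
    return tuple(f"{side}_{area}" for area in areas for side in ("L", "R"))


# Five designated reduced-connectivity pairs, centered on the posterior
# fusiform (FG1) as the hub, each modulated negatively during stimulation.
DEFAULT_PPI_EFFECTS: dict[tuple[str, str], float] = {
    ("L_FG1", "L_OC1"): -0.5,
    ("L_FG1", "R_OC1"): -0.5,
    ("R_FG1", "L_OC2"): -0.5,
    ("R_FG1", "R_OC2"): -0.5,
    ("L_FG1", "R_OC4d"): -0.5,
}


@dataclass(frozen=True)
class RunSpec:
    tr: float
    n_scans: int
    discard_s: float


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; defaults mirror the two-run study layout.

    ``baseline_corr`` is either an exchangeable off-diagonal correlation (a
    float) or a full positive-semidefinite ROI x ROI matrix.  ``ppi_effects``
    maps ROI-label pairs to signed neuronal-level modulation coefficients;
    ``effect_sd_between`` is the SD of the per-subject deviation around each
    coefficient.  Neuronal fluctuations are AR(1) in continuous time with
    autocorrelation time ``neuronal_tau`` seconds and unit variance, so both
    runs sample the same underlying process despite different TRs.  Noise is
    per-scan AR(1) measurement noise on top of slow cosine drift and a small
    leak of shared WM/CSF-like nuisance signal.
    """

    n_subjects: int = 20
    runs: tuple[RunSpec, ...] = (RunSpec(0.645, 225, 9.0), RunSpec(1.4, 93, 7.0))
    roi_labels: tuple[str, ...] = field(default_factory=default_roi_labels)
    baseline_corr: float | np.ndarray = 0.3
    ppi_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PPI_EFFECTS)
    )
    activation_amp: float = 1.5
    neuronal_tau: float = 2.0
    hrf_jitter: float = 0.5
    ar1: float = 0.3
    noise_sd: float = 0.8
    drift_amp: float = 0.5
    nuisance_leak: float = 0.2
    effect_sd_between: float = 0.2
    motion_step_mm: float = 0.02
    hrf: HRFSpec = field(default_factory=HRFSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")
        labels = set(self.roi_labels)
        for pair in self.ppi_effects:
            if pair[0] not in labels or pair[1] not in labels:
                raise ValueError(f"ppi_effects pair {pair} names an unknown ROI")
            if pair[0] == pair[1]:
                raise ValueError("ppi_effects pairs must join distinct ROIs")

    def correlation_matrix(self) -> np.ndarray:
        r = len(self.roi_labels)
        if np.isscalar(self.baseline_corr):
            mat = np.full((r, r), float(self.baseline_corr))
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(self.baseline_corr, dtype=float)
            if mat.shape != (r, r):
                raise ValueError("baseline_corr matrix has the wrong shape")
        eigvals = np.linalg.eigvalsh(mat)
        if eigvals.min() < -1e-10:
            raise ValueError("baseline correlation structure is not positive semidefinite")
        return mat


@dataclass
class RunData:
    tr: float
    n_scans: int
    discard_s: float
    design: TaskDesign
    roi_table: pd.DataFrame
    motion: MotionTrace
    nuisance: pd.DataFrame

    def roi_series(self) -> list[BoldSeries]:
        return [
            BoldSeries(self.roi_table[label].to_numpy(), tr=self.tr, label=label)
            for label in self.roi_table.columns
        ]


@dataclass
class SubjectData:
    subject_id: str
    runs: list[RunData]
    effects: dict[tuple[str, str], float]
    hrf_delay: float


@dataclass
class SyntheticDataset:
    spec: CohortSpec
    subjects: list[SubjectData]

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return self.spec.roi_labels

    @property
    def n_runs(self) -> int:
        return len(self.spec.runs)

    def truth(self) -> dict:
        """Ground-truth record: designated effects and per-subject draws."""
        return {
            "ppi_effects": {f"{a}--{b}": v for (a, b), v in self.spec.ppi_effects.items()},
            "per_subject": {
                s.subject_id: {f"{a}--{b}": v for (a, b), v in s.effects.items()}
                for s in self.subjects
            },
            "hrf_delays": {s.subject_id: s.hrf_delay for s in self.subjects},
        }


def _ar1_noise(rng: np.random.Generator, n: int, cols: int, phi: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros((n, cols))
    innov_sd = sd * np.sqrt(1.0 - phi**2) if phi > 0 else sd
    eps = rng.standard_normal((n, cols)) * innov_sd
    out = np.empty_like(eps)
    out[0] = eps[0] if phi == 0 else rng.standard_normal(cols) * sd
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def _drift(rng: np.random.Generator, n: int, tr: float, amp: float, cols: int) -> np.ndarray:
    """Random slow cosine drifts with periods longer than 128 s."""
    if amp == 0:
        return np.zeros((n, cols))
    n_drift = max(int(np.floor(2 * n * tr / 128.0)), 1)
    t = np.arange(n)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n)) for k in range(1, n_drift + 1)]
    )
    coefs = rng.standard_normal((n_drift, cols)) * amp
    return basis @ coefs


def generate_motion(
    n_scans: int,
    max_step_mm: float = 0.02,
    seed: int | np.random.Generator = 0,
    spike_mm: float = 0.0,
    spike_at: int | None = None,
) -> MotionTrace:
    """Smooth random-walk motion trace with an optional injected jump.

    Steps per scan are Gaussian with SD ``max_step_mm`` on every translation
    axis (mm) and rotation angle (degrees).  ``spike_mm`` adds a single
    sustained jump of that size on the x translation at scan ``spike_at``
    (mid-run by default), producing a frame-wise displacement of exactly
    that magnitude at one frame.
    """
    if n_scans < 2:
        raise ValueError("n_scans must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.standard_normal((n_scans, 6)) * max_step_mm
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    if spike_mm:
        at = n_scans // 2 if spike_at is None else spike_at
        params[at:, 0] += spike_mm
    return MotionTrace(params)


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticDataset:
    """Draw a full cohort from the forward model; deterministic under seed."""
    if spec is None:
        spec = CohortSpec()
    labels = list(spec.roi_labels)
    r = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    corr = spec.correlation_matrix()
    # PSD square root (eigh handles semidefinite structures cholesky cannot)
    w, v = np.linalg.eigh(corr)
    chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    root = np.random.SeedSequence(spec.seed)
    subjects = []
    for s, subj_seq in enumerate(root.spawn(spec.n_subjects)):
        rng = np.random.default_rng(subj_seq)
        delay = spec.hrf.response_delay + rng.normal(0.0, spec.hrf_jitter)
        delay = float(np.clip(delay, 3.0, 10.0))
        hrf = dataclasses.replace(spec.hrf, response_delay=delay)
        effects = {
            pair: float(rng.normal(base, spec.effect_sd_between))
            for pair, base in spec.ppi_effects.items()
        }
        runs = []
        for run in spec.runs:
            design = checkerboard_design(run.tr, run.n_scans, run.discard_s)
            box = sample_boxcar(design)
            centered = box - box.mean()
            # same continuous neuronal process regardless of TR: AR(1) with a
            # fixed autocorrelation time in seconds, unit stationary variance
            phi = float(np.exp(-run.tr / spec.neuronal_tau)) if spec.neuronal_tau > 0 else 0.0
            eps = rng.standard_normal((run.n_scans, r)) @ chol.T
            innov = np.empty_like(eps)
            innov[0] = eps[0]
            scale = np.sqrt(1.0 - phi**2)
            for t in range(1, run.n_scans):
                innov[t] = phi * innov[t - 1] + scale * eps[t]
            base = innov + spec.activation_amp * box[:, None]
            neuronal = base.copy()
            for (a, b), gamma in effects.items():
                i, j = idx[a], idx[b]
                neuronal[:, j] += gamma * centered * base[:, i]
                neuronal[:, i] += gamma * centered * base[:, j]
            kernel = canonical_hrf(hrf.at_dt(run.tr))
            bold = np.column_stack(
                [convolve_causal(neuronal[:, k], kernel, run.tr) for k in range(r)]
            )
            wm = _ar1_noise(rng, run.n_scans, 1, 0.9, 1.0)[:, 0]
            csf = _ar1_noise(rng, run.n_scans, 1, 0.9, 1.0)[:, 0]
            leak = spec.nuisance_leak * (wm + csf)
            noise = _ar1_noise(rng, run.n_scans, r, spec.ar1, spec.noise_sd)
            drift = _drift(rng, run.n_scans, run.tr, spec.drift_amp, r)
            table = pd.DataFrame(bold + noise + drift + leak[:, None], columns=labels)
            motion = generate_motion(run.n_scans, spec.motion_step_mm, rng)
            runs.append(
                RunData(
                    tr=run.tr,
                    n_scans=run.n_scans,
                    discard_s=run.discard_s,
                    design=design,
                    roi_table=table,
                    motion=motion,
                    nuisance=pd.DataFrame({"wm": wm, "csf": csf}),
                )
            )
        subjects.append(
            SubjectData(
                subject_id=f"sub-{s + 1:03d}", runs=runs, effects=effects, hrf_delay=delay
            )
        )
    return SyntheticDataset(spec=spec, subjects=subjects)


def render_volumes(
    run: RunData,
    shape: tuple[int, int, int] = (20, 20, 10),
    voxels_per_roi: int = 27,
    voxel_noise_sd: float = 0.1,
    seed: int = 0,
):
    """Paint ROI series into a small 4D volume with disjoint cubic ROIs.

    Each ROI occupies a 3x3x3 block laid out on a grid inside ``shape``; its
    voxels carry the ROI series plus independent Gaussian voxel noise.
    Returns ``(img4d, masks)`` as nibabel NIfTI images (3 mm isotropic grid,
    TR in the header), so the voxel-wise path — mask an ROI, extract its
    eigenvariate, recover the source series — is testable end to end.
    """
    import nibabel as nib

    labels = list(run.roi_table.columns)
    side = int(round(voxels_per_roi ** (1 / 3)))
    if side**3 != voxels_per_roi:
        raise ValueError("voxels_per_roi must be a perfect cube")
    per_x = shape[0] // (side + 1)
    per_y = shape[1] // (side + 1)
    if per_x * per_y * (shape[2] // (side + 1) + 1) < len(labels):
        raise ValueError("volume shape too small for the ROI geometry")
    rng = np.random.default_rng(seed)
    data = np.zeros(shape + (run.n_scans,), dtype=np.float32)
    masks: dict[str, "nib.Nifti1Image"] = {}
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    for k, label in enumerate(labels):
        gx = k % per_x
        gy = (k // per_x) % per_y
        gz = k // (per_x * per_y)
        x0, y0, z0 = gx * (side + 1), gy * (side + 1), gz * (side + 1)
        if z0 + side > shape[2]:
            raise ValueError("volume shape too small for the ROI geometry")
        series = run.roi_table[label].to_numpy(dtype=np.float32)
        block = series[None, None, None, :] + rng.standard_normal(
            (side, side, side, run.n_scans)
        ).astype(np.float32) * voxel_noise_sd
        region = data[x0 : x0 + side, y0 : y0 + side, z0 : z0 + side, :]
        if np.any(region):
            raise ValueError(f"ROI geometry overlap at '{label}'")
        data[x0 : x0 + side, y0 : y0 + side, z0 : z0 + side, :] = block
        mask = np.zeros(shape, dtype=np.uint8)
        mask[x0 : x0 + side, y0 : y0 + side, z0 : z0 + side] = 1
        masks[label] = nib.Nifti1Image(mask, affine)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((3.0, 3.0, 3.0, run.tr))
    return img, masks


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write the on-disk layout the pipeline reads back.

    Per subject/run: ROI series TSV with a header of labels, a JSON sidecar
    {tr, n_scans}, a whitespace-delimited 6-column motion file, and a
    nuisance TSV; plus one ground-truth JSON at the root.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for subj in dataset.subjects:
        for k, run in enumerate(subj.runs):
            rdir = out / subj.subject_id / f"run-{k + 1}"
            rdir.mkdir(parents=True, exist_ok=True)
            run.roi_table.to_csv(rdir / "roi_series.tsv", sep="\t", index=False)
            (rdir / "roi_series.json").write_text(
                json.dumps({"tr": run.tr, "n_scans": run.n_scans, "discard_s": run.discard_s})
            )
            np.savetxt(rdir / "motion.txt", run.motion.params, fmt="%.6f")
            run.nuisance.to_csv(rdir / "nuisance.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(json.dumps(dataset.truth(), indent=1))
    return out
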