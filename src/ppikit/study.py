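"""Full study replica: both PPI methods x both runs, group stats, reliability.

`run_study` takes a cohort (synthetic or loaded from disk), screens subjects
by motion, fits ROI-pair PPI edge matrices per subject/run/method, runs
group one-sample t tests per scenario, counts the conjunction of negative
effects across scenarios, and assembles a reliability report comparing the
two runs: Dice curves under both thresholding strategies, edgewise ICC with
histograms, and coefficients of variation on the consistently modulated
edges.  Also houses the winner-takes-all labelling utility used to collapse
probabilistic atlas maps into disjoint ROIs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .cohort import RunData, SyntheticDataset
from .design import build_nuisance, screen_subject
from .hemodynamics import BoldSeries
from .group import conjunction_count, one_sample_t
from .hemodynamics import HRFSpec
from .ppi import EdgeMatrix, edge_matrix
from .reliability import (
    DEFAULT_PERCENTILE_GRID,
    DEFAULT_T_GRID,
    coefficient_of_variation,
    dice_curves,
    icc_map,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_study",
    "winner_takes_all",
    "nuisance_adjusted_series",
]


def nuisance_adjusted_series(run: RunData) -> list[BoldSeries]:
    """ROI series with nuisance effects regressed out, ready for PPI fits.

    Regresses the motion-24 expansion, the WM/CSF series and the DCT drift
    columns (plus an intercept) out of every ROI column, mirroring the
    convention of extracting ROI summaries "with adjustment of effects of no
    interest" so the PPI models themselves need no covariates.
    """
    nuis = build_nuisance(
        motion=run.motion,
        wm=run.nuisance["wm"].to_numpy(),
        csf=run.nuisance["csf"].to_numpy(),
        tr=run.tr,
    )
    x = np.column_stack([np.ones(run.n_scans), nuis.columns])
    y = run.roi_table.to_numpy()
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return [
        BoldSeries(resid[:, k], tr=run.tr, label=label)
        for k, label in enumerate(run.roi_table.columns)
    ]


@dataclass(frozen=True)
class StudyConfig:
    """Resolved configuration of a study replica."""

    methods: tuple[str, ...] = ("deconv", "nondeconv")
    # Common ridge weight for the deconvolution method across all subjects:
    # per-series GCV can collapse a noise-dominated series to a constant,
    # which leaves the PPI betas on incomparable scales between subjects.
    deconv_reg_weight: float | None = 1.0
    contrast_sign: str = "-"
    p_voxel: float = 0.001
    p_conjunction: float = 0.01
    t_grid: tuple[float, ...] = tuple(DEFAULT_T_GRID)
    percentile_grid: tuple[float, ...] = tuple(DEFAULT_PERCENTILE_GRID)
    screen_mm: float = 1.5
    screen_deg: float = 1.5
    hrf: HRFSpec = field(default_factory=HRFSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one PPI method is required")
        for m in self.methods:
            if m not in ("deconv", "nondeconv"):
                raise ValueError(f"unknown method '{m}'")

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class StudyResult:
    """All study outputs plus a provenance manifest."""

    config: StudyConfig
    roi_labels: list[str]
    # per (method, run index): subjects x R x R symmetrized beta stack
    betas: dict[tuple[str, int], np.ndarray]
    group_t: dict[tuple[str, int], np.ndarray]
    group_p: dict[tuple[str, int], np.ndarray]
    sig_masks: dict[tuple[str, int], np.ndarray]
    conjunction: np.ndarray | None
    full_conjunction: np.ndarray | None
    reliability: dict | None
    excluded: list[tuple[str, str]]
    manifest: dict

    def scenario_keys(self) -> list[tuple[str, int]]:
        return sorted(self.betas.keys())


def _edge_stack(
    dataset: SyntheticDataset,
    subject_indices: list[int],
    run_idx: int,
    method: str,
    hrf: HRFSpec,
    reg_weight: float | None,
) -> np.ndarray:
    mats = []
    for s in subject_indices:
        run = dataset.subjects[s].runs[run_idx]
        mat = edge_matrix(
            nuisance_adjusted_series(run),
            run.design,
            hrf,
            method=method,
            reg_weight=reg_weight,
        )
        mats.append(mat.values)
    return np.stack(mats)


def run_study(dataset: SyntheticDataset, config: StudyConfig | None = None) -> StudyResult:
    """Run the ROI-wise study replica on a two-run cohort.

    Deterministic given the dataset and configuration.  Subjects failing the
    motion screen are excluded with recorded reasons; the study aborts only
    if fewer than 3 subjects survive.  The reliability section requires both
    methods and at least two runs; with a restricted configuration it is
    omitted with a warning.
    """
    if config is None:
        config = StudyConfig()
    labels = list(dataset.roi_labels)
    keep_idx: list[int] = []
    excluded: list[tuple[str, str]] = []
    for i, subj in enumerate(dataset.subjects):
        res = screen_subject(
            [run.motion for run in subj.runs],
            config.screen_mm,
            config.screen_deg,
            run_labels=[f"run-{k + 1}" for k in range(len(subj.runs))],
        )
        if res.keep:
            keep_idx.append(i)
        else:
            excluded.append((subj.subject_id, res.reason))
    if len(keep_idx) < 3:
        raise RuntimeError(
            f"only {len(keep_idx)} subject(s) survive motion screening; need at least 3"
        )
    n_runs = dataset.n_runs
    sign = config.contrast_sign
    betas: dict[tuple[str, int], np.ndarray] = {}
    group_t: dict[tuple[str, int], np.ndarray] = {}
    group_p: dict[tuple[str, int], np.ndarray] = {}
    sig: dict[tuple[str, int], np.ndarray] = {}
    for method in config.methods:
        for r in range(n_runs):
            stack = _edge_stack(
                dataset, keep_idx, r, method, config.hrf, config.deconv_reg_weight
            )
            stat = one_sample_t(stack, contrast_sign=sign)
            betas[(method, r)] = stack
            group_t[(method, r)] = stat.t
            group_p[(method, r)] = stat.p_onetailed
            sig[(method, r)] = np.nan_to_num(stat.p_onetailed, nan=1.0) < config.p_conjunction
    conjunction = full = None
    if len(sig) > 1:
        conjunction, full = conjunction_count(list(sig.values()))
    reliability = None
    if n_runs >= 2:
        reliability = _reliability_report(betas, group_t, full, config, labels)
    else:
        warnings.warn("single-run configuration: reliability section omitted", stacklevel=2)
    manifest = {
        "ppikit_version": __version__,
        "config_digest": config.digest(),
        "n_subjects_analyzed": len(keep_idx),
        "n_subjects_excluded": len(excluded),
        "exclusions": [{"subject": s, "reason": r} for s, r in excluded],
        "methods": list(config.methods),
        "n_runs": n_runs,
        "n_rois": len(labels),
        "n_unique_effects": len(labels) * (len(labels) - 1) // 2,
    }
    return StudyResult(
        config=config,
        roi_labels=labels,
        betas=betas,
        group_t=group_t,
        group_p=group_p,
        sig_masks=sig,
        conjunction=conjunction,
        full_conjunction=full,
        reliability=reliability,
        excluded=excluded,
        manifest=manifest,
    )


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _reliability_report(betas, group_t, full_conjunction, config: StudyConfig, labels) -> dict:
    """Dice curves, edgewise ICC and CV between the first two runs."""
    sign = -1 if config.contrast_sign == "-" else 1
    report: dict = {"dice": {}, "icc": {}, "cv": {}}
    for method in config.methods:
        if (method, 0) not in group_t or (method, 1) not in group_t:
            continue
        t_a, t_b = group_t[(method, 0)], group_t[(method, 1)]
        report["dice"][method] = {
            strategy: dice_curves(t_a, t_b, strategy=strategy, sign=sign)
            for strategy in ("t_threshold", "percentile")
        }
        ua = np.stack([_upper(m) for m in betas[(method, 0)]])
        ub = np.stack([_upper(m) for m in betas[(method, 1)]])
        masks = None
        if full_conjunction is not None:
            masks = {"significant": _upper(full_conjunction).astype(bool)}
        icc_values, icc_hists = icc_map(ua, ub, masks=masks)
        report["icc"][method] = {
            "values": icc_values,
            "median": float(np.nanmedian(icc_values)),
            "histograms": icc_hists,
        }
        cv_edges: dict[str, float] = {}
        if full_conjunction is not None:
            iu = np.triu_indices(len(labels), k=1)
            for a, b, hit in zip(*iu, _upper(full_conjunction)):
                if not hit:
                    continue
                pair = np.column_stack([ua[:, _flat_index(a, b, len(labels))],
                                        ub[:, _flat_index(a, b, len(labels))]])
                try:
                    cv_edges[f"{labels[a]}--{labels[b]}"] = coefficient_of_variation(
                        pair, orient_sign=sign
                    )
                except ValueError:
                    continue  # mixed-sign effect: CV undefined for this edge
        report["cv"][method] = cv_edges
    return report


def _flat_index(i: int, j: int, r: int) -> int:
    """Position of (i, j), i < j, in the upper-triangle flattening."""
    return i * r - i * (i + 1) // 2 + (j - i - 1)


def winner_takes_all(prob_maps: list[np.ndarray]) -> np.ndarray:
    """Collapse probabilistic maps into a disjoint label volume.

    Each voxel gets the 1-based index of the map with the highest
    probability; voxels where every map is zero stay unlabelled (0).  Ties
    break toward the lowest map index.
    """
    if not prob_maps:
        raise ValueError("no probability maps given")
    arrs = [np.asarray(m, dtype=float) for m in prob_maps]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError("probability maps differ in shape")
        if np.any((a < 0) | (a > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
    stack = np.stack(arrs)
    labels = np.argmax(stack, axis=0) + 1
    labels[stack.max(axis=0) == 0] = 0
    return labels


def write_study(result: StudyResult, out_dir: str | Path) -> Path:
    """Serialize study outputs: CSV matrices/curves and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = result.roi_labels
    for (method, r), t in result.group_t.items():
        pd.DataFrame(t, index=labels, columns=labels).to_csv(
            out / f"group_t_{method}_run{r + 1}.csv"
        )
        mean_beta = result.betas[(method, r)].mean(axis=0)
        pd.DataFrame(mean_beta, index=labels, columns=labels).to_csv(
            out / f"mean_beta_{method}_run{r + 1}.csv"
        )
    if result.conjunction is not None:
        pd.DataFrame(result.conjunction, index=labels, columns=labels).to_csv(
            out / "conjunction_count.csv"
        )
    if result.reliability is not None:
        rel = {"cv": result.reliability["cv"]}
        rel["icc_median"] = {
            m: result.reliability["icc"][m]["median"] for m in result.reliability["icc"]
        }
        (out / "reliability.json").write_text(json.dumps(rel, indent=1))
        for method, curves in result.reliability["dice"].items():
            for strategy, curve in curves.items():
                pd.DataFrame(
                    {"threshold": curve.thresholds, "dice": curve.dice}
                ).to_csv(out / f"dice_{method}_{strategy}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    return out
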