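"""Two-stage dual regression for molecular-enriched functional connectivity.

The REACT procedure combines a subject's BOLD run ``Y`` (time x voxels) with a
set of receptor-density templates ``X1`` (voxels x targets, each rescaled to
[0, 1]) in two ordinary-least-squares stages:

* stage 1 (spatial design): every time frame of ``Y`` is regressed on the
  standardized templates, yielding a weight time series ``B1`` (time x
  targets) that tracks how strongly each molecular distribution modulates the
  ongoing BOLD fluctuations;
* stage 2 (temporal design): every voxel's time series is regressed on the
  standardized weight time series, yielding voxel-wise enriched connectivity
  maps ``B2`` (voxels x targets).

Both stages fit all targets jointly in a single design.  Design columns are
standardized to zero mean / unit variance within the relevant mask and the
response is demeaned, so stage-2 coefficients are expressed as BOLD change per
1 SD of the weight time series and are invariant to affine rescaling of the
raw templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ReceptorTemplateSet",
    "BoldRun",
    "StageMasks",
    "MolecularTimeSeries",
    "EnrichedMaps",
    "rescale_template",
    "build_stage_masks",
    "stage1_spatial_regression",
    "stage2_temporal_regression",
    "run_react",
    "CONDITION_NUMBER_WARN",
]

#: joint designs with a condition number above this emit a warning
CONDITION_NUMBER_WARN = 1e6


def _check_mask(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"{name} must be a 3-D boolean image, got ndim={mask.ndim}")
    if not mask.any():
        raise ValueError(f"{name} is empty")
    return mask


@dataclass
class ReceptorTemplateSet:
    """Receptor-density templates sampled on the voxels of a reference mask.

    ``values`` has one row per in-mask voxel (row-major / C order over the
    mask, i.e. the order of ``np.flatnonzero(mask)``) and one column per
    molecular target; every column is min-max rescaled to [0, 1].
    """

    values: np.ndarray  # (V, K)
    target_names: tuple[str, ...]
    mask: np.ndarray  # bool, 3-D
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = _check_mask(self.mask, "template mask")
        self.values = np.asarray(self.values, dtype=float)
        self.target_names = tuple(str(n) for n in self.target_names)
        if self.values.ndim != 2:
            raise ValueError("template values must be a (voxels, targets) matrix")
        if len(self.target_names) != self.values.shape[1]:
            raise ValueError("one target name per template column is required")
        if self.values.shape[1] < 1:
            raise ValueError("at least one target is required")
        if self.values.shape[0] != int(self.mask.sum()):
            raise ValueError("template rows must match the in-mask voxel count")
        if not np.isfinite(self.values).all():
            raise ValueError("template values must be finite")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("templates must be rescaled to [0, 1] (see rescale_template)")

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    def to_image(self) -> nib.Nifti1Image:
        """Export as a 4-D NIfTI image, one volume per target (0 outside mask)."""
        data = np.zeros(self.mask.shape + (self.n_targets,))
        data[self.mask] = self.values
        return nib.Nifti1Image(data, self.affine)

    @classmethod
    def from_images(
        cls,
        images: "list[nib.Nifti1Image]",
        mask: np.ndarray,
        target_names: "tuple[str, ...]",
        affine: np.ndarray | None = None,
        rescale: bool = True,
    ) -> "ReceptorTemplateSet":
        mask = _check_mask(mask, "template mask")
        cols = []
        for img in images:
            vol = np.asarray(img.get_fdata(), dtype=float)
            if vol.shape != mask.shape:
                raise ValueError("template image grid does not match the mask")
            if rescale:
                vol = rescale_template(vol, mask)
            cols.append(vol[mask])
        aff = affine if affine is not None else np.asarray(images[0].affine)
        return cls(np.column_stack(cols), tuple(target_names), mask, aff)


@dataclass
class BoldRun:
    """A denoised BOLD run sampled on the voxels of a brain mask (T x V)."""

    values: np.ndarray  # (T, V)
    mask: np.ndarray  # bool, 3-D
    repetition_time: float = 1.0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = _check_mask(self.mask, "BOLD mask")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BOLD values must be a (time, voxels) matrix")
        if self.values.shape[1] != int(self.mask.sum()):
            raise ValueError("BOLD columns must match the in-mask voxel count")
        if not np.isfinite(self.values).all():
            raise ValueError("BOLD values must be finite")
        if self.repetition_time <= 0:
            raise ValueError("repetition time must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def to_image(self) -> nib.Nifti1Image:
        data = np.zeros(self.mask.shape + (self.n_timepoints,))
        data[self.mask] = self.values.T
        return nib.Nifti1Image(data, self.affine)


@dataclass
class StageMasks:
    """Masks for the two regression stages.

    ``stage1`` is the joint intersection (over all targets) of template
    support with gray matter, used as the voxel set of the stage-1 design;
    ``per_target`` records each target's own support-within-GM; ``stage2``
    is the gray-matter mask itself.
    """

    stage1: np.ndarray
    stage2: np.ndarray
    per_target: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.stage1 = _check_mask(self.stage1, "stage-1 mask")
        self.stage2 = _check_mask(self.stage2, "stage-2 mask")
        if (self.stage1 & ~self.stage2).any():
            raise ValueError("stage-1 mask must be a subset of the stage-2 mask")


@dataclass
class MolecularTimeSeries:
    """Stage-1 weight time series (T x K), one column per molecular target."""

    values: np.ndarray
    target_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.target_names = tuple(str(n) for n in self.target_names)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.target_names):
            raise ValueError("weight time series must be (time, targets) with one name per column")
        if not np.isfinite(self.values).all():
            raise ValueError("weight time series must be finite")


@dataclass
class EnrichedMaps:
    """Stage-2 enriched connectivity maps over the stage-2 mask (V x K)."""

    values: np.ndarray
    target_names: tuple[str, ...]
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = _check_mask(self.mask, "map mask")
        self.values = np.asarray(self.values, dtype=float)
        self.target_names = tuple(str(n) for n in self.target_names)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.target_names):
            raise ValueError("maps must be (voxels, targets) with one name per column")
        if self.values.shape[0] != int(self.mask.sum()):
            raise ValueError("map rows must match the in-mask voxel count")
        if not np.isfinite(self.values).all():
            raise ValueError("map values must be finite")

    def to_image(self) -> nib.Nifti1Image:
        """4-D NIfTI export, zero-filled outside the stage-2 mask."""
        data = np.zeros(self.mask.shape + (len(self.target_names),))
        data[self.mask] = self.values
        return nib.Nifti1Image(data, self.affine)


def rescale_template(raw_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max rescale a raw density map to [0, 1] within ``mask``.

    Voxels outside the mask are set to 0.  A map that is constant within the
    mask is degenerate (no spatial information) and raises ``ValueError``.
    """
    mask = _check_mask(mask, "mask")
    raw_map = np.asarray(raw_map, dtype=float)
    if raw_map.shape != mask.shape:
        raise ValueError("map and mask grids differ")
    vals = raw_map[mask]
    if not np.isfinite(vals).all():
        raise ValueError("template values must be finite within the mask")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("degenerate template: constant within the mask")
    out = np.zeros_like(raw_map, dtype=float)
    out[mask] = (vals - lo) / (hi - lo)
    return out


def build_stage_masks(templates: ReceptorTemplateSet, gm_mask: np.ndarray) -> StageMasks:
    """Intersect each template's support with gray matter; stage 2 = GM.

    The joint stage-1 mask is the intersection across all targets, since the
    stage-1 fit uses a single multi-column design over one voxel set.
    """
    gm_mask = _check_mask(gm_mask, "gray-matter mask")
    if gm_mask.shape != templates.mask.shape:
        raise ValueError("gray-matter mask grid does not match the template grid")
    per_target: dict[str, np.ndarray] = {}
    joint = gm_mask.copy()
    for k, name in enumerate(templates.target_names):
        support = np.zeros(templates.mask.shape, dtype=bool)
        support[templates.mask] = templates.values[:, k] > 0
        inter = support & gm_mask
        if not inter.any():
            raise ValueError(
                f"stage-1 mask is empty for target {name!r}: "
                "template support does not intersect gray matter"
            )
        per_target[name] = inter
        joint &= inter
    if not joint.any():
        raise ValueError("joint stage-1 mask is empty across targets")
    return StageMasks(stage1=joint, stage2=gm_mask, per_target=per_target)


def _standardize_columns(X: np.ndarray, what: str) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [i for i, s in enumerate(sd) if s == 0]
        raise ValueError(f"constant {what} column(s) at index {bad}: cannot standardize")
    return (X - mu) / sd


def _check_design(X: np.ndarray, names: tuple[str, ...], stage: str) -> None:
    s = np.linalg.svd(X, compute_uv=False)
    eps = np.finfo(float).eps * max(X.shape) * s[0]
    if s[-1] <= eps:
        # name collinear pairs when they exist, otherwise report generically
        corr = np.corrcoef(X.T) if X.shape[1] > 1 else np.ones((1, 1))
        pairs = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        detail = f" (collinear: {', '.join(pairs)})" if pairs else ""
        raise ValueError(f"rank-deficient {stage} design{detail}")
    cond = s[0] / s[-1]
    if cond > CONDITION_NUMBER_WARN:
        warnings.warn(
            f"{stage} design condition number {cond:.3g} exceeds {CONDITION_NUMBER_WARN:.0e}",
            RuntimeWarning,
            stacklevel=3,
        )


def _mask_selector(inner: np.ndarray, outer: np.ndarray, what: str) -> np.ndarray:
    """Boolean selector of ``inner`` voxels within the flattened ``outer`` order."""
    if (inner & ~outer).any():
        raise ValueError(f"{what} extends outside the data mask")
    return inner[outer]


def stage1_spatial_regression(
    bold: BoldRun, templates: ReceptorTemplateSet, masks: StageMasks
) -> MolecularTimeSeries:
    """Joint OLS of every demeaned BOLD frame on the standardized templates.

    Restricted to the joint stage-1 mask; all K templates enter one design.
    """
    K = templates.n_targets
    # stage 1 regresses across voxels, frame by frame: the sample size is the
    # stage-1 voxel count, not the number of time points
    if int(masks.stage1.sum()) <= K + 1:
        raise ValueError("need more stage-1 voxels than targets + 1")
    sel_t = _mask_selector(masks.stage1, templates.mask, "stage-1 mask")
    sel_b = _mask_selector(masks.stage1, bold.mask, "stage-1 mask")
    X = _standardize_columns(templates.values[sel_t], "template")
    _check_design(X, templates.target_names, "stage-1")
    Y = bold.values[:, sel_b]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    beta, *_ = np.linalg.lstsq(X, Yc.T, rcond=None)
    return MolecularTimeSeries(values=beta.T, target_names=templates.target_names)


def stage2_temporal_regression(
    bold: BoldRun, ts: MolecularTimeSeries, masks: StageMasks
) -> EnrichedMaps:
    """Joint OLS of every demeaned voxel time series on the standardized weights.

    Runs over the stage-2 (gray-matter) mask; coefficients are BOLD change per
    1 SD of the weight time series.
    """
    if ts.values.shape[0] != bold.n_timepoints:
        raise ValueError("weight time series and BOLD run disagree on time points")
    if bold.n_timepoints <= ts.values.shape[1] + 1:
        raise ValueError("need more time points than targets + 1 for stage 2")
    X = _standardize_columns(ts.values, "weight time series")
    _check_design(X, ts.target_names, "stage-2")
    sel = _mask_selector(masks.stage2, bold.mask, "stage-2 mask")
    Y = bold.values[:, sel]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    beta, *_ = np.linalg.lstsq(X, Yc, rcond=None)
    return EnrichedMaps(
        values=beta.T,
        target_names=ts.target_names,
        mask=masks.stage2,
        affine=bold.affine,
    )


def run_react(
    bold: BoldRun, templates: ReceptorTemplateSet, gm_mask: np.ndarray
) -> tuple[MolecularTimeSeries, EnrichedMaps]:
    """Full two-stage pipeline: mask construction, stage 1, stage 2."""
    masks = build_stage_masks(templates, gm_mask)
    ts = stage1_spatial_regression(bold, templates, masks)
    maps = stage2_temporal_regression(bold, ts, masks)
    return ts, maps
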