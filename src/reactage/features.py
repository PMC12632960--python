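"""Feature blocks, atlas parcellation and image-quality screening.

Voxel-wise enriched connectivity maps are reduced to regional means over a
label atlas; regional functional features and structural morphometry tables
are then assembled into the model configurations compared in the analysis:
three single-transporter blocks (DAT, NET, SERT), their concatenation (MEF),
the structural block (SMF) and the multimodal union (MMF).

Image-quality metric (IQM) tables are screened with the inner Tukey fences:
a value is an outlier when it lies below Q1 - 1.5*IQR or above Q3 + 1.5*IQR,
with quartiles computed by linear interpolation (type-7).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .react import EnrichedMaps, _check_mask

__all__ = [
    "ParcellationAtlas",
    "FeatureTable",
    "QcFlags",
    "FUNCTIONAL_BLOCKS",
    "BLOCK_NAMES",
    "parcellate",
    "assemble_blocks",
    "tukey_fence_flags",
    "write_feature_table",
    "read_feature_table",
]

FUNCTIONAL_BLOCKS = ("DAT", "NET", "SERT")
BLOCK_NAMES = ("DAT", "NET", "SERT", "MEF", "SMF", "MMF")

COVARIATE_COLUMNS = ("age", "sex", "site")

#: per-feature metadata columns carried by a FeatureTable
META_COLUMNS = ("block", "group", "nature", "parcel")


@dataclass
class ParcellationAtlas:
    """Integer label image (0 = background) with per-ROI names and groups.

    ``roi_groups`` records the parcel-set membership used for harmonization
    subgrouping (e.g. one of seven cortical networks, "subcortical",
    "cerebellar").
    """

    labels: np.ndarray  # int, 3-D
    roi_ids: np.ndarray  # (R,)
    roi_names: tuple[str, ...]
    roi_groups: tuple[str, ...]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be a 3-D integer image")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative (0 = background)")
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        self.roi_names = tuple(str(n) for n in self.roi_names)
        self.roi_groups = tuple(str(g) for g in self.roi_groups)
        if not (len(self.roi_ids) == len(self.roi_names) == len(self.roi_groups)):
            raise ValueError("roi_ids, roi_names and roi_groups must align")
        present = np.unique(self.labels)
        missing = set(self.roi_ids.tolist()) - set(present.tolist())
        if missing:
            raise ValueError(f"ROI ids absent from the label image: {sorted(missing)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def to_image(self):
        import nibabel as nib

        return nib.Nifti1Image(self.labels.astype(np.int16), self.affine)


def _as_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    return covariates


@dataclass
class FeatureTable:
    """Subjects x features matrix with per-feature and per-subject metadata.

    ``values``: DataFrame indexed by subject id, one column per feature.
    ``feature_meta``: DataFrame indexed by feature name with at least a
    ``block`` column plus ``group``/``nature`` used for harmonization
    subgrouping.  ``covariates``: DataFrame indexed like ``values`` with
    ``age`` (years), ``sex`` (0/1) and ``site`` columns.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.feature_meta.index):
            if set(self.values.columns) != set(self.feature_meta.index):
                raise ValueError("feature_meta must describe exactly the value columns")
            self.feature_meta = self.feature_meta.loc[self.values.columns]
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dup[:5]}")
        self.covariates = _as_covariates(self.covariates)
        if not self.values.index.equals(self.covariates.index):
            raise ValueError("values and covariates must share the subject index")
        if self.values.isna().any().any():
            raise ValueError("feature values must not contain missing entries")
        if "block" not in self.feature_meta.columns:
            raise ValueError("feature_meta requires a 'block' column")

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.feature_meta.copy(), self.covariates.copy()
        )


@dataclass
class QcFlags:
    """Per (subject, metric) Tukey-fence outlier flags with fence bounds."""

    flags: pd.DataFrame  # bool, subjects x metrics
    fences: pd.DataFrame  # metrics x {lower, upper}

    @property
    def flagged_subjects(self) -> pd.Index:
        return self.flags.index[self.flags.any(axis=1)]


def parcellate(maps: EnrichedMaps, atlas: ParcellationAtlas) -> np.ndarray:
    """Mean of each map over every ROI, restricted to the map's mask.

    Returns an (R, K) matrix ordered like ``atlas.roi_ids`` x map targets.
    Grids must match exactly; no resampling is performed.
    """
    if atlas.labels.shape != maps.mask.shape:
        raise ValueError("atlas and map grids differ in shape")
    if not np.allclose(atlas.affine, maps.affine):
        raise ValueError("atlas and map affines differ; resampling is not supported")
    labels_in = atlas.labels[maps.mask]
    minlength = int(max(atlas.roi_ids.max(), labels_in.max())) + 1
    counts = np.bincount(labels_in, minlength=minlength)
    empty = [
        name
        for rid, name in zip(atlas.roi_ids, atlas.roi_names)
        if counts[rid] == 0
    ]
    if empty:
        raise ValueError(f"ROI(s) with no in-mask voxels: {empty}")
    out = np.empty((atlas.n_rois, maps.values.shape[1]))
    for k in range(maps.values.shape[1]):
        sums = np.bincount(labels_in, weights=maps.values[:, k], minlength=minlength)
        with np.errstate(invalid="ignore"):
            means = sums / counts
        out[:, k] = means[atlas.roi_ids]
    return out


def _functional_frame(
    target: str, frame: pd.DataFrame, atlas: ParcellationAtlas
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if frame.shape[1] != atlas.n_rois:
        raise ValueError(
            f"{target}: expected {atlas.n_rois} regional columns, got {frame.shape[1]}"
        )
    cols = [f"{target}_{name}" for name in atlas.roi_names]
    vals = frame.copy()
    vals.columns = cols
    meta = pd.DataFrame(
        {
            "block": target,
            "group": list(atlas.roi_groups),
            "nature": "connectivity",
            "parcel": list(atlas.roi_names),
        },
        index=pd.Index(cols, name="feature"),
    )
    return vals, meta


def assemble_blocks(
    block: str,
    per_target: Mapping[str, pd.DataFrame] | None = None,
    atlas: ParcellationAtlas | None = None,
    structural: FeatureTable | None = None,
    covariates: pd.DataFrame | None = None,
) -> FeatureTable:
    """Assemble one of the six model configurations into a FeatureTable.

    ``per_target`` maps transporter name -> subjects x R regional-mean frame
    (as produced by :func:`parcellate`, one row per subject).  ``structural``
    supplies the SMF block.  Covariates are taken from ``covariates`` or, if
    absent, from the structural table.
    """
    block = block.upper()
    if block not in BLOCK_NAMES:
        raise ValueError(f"unknown block {block!r}; expected one of {BLOCK_NAMES}")

    pieces: list[tuple[pd.DataFrame, pd.DataFrame]] = []
    wanted = (
        [block]
        if block in FUNCTIONAL_BLOCKS
        else list(FUNCTIONAL_BLOCKS)
        if block in ("MEF", "MMF")
        else []
    )
    if wanted:
        if per_target is None or atlas is None:
            raise ValueError(f"{block} requires per-target regional frames and an atlas")
        for t in wanted:
            if t not in per_target:
                raise ValueError(f"missing regional frame for transporter {t!r}")
            pieces.append(_functional_frame(t, per_target[t], atlas))
    if block in ("SMF", "MMF"):
        if structural is None:
            raise ValueError(f"{block} requires the structural table")
        pieces.append((structural.values, structural.feature_meta))

    frames = [p[0] for p in pieces]
    idx = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(idx):
            if set(f.index) != set(idx):
                raise ValueError("blocks disagree on the subject set")
            raise ValueError("blocks list the same subjects in different orders")
    values = pd.concat(frames, axis=1)
    meta = pd.concat([p[1] for p in pieces], axis=0)
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column names across blocks: {dup[:5]}")

    if covariates is None:
        if structural is not None:
            covariates = structural.covariates
        else:
            raise ValueError("covariates are required for functional-only blocks")
    covariates = _as_covariates(covariates).loc[idx]
    return FeatureTable(values=values, feature_meta=meta, covariates=covariates)


def tukey_fence_flags(iqms: pd.DataFrame) -> QcFlags:
    """Flag IQM values outside the inner Tukey fences, metric by metric.

    Quartiles use linear interpolation (numpy default, type-7).  A constant
    metric has IQR 0 and yields no flags (the fence collapses onto the value
    shared by all subjects).
    """
    if len(iqms) < 4:
        raise ValueError("Tukey fences need at least 4 subjects per metric")
    arr = iqms.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("IQM table contains non-finite values")
    q1 = np.quantile(arr, 0.25, axis=0)
    q3 = np.quantile(arr, 0.75, axis=0)
    iqr = q3 - q1
    lower = q1 - 1.5 * iqr
    upper = q3 + 1.5 * iqr
    flags = (arr < lower) | (arr > upper)
    return QcFlags(
        flags=pd.DataFrame(flags, index=iqms.index, columns=iqms.columns),
        fences=pd.DataFrame(
            {"lower": lower, "upper": upper}, index=pd.Index(iqms.columns, name="metric")
        ),
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable as TSV (+ sidecar JSON for per-feature metadata).

    The TSV carries one header row, a ``subject`` column, the covariates and
    the feature columns at full float precision; feature block/group/nature
    metadata goes into ``<path>.meta.json`` so the round trip is lossless.
    """
    path = Path(path)
    out = pd.concat([table.covariates[list(COVARIATE_COLUMNS)], table.values], axis=1)
    out.index.name = "subject"
    out.to_csv(path, sep="\t")
    meta = {
        name: {
            k: (None if pd.isna(row.get(k)) else row.get(k)) for k in META_COLUMNS
        }
        for name, row in table.feature_meta.iterrows()
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a FeatureTable written by :func:`write_feature_table`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "subject" not in df.columns:
        raise ValueError("malformed feature TSV: missing 'subject' column")
    df = df.set_index("subject")
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    covariates = df[list(COVARIATE_COLUMNS)]
    values = df.drop(columns=list(COVARIATE_COLUMNS))
    values.columns.name = "feature"
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        raw = json.loads(meta_path.read_text())
        meta = pd.DataFrame.from_dict(raw, orient="index").reindex(values.columns)
        meta.index.name = "feature"
        if meta["block"].isna().any():
            raise ValueError("metadata sidecar does not describe every feature column")
    else:
        meta = pd.DataFrame(
            {"block": "NA", "group": "NA", "nature": None},
            index=pd.Index(values.columns, name="feature"),
        )
    return FeatureTable(values=values, feature_meta=meta, covariates=covariates)
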