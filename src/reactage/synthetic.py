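"""Synthetic inputs with known ground truth for every pipeline stage.

Everything downstream of raw-image preprocessing can be exercised without any
real cohort: BOLD runs carry a planted template-weighted low-rank signal, the
multi-site feature cohort follows the location/scale batch-effect generative
model (linear age effect, additive sex offset, per-site shift gamma and scale
delta on Gaussian residuals), the structural morphometry fixture reproduces
the 649-column composition of a FreeSurfer stats export, and IQM tables carry
planted gross outliers.

All generators are pure functions of (config, seed): the same seed yields
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .features import FeatureTable, ParcellationAtlas
from .react import BoldRun, ReceptorTemplateSet, build_stage_masks, rescale_template

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SCHAEFER7_NETWORKS",
    "DEFAULT_ATLAS_COMPOSITION",
    "make_brain_mask",
    "make_templates",
    "make_atlas",
    "make_weight_timeseries",
    "make_bold_run",
    "make_feature_meta",
    "make_cohort",
    "make_structural_block",
    "make_iqm_table",
]

SCHAEFER7_NETWORKS = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)

#: 200 cortical parcels over seven networks, 15 subcortical, 32 cerebellar = 247
DEFAULT_ATLAS_COMPOSITION: tuple[tuple[str, int], ...] = (
    ("Vis", 29),
    ("SomMot", 29),
    ("DorsAttn", 29),
    ("SalVentAttn", 29),
    ("Limbic", 28),
    ("Cont", 28),
    ("Default", 28),
    ("subcortical", 15),
    ("cerebellar", 32),
)

# Desikan-Killiany-Tourville cortical regions (31 per hemisphere)
DKT_REGIONS = (
    "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus", "entorhinal",
    "fusiform", "inferiorparietal", "inferiortemporal", "isthmuscingulate",
    "lateraloccipital", "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "parahippocampal", "paracentral", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "transversetemporal", "insula",
)
# Desikan-Killiany regions used for the WM parcellation (34 per hemisphere)
DK_WM_REGIONS = DKT_REGIONS + ("bankssts", "frontalpole", "temporalpole")

# (column suffix, measurement nature) for the 8 cortical surface metrics
CORTICAL_METRICS = (
    ("grayvol", "volume"),
    ("surfarea", "area"),
    ("thickavg", "thickness"),
    ("thickstd", "thickness"),
    ("foldind", "folding"),
    ("meancurv", "curvature"),
    ("gauscurv", "curvature"),
    ("curvind", "curvature"),
)

N_ASEG_VOLUMES = 85  # global + subcortical volumetric indices


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``sites`` lists (site id, subject count) pairs; ``beta_age`` (feature
    units per year) and ``beta_sex`` (feature units) may be scalars or
    per-feature arrays; ``site_shift``/``site_scale`` map site id to a scalar
    or per-feature location/scale batch effect.  ``noise_sd`` is the SD of
    the residual noise (BOLD voxel noise, or the cohort residual before the
    per-site scale is applied).
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_targets: int = 3
    n_timepoints: int = 120
    sites: tuple[tuple[str, int], ...] = (("siteA", 100), ("siteB", 100))
    age_range: tuple[float, float] = (18.0, 90.0)
    beta_age: float | np.ndarray = 0.1
    beta_sex: float | np.ndarray = 0.5
    site_shift: Mapping[str, float | np.ndarray] | None = None
    site_scale: Mapping[str, float | np.ndarray] | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 1 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        self.sites = tuple((str(s), int(n)) for s, n in self.sites)
        if any(n < 1 for _, n in self.sites):
            raise ValueError("every site needs at least one subject")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.site_scale is not None:
            for s, v in self.site_scale.items():
                if np.any(np.asarray(v) <= 0):
                    raise ValueError(f"site_scale must be positive (site {s!r})")

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.sites)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent seeded stream per generator."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted quantities returned alongside synthetic outputs."""

    true_weight_timeseries: np.ndarray | None = None  # (T, K)
    true_template_maps: np.ndarray | None = None  # (V, K), standardized
    true_age_slopes: np.ndarray | None = None  # (G,)
    true_sex_effects: np.ndarray | None = None  # (G,)
    true_intercepts: np.ndarray | None = None  # (G,)
    true_site_effects: dict[str, dict[str, np.ndarray]] | None = None


def make_brain_mask(grid_shape: Sequence[int]) -> np.ndarray:
    """Ellipsoidal 'brain' mask inscribed in the voxel grid."""
    nx, ny, nz = (int(g) for g in grid_shape)
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = (
        ((x - cx) / (0.48 * nx)) ** 2
        + ((y - cy) / (0.48 * ny)) ** 2
        + ((z - cz) / (0.48 * nz)) ** 2
    )
    mask = r <= 1.0
    if not mask.any():  # degenerate tiny grids: keep every voxel
        mask = np.ones((nx, ny, nz), dtype=bool)
    return mask


MAX_COLLINEARITY = 0.5  # pairwise voxel-wise Pearson bound between templates


def make_templates(cfg: SimulationConfig) -> ReceptorTemplateSet:
    """K smooth, spatially distinct density maps, min-max scaled to [0, 1].

    Each map is a Gaussian blob at a random in-mask center, blurred and
    rescaled; candidates are rejected until all pairwise voxel-wise Pearson
    correlations stay below 0.5, limiting spatial collinearity of the
    stage-1 design.  Raises if the grid cannot host that many distinct maps.
    """
    mask = make_brain_mask(cfg.grid_shape)
    rng = cfg.rng(1)
    coords = np.argwhere(mask)
    grids = np.indices(cfg.grid_shape, dtype=float)
    sigma = max(min(cfg.grid_shape) / 6.0, 1.0)
    accepted: list[np.ndarray] = []
    attempts, max_attempts = 0, 60 * cfg.n_targets
    while len(accepted) < cfg.n_targets:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {cfg.n_targets} spatially distinct templates on "
                f"grid {cfg.grid_shape} (pairwise correlation bound {MAX_COLLINEARITY})"
            )
        center = coords[rng.integers(len(coords))]
        d2 = sum((grids[i] - center[i]) ** 2 for i in range(3))
        blob = np.exp(-d2 / (2.0 * sigma**2))
        blob = gaussian_filter(blob, sigma=1.0)
        vals = rescale_template(blob, mask)[mask]
        if all(
            abs(np.corrcoef(vals, prev)[0, 1]) <= MAX_COLLINEARITY for prev in accepted
        ):
            accepted.append(vals)
    names = tuple(("DAT", "NET", "SERT")[k] if k < 3 else f"T{k + 1}" for k in range(cfg.n_targets))
    return ReceptorTemplateSet(
        values=np.column_stack(accepted), target_names=names, mask=mask
    )


def make_atlas(
    cfg: SimulationConfig,
    composition: Sequence[tuple[str, int]] = DEFAULT_ATLAS_COMPOSITION,
) -> ParcellationAtlas:
    """Partition the brain mask into labeled parcels per the composition.

    Voxels are ordered lexicographically and split into contiguous chunks, so
    every parcel is non-empty whenever the total parcel count does not exceed
    the in-mask voxel count.  Labels run 1..R; group metadata records the
    parcel set of each ROI for harmonization subgrouping.
    """
    mask = make_brain_mask(cfg.grid_shape)
    total = sum(int(n) for _, n in composition)
    if any(int(n) < 1 for _, n in composition):
        raise ValueError("every atlas group needs at least one parcel")
    n_vox = int(mask.sum())
    if total > n_vox:
        raise ValueError(
            f"{total} parcels requested but the mask has only {n_vox} voxels "
            "(parcels would be empty)"
        )
    flat_idx = np.flatnonzero(mask.ravel())  # lexicographic voxel order
    chunks = np.array_split(flat_idx, total)
    labels = np.zeros(mask.size, dtype=np.int32)
    roi_ids, roi_names, roi_groups = [], [], []
    rid = 0
    for group, n in composition:
        for i in range(int(n)):
            rid += 1
            labels[chunks[rid - 1]] = rid
            roi_ids.append(rid)
            roi_names.append(f"{group}_{i + 1}")
            roi_groups.append(str(group))
    return ParcellationAtlas(
        labels=labels.reshape(mask.shape),
        roi_ids=np.array(roi_ids),
        roi_names=tuple(roi_names),
        roi_groups=tuple(roi_groups),
    )


def make_weight_timeseries(cfg: SimulationConfig) -> np.ndarray:
    """Smooth random (T, K) weight time series to plant into a BOLD run."""
    rng = cfg.rng(2)
    ts = rng.standard_normal((cfg.n_timepoints, cfg.n_targets))
    ts = gaussian_filter1d(ts, sigma=2.0, axis=0)
    ts -= ts.mean(axis=0)
    ts /= ts.std(axis=0)
    return ts


def make_bold_run(
    cfg: SimulationConfig,
    templates: ReceptorTemplateSet,
    truth_ts: np.ndarray,
) -> tuple[BoldRun, GroundTruth]:
    """BOLD run with a planted template-weighted signal plus Gaussian noise.

    The signal is ``truth_ts @ Z.T`` on the joint stage-1 mask, where ``Z``
    is the template matrix standardized exactly as the stage-1 regression
    standardizes it; with ``noise_sd = 0`` the dual regression recovers
    ``truth_ts`` and maps proportional to ``Z`` to machine precision.
    """
    truth_ts = np.asarray(truth_ts, dtype=float)
    if truth_ts.ndim != 2 or truth_ts.shape[1] != templates.n_targets:
        raise ValueError("truth_ts must be (T, K) matching the template count")
    if cfg.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    masks = build_stage_masks(templates, templates.mask)
    sel = masks.stage1[templates.mask]
    Xs = templates.values[sel]
    Z = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0)
    T, V = truth_ts.shape[0], templates.n_voxels
    Y = np.zeros((T, V))
    Y[:, sel] = truth_ts @ Z.T
    if cfg.noise_sd > 0:
        Y += cfg.rng(3).normal(0.0, cfg.noise_sd, size=(T, V))
    true_maps = np.zeros((V, templates.n_targets))
    true_maps[sel] = Z
    bold = BoldRun(values=Y, mask=templates.mask, affine=templates.affine)
    truth = GroundTruth(true_weight_timeseries=truth_ts, true_template_maps=true_maps)
    return bold, truth


def make_feature_meta(
    n_features: int,
    blocks: Sequence[str] = ("DAT", "NET", "SERT"),
    groups: Sequence[str] = SCHAEFER7_NETWORKS + ("subcortical", "cerebellar"),
) -> pd.DataFrame:
    """Generic functional feature metadata cycling over blocks and groups."""
    names = [f"f{i:04d}" for i in range(n_features)]
    return pd.DataFrame(
        {
            "block": [blocks[i % len(blocks)] for i in range(n_features)],
            "group": [groups[(i // len(blocks)) % len(groups)] for i in range(n_features)],
            "nature": "connectivity",
        },
        index=pd.Index(names, name="feature"),
    )


def _per_feature(value: float | np.ndarray, n_features: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_features,)).copy()
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} must be finite")
    return arr


def make_cohort(
    cfg: SimulationConfig, feature_meta: pd.DataFrame
) -> tuple[FeatureTable, GroundTruth]:
    """Multi-site feature cohort following the ComBat generative model.

    Per subject j and feature g:
    ``x[j,g] = alpha_g + beta_age_g*age_j + beta_sex_g*sex_j
    + gamma_{site(j),g} + delta_{site(j),g} * eps`` with
    ``eps ~ N(0, noise_sd)``; ages uniform on ``age_range``, sex Bernoulli(1/2).
    Sites with fewer than 3 subjects are rejected (location/scale
    harmonization would be degenerate).
    """
    if any(n < 3 for _, n in cfg.sites):
        raise ValueError("every site needs at least 3 subjects for harmonization")
    rng = cfg.rng(4)
    G = len(feature_meta)
    n = cfg.n_subjects
    beta_age = _per_feature(cfg.beta_age, G, "beta_age")
    beta_sex = _per_feature(cfg.beta_sex, G, "beta_sex")

    site_names = [s for s, _ in cfg.sites]
    shift_cfg = cfg.site_shift
    scale_cfg = cfg.site_scale
    site_effects: dict[str, dict[str, np.ndarray]] = {}
    for i, s in enumerate(site_names):
        shift = shift_cfg[s] if shift_cfg is not None else 1.5 * i
        scale = scale_cfg[s] if scale_cfg is not None else 1.0 + 0.5 * i
        site_effects[s] = {
            "shift": _per_feature(shift, G, "site_shift"),
            "scale": _per_feature(scale, G, "site_scale"),
        }
        if np.any(site_effects[s]["scale"] <= 0):
            raise ValueError(f"site_scale must be positive (site {s!r})")

    ages = rng.uniform(*cfg.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    site = np.repeat(site_names, [c for _, c in cfg.sites])
    alpha = rng.normal(0.0, 1.0, size=G)

    eps = rng.normal(0.0, cfg.noise_sd, size=(n, G)) if cfg.noise_sd > 0 else np.zeros((n, G))
    X = alpha + np.outer(ages, beta_age) + np.outer(sex, beta_sex)
    for s in site_names:
        rows = site == s
        X[rows] += site_effects[s]["shift"]
        X[rows] += site_effects[s]["scale"] * eps[rows]

    subjects = pd.Index([f"sub-{i:04d}" for i in range(n)], name="subject")
    values = pd.DataFrame(X, index=subjects, columns=feature_meta.index)
    covariates = pd.DataFrame({"age": ages, "sex": sex, "site": site}, index=subjects)
    table = FeatureTable(values=values, feature_meta=feature_meta.copy(), covariates=covariates)
    truth = GroundTruth(
        true_age_slopes=beta_age,
        true_sex_effects=beta_sex,
        true_intercepts=alpha,
        true_site_effects=site_effects,
    )
    return table, truth


def _structural_columns() -> pd.DataFrame:
    """Metadata for the 649-column structural morphometry composition."""
    rows = []
    for i in range(N_ASEG_VOLUMES):
        rows.append((f"aseg_vol{i + 1:03d}", "aseg.stats", "volume"))
    for hemi in ("lh", "rh"):
        for region in DKT_REGIONS:
            for suffix, nature in CORTICAL_METRICS:
                rows.append((f"{hemi}_{region}_{suffix}", f"{hemi}.aparc.stats", nature))
    for hemi in ("lh", "rh"):
        for region in DK_WM_REGIONS:
            rows.append((f"wm_{hemi}_{region}", "wmparc.stats", "volume"))
    meta = pd.DataFrame(rows, columns=["feature", "group", "nature"]).set_index("feature")
    meta.insert(0, "block", "SMF")
    return meta


#: typical scale (location, spread) per measurement nature -- arbitrary units
_NATURE_SCALE = {
    "volume": (2000.0, 400.0),
    "area": (2500.0, 500.0),
    "thickness": (2.5, 0.25),
    "folding": (15.0, 3.0),
    "curvature": (0.15, 0.03),
}


def make_structural_block(
    n_subjects: int,
    seed: int,
    covariates: pd.DataFrame | None = None,
    beta_age: float | np.ndarray = 0.0,
) -> FeatureTable:
    """Structural morphometry fixture: 649 columns with stats-file metadata.

    Composition: 85 global/subcortical volumes, 2 hemispheres x 31 cortical
    regions x 8 surface metrics, and 68 regional WM volumes.  Values are
    Gaussian draws around nature-typical scales (arbitrary units); an
    optional linear age effect (``beta_age``, units per year, scaled by each
    column's spread) can be planted.  ``covariates`` defaults to a synthetic
    single-site cohort.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    meta = _structural_columns()
    rng = np.random.default_rng([int(seed), 5])
    G = len(meta)
    loc = np.empty(G)
    spread = np.empty(G)
    for g, nature in enumerate(meta["nature"]):
        m, s = _NATURE_SCALE[nature]
        loc[g] = rng.normal(m, 0.2 * m)
        spread[g] = abs(rng.normal(s, 0.2 * s)) + 1e-6

    subjects = pd.Index([f"sub-{i:04d}" for i in range(n_subjects)], name="subject")
    if covariates is None:
        ages = rng.uniform(18.0, 90.0, size=n_subjects)
        covariates = pd.DataFrame(
            {
                "age": ages,
                "sex": rng.integers(0, 2, size=n_subjects).astype(float),
                "site": "site0",
            },
            index=subjects,
        )
    else:
        covariates = covariates.copy()
        subjects = covariates.index
        ages = covariates["age"].to_numpy(dtype=float)

    slopes = _per_feature(beta_age, G, "beta_age") * spread
    X = loc + np.outer(ages, slopes) + rng.normal(0.0, 1.0, size=(n_subjects, G)) * spread
    values = pd.DataFrame(X, index=subjects, columns=meta.index)
    return FeatureTable(values=values, feature_meta=meta, covariates=covariates)


def make_structural_block_on_atlas(
    n_subjects: int,
    atlas: ParcellationAtlas,
    seed: int,
    covariates: pd.DataFrame | None = None,
    beta_age: float | np.ndarray = 0.0,
) -> FeatureTable:
    """Structural block for the common-parcellation analysis.

    One volumetric feature per atlas ROI, so structural and functional
    columns share identical parcel identifiers (recorded in the ``parcel``
    metadata column).  Values follow the same generative scheme as
    :func:`make_structural_block`.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng([int(seed), 7])
    R = atlas.n_rois
    m, s = _NATURE_SCALE["volume"]
    loc = rng.normal(m, 0.2 * m, size=R)
    spread = np.abs(rng.normal(s, 0.2 * s, size=R)) + 1e-6

    subjects = pd.Index([f"sub-{i:04d}" for i in range(n_subjects)], name="subject")
    if covariates is None:
        covariates = pd.DataFrame(
            {
                "age": rng.uniform(18.0, 90.0, size=n_subjects),
                "sex": rng.integers(0, 2, size=n_subjects).astype(float),
                "site": "site0",
            },
            index=subjects,
        )
    else:
        covariates = covariates.copy()
        subjects = covariates.index
    ages = covariates["age"].to_numpy(dtype=float)
    slopes = _per_feature(beta_age, R, "beta_age") * spread
    X = loc + np.outer(ages, slopes) + rng.normal(0.0, 1.0, size=(n_subjects, R)) * spread
    cols = [f"SMF_{name}" for name in atlas.roi_names]
    meta = pd.DataFrame(
        {
            "block": "SMF",
            "group": "atlas.stats",
            "nature": "volume",
            "parcel": list(atlas.roi_names),
        },
        index=pd.Index(cols, name="feature"),
    )
    values = pd.DataFrame(X, index=subjects, columns=cols)
    return FeatureTable(values=values, feature_meta=meta, covariates=covariates)


#: default IQM columns (structural + functional quality metrics)
IQM_METRICS = ("snr", "cnr", "efc", "tsnr", "fd_mean", "dvars_std")


def make_iqm_table(
    n_subjects: int,
    n_outliers: int,
    seed: int,
    metrics: Sequence[str] = IQM_METRICS,
) -> tuple[pd.DataFrame, pd.Index]:
    """IQM table with ``n_outliers`` planted gross outliers (>= 6 SD).

    Base variation per metric is uniform with the stated SD, hence bounded
    at +/-sqrt(3) SD -- strictly inside the inner Tukey fences, whose width
    for this base distribution is about +/-2 SD with a wide safety margin
    against sampling noise.  Planted rows displace one randomly chosen
    metric by 6-8 SD, guaranteeing a fence crossing; no unplanted value can
    cross.  Returns the table and the index of displaced rows.
    """
    if n_outliers >= n_subjects:
        raise ValueError("n_outliers must be smaller than n_subjects")
    if n_outliers < 0:
        raise ValueError("n_outliers must be non-negative")
    rng = np.random.default_rng([int(seed), 6])
    subjects = pd.Index([f"sub-{i:04d}" for i in range(n_subjects)], name="subject")
    loc = rng.uniform(5.0, 50.0, size=len(metrics))
    sd = rng.uniform(0.5, 5.0, size=len(metrics))
    half_width = np.sqrt(3.0)  # uniform with unit SD
    z = rng.uniform(-half_width, half_width, size=(n_subjects, len(metrics)))
    X = loc + sd * z
    planted = rng.choice(n_subjects, size=n_outliers, replace=False)
    planted.sort()
    for row in planted:
        m = int(rng.integers(len(metrics)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        X[row, m] = loc[m] + sign * (6.0 + 2.0 * rng.random()) * sd[m]
    table = pd.DataFrame(X, index=subjects, columns=list(metrics))
    return table, subjects[planted]
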