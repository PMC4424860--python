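"""The five component features that separate functional networks from artifacts.

Resting-state functional networks (RFNs) are expected to show compact,
gray-matter-centred suprathreshold activation with slow (< 0.08 Hz),
smoothly varying time courses; artifact components concentrate outside gray
matter (brain rim, ventricles), have extreme cluster geometry, or carry
high-frequency/spiky time courses.  Each feature quantifies one of these
manual-inspection criteria:

``gm_pos_overlap``
    Fraction of positive suprathreshold statistic mass inside the
    gray-matter mask (value-weighted), in [0, 1].
``peak_in_gm``
    1 if the suprathreshold peak voxel lies in gray matter, else 0.
``freq_ratio``
    Periodogram power of the time course inside the low-frequency band
    (default 0.01-0.08 Hz) divided by total power in (0, Nyquist].
``lag1_autocorr``
    Pearson correlation between the time course and its one-sample lag.
``bbox_voxel_ratio``
    Size-weighted mean over retained clusters of bounding-box volume over
    cluster size; 1 for a solid box, large for sheets/lines/shells.

Raw features are conditioned (mean-centred, scaled by the training-set
standard deviation) before entering the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .clusters import Cluster, ThresholdSpec, threshold_and_cluster
from .data import BinaryMask, Component, ICASet, ICTimeCourse, StatMap, check_same_grid

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_BAND",
    "FeatureVector",
    "ConditioningStats",
    "feat_gm_pos_overlap",
    "feat_peak_in_gm",
    "feat_freq_ratio",
    "feat_lag1_autocorr",
    "feat_bbox_voxel_ratio",
    "extract_features",
    "extract_feature_table",
    "fit_conditioning",
    "apply_conditioning",
    "andrews_projection",
]

FEATURE_NAMES = (
    "gm_pos_overlap",
    "peak_in_gm",
    "freq_ratio",
    "lag1_autocorr",
    "bbox_voxel_ratio",
)

DEFAULT_BAND = (0.01, 0.08)  # Hz; conventional low-frequency fluctuation band

#: bounding-box/voxel ratio assigned to components with no suprathreshold
#: cluster: the worst case for a single isolated voxel's 3x3x3 neighbourhood.
DEGENERATE_BBOX_RATIO = 27.0


@dataclass(frozen=True)
class FeatureVector:
    gm_pos_overlap: float
    peak_in_gm: float
    freq_ratio: float
    lag1_autocorr: float
    bbox_voxel_ratio: float
    conditioned: bool = False
    degenerate: bool = False

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(
        cls, values: np.ndarray, conditioned: bool = False, degenerate: bool = False
    ) -> "FeatureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise ValueError(f"expected 5 feature values, got shape {values.shape}")
        return cls(*values, conditioned=conditioned, degenerate=degenerate)


@dataclass(frozen=True)
class ConditioningStats:
    """Per-feature training-set mean and standard deviation (sample sd)."""

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if not (len(self.names) == self.mean.size == self.sd.size):
            raise ValueError("names, mean and sd must have matching lengths")
        if np.any(self.sd <= 0):
            bad = [n for n, s in zip(self.names, self.sd) if s <= 0]
            raise ValueError(f"zero-variance feature(s): {bad}")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd


def feat_gm_pos_overlap(stat_map: StatMap, suprathreshold: BinaryMask, gm: BinaryMask) -> float:
    """Positive statistic mass inside gray matter over total positive mass."""
    check_same_grid(stat_map.grid, suprathreshold.grid, "map and suprathreshold mask")
    check_same_grid(stat_map.grid, gm.grid, "map and gray-matter mask")
    values = stat_map.values
    pos = suprathreshold.membership & (values > 0)
    denom = float(values[pos].sum())
    if denom <= 0:
        warnings.warn("no positive suprathreshold mass; gm_pos_overlap defined as 0")
        return 0.0
    num = float(values[pos & gm.membership].sum())
    return num / denom


def feat_peak_in_gm(stat_map: StatMap, suprathreshold: BinaryMask, gm: BinaryMask) -> float:
    """1 iff the maximum suprathreshold statistic lies in gray matter.

    Ties are broken by the lowest linear (raster-order) voxel index.
    """
    check_same_grid(stat_map.grid, suprathreshold.grid, "map and suprathreshold mask")
    check_same_grid(stat_map.grid, gm.grid, "map and gray-matter mask")
    flat_idx = np.flatnonzero(suprathreshold.membership.ravel())
    if flat_idx.size == 0:
        warnings.warn("empty suprathreshold mask; peak_in_gm defined as 0")
        return 0.0
    vals = stat_map.values.ravel()[flat_idx]
    peak = flat_idx[int(np.argmax(vals))]  # argmax keeps the first (lowest) index on ties
    if vals.max() <= 0:
        warnings.warn("no positive suprathreshold statistic; peak_in_gm defined as 0")
        return 0.0
    return float(bool(gm.membership.ravel()[peak]))


def feat_freq_ratio(
    tc: ICTimeCourse,
    low_band: tuple[float, float] = DEFAULT_BAND,
    method: str = "periodogram",
) -> float:
    """Fraction of (non-DC) spectral power inside the low-frequency band.

    A plain (untapered) periodogram is the default for reproducibility;
    ``method="welch"`` averages Hann-windowed segments instead.
    """
    f_lo, f_hi = low_band
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"invalid band {low_band}")
    if tc.n_samples < 8:
        raise ValueError("frequency ratio needs at least 8 samples")
    if f_hi > tc.nyquist + 1e-12:
        raise ValueError(f"band upper edge {f_hi} Hz exceeds Nyquist {tc.nyquist} Hz")
    fs = 1.0 / tc.tr
    if method == "periodogram":
        freqs, psd = signal.periodogram(tc.samples, fs=fs, window="boxcar", detrend="constant")
    elif method == "welch":
        freqs, psd = signal.welch(tc.samples, fs=fs, nperseg=min(tc.n_samples, 128))
    else:
        raise ValueError(f"unknown method {method!r}")
    nonzero = freqs > 0
    total = float(psd[nonzero].sum())
    if total <= 0:
        warnings.warn("constant time course; freq_ratio defined as 0")
        return 0.0
    in_band = nonzero & (freqs >= f_lo) & (freqs <= f_hi)
    return float(psd[in_band].sum()) / total


def feat_lag1_autocorr(tc: ICTimeCourse) -> float:
    """Pearson correlation between the series and its one-sample lag."""
    x = tc.samples
    if x.size < 3:
        raise ValueError("need at least 3 samples for lag-1 autocorrelation")
    a, b = x[:-1], x[1:]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: lag-1 autocorrelation undefined for a constant series")
    return float(np.corrcoef(a, b)[0, 1])


def feat_bbox_voxel_ratio(clusters: list[Cluster]) -> float:
    """Size-weighted mean of (bounding-box volume / cluster size) over clusters."""
    if not clusters:
        warnings.warn(
            "no clusters; bbox_voxel_ratio defined as the degenerate worst case "
            f"{DEGENERATE_BBOX_RATIO}"
        )
        return DEGENERATE_BBOX_RATIO
    sizes = np.array([c.size for c in clusters], dtype=float)
    ratios = np.array([c.bbox_volume / c.size for c in clusters], dtype=float)
    return float((sizes * ratios).sum() / sizes.sum())


def extract_features(
    component: Component,
    gm: BinaryMask,
    spec: ThresholdSpec | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    connectivity: int = 6,
) -> FeatureVector:
    """Run the filtering rule and compute the raw five-feature vector.

    Components with no retained suprathreshold cluster get documented
    degenerate spatial defaults (0, 0, ratio 27) and are flagged so callers
    can force-label them as artifacts.
    """
    spec = spec or ThresholdSpec()
    check_same_grid(component.map.grid, gm.grid, "component map and gray-matter mask")
    supra, kept = threshold_and_cluster(component.map, spec, connectivity)
    tc = component.timecourse
    try:
        freq = feat_freq_ratio(tc, band)
    except ValueError:
        freq = 0.0
    try:
        lag1 = feat_lag1_autocorr(tc)
    except ValueError:
        lag1 = 0.0
    if not kept:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bbox = feat_bbox_voxel_ratio(kept)
        return FeatureVector(0.0, 0.0, freq, lag1, bbox, degenerate=True)
    return FeatureVector(
        gm_pos_overlap=feat_gm_pos_overlap(component.map, supra, gm),
        peak_in_gm=feat_peak_in_gm(component.map, supra, gm),
        freq_ratio=freq,
        lag1_autocorr=lag1,
        bbox_voxel_ratio=feat_bbox_voxel_ratio(kept),
    )


def extract_feature_table(
    ica_set: ICASet,
    gm: BinaryMask,
    spec: ThresholdSpec | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    connectivity: int = 6,
) -> pd.DataFrame:
    """Feature vectors for every component of a set, indexed by component id."""
    rows = {}
    degenerate = {}
    for comp in ica_set.components:
        fv = extract_features(comp, gm, spec, band, connectivity)
        rows[comp.id] = fv.to_array()
        degenerate[comp.id] = fv.degenerate
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    table.index.name = "component"
    table["degenerate"] = pd.Series(degenerate)
    return table.sort_index()


def fit_conditioning(vectors: list[FeatureVector] | np.ndarray) -> ConditioningStats:
    """Training-set mean and sample standard deviation per feature."""
    if isinstance(vectors, (list, tuple)):
        mat = np.stack([v.to_array() for v in vectors])
    else:
        mat = np.asarray(vectors, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("conditioning requires at least 2 training vectors")
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"zero-variance feature(s) in training set: {bad}")
    return ConditioningStats(tuple(FEATURE_NAMES[: mat.shape[1]]), mean, sd)


def apply_conditioning(vector: FeatureVector, stats: ConditioningStats) -> FeatureVector:
    """Mean-centre and scale a raw feature vector by the training statistics."""
    if vector.conditioned:
        raise ValueError("vector is already conditioned")
    z = stats.transform(vector.to_array())
    return FeatureVector.from_array(z, conditioned=True, degenerate=vector.degenerate)


def andrews_projection(x, t):
    """Andrews-curve value of a 5-feature vector at angle(s) ``t``.

    f(x, t) = x1 sin t + x2 cos t + x3 sin 2t + x4 cos 2t + x5 sin 3t,
    the projection of x onto [sin t, cos t, sin 2t, cos 2t, sin 3t]; plotted
    for t in [-pi, pi] it gives each component a unique curve in feature space.
    """
    if isinstance(x, FeatureVector):
        x = x.to_array()
    x = np.asarray(x, dtype=float)
    if x.shape != (5,):
        raise ValueError(f"expected a 5-component vector, got shape {x.shape}")
    t = np.asarray(t, dtype=float)
    value = (
        x[0] * np.sin(t)
        + x[1] * np.cos(t)
        + x[2] * np.sin(2 * t)
        + x[3] * np.cos(2 * t)
        + x[4] * np.sin(3 * t)
    )
    return float(value) if value.ndim == 0 else value
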