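"""Tracking a component across ICA decompositions of different model order.

An epsilon-SVR one-vs-rest model is trained on the conditioned five-feature
vectors of a reference decomposition (the reference component labeled 1,
all others 0).  Applied to a decomposition at another NIC, its raw
regression outputs - clipped to [0, 1] - serve as class probabilities; the
top-ranked component is the match.  Change between a reference component
and a candidate is quantified by CISOTA, the change index of spatial
overlap and temporal association:

    CISOTA = 1 / (spatial overlap x time-course correlation)

with spatial overlap the fraction of the reference's suprathreshold pattern
covered by the candidate's.  An unchanged component scores 1, the minimum;
when the overlap-correlation product is non-positive the index is undefined
and a flagged infinite sentinel is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .clusters import ThresholdSpec, threshold_and_cluster
from .data import BinaryMask, Component, ICASet, check_same_grid
from .features import DEFAULT_BAND, FEATURE_NAMES, ConditioningStats, extract_feature_table, fit_conditioning
from .svm import estimate_sigma, kernel_matrix

__all__ = [
    "TrackerModel",
    "TrackingResult",
    "CisotaValue",
    "train_tracker",
    "rank_components",
    "spatial_overlap",
    "cisota",
    "track_across_nic",
    "cross_sectional_change",
]


@dataclass
class TrackerModel:
    """Epsilon-SVR state for one reference component."""

    reference_id: int
    reference_nic: int
    support_vectors: np.ndarray
    dual_coefficients: np.ndarray
    bias: float
    sigma: float
    epsilon: float
    conditioning: ConditioningStats
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def predict(self, X: np.ndarray) -> np.ndarray:
        K = kernel_matrix(self.support_vectors, np.atleast_2d(X), self.sigma)
        return self.dual_coefficients @ K + self.bias


@dataclass
class TrackingResult:
    """Per-component probabilities and the descending-probability ranking."""

    probabilities: dict[int, float]
    ranking: list[int]
    matched_id: int

    def rank_of(self, comp_id: int) -> int:
        """1-based rank of a component in this result."""
        return self.ranking.index(comp_id) + 1


@dataclass(frozen=True)
class CisotaValue:
    spatial_overlap: float
    timecourse_r: float
    cisota: float

    @property
    def is_defined(self) -> bool:
        return np.isfinite(self.cisota)


def train_tracker(
    reference_set: ICASet,
    reference_id: int,
    gm: BinaryMask,
    spec: ThresholdSpec | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    epsilon: float = 0.1,
    cost: float = 100.0,
    sigma: float | None = None,
    seed: int | None = None,
    connectivity: int = 6,
) -> TrackerModel:
    """Fit the one-vs-rest epsilon-SVR for a reference component."""
    if reference_set.nic < 3:
        raise ValueError("reference set must have at least 3 components")
    if reference_id not in reference_set.ids():
        raise KeyError(f"reference id {reference_id} not in the reference set")
    table = extract_feature_table(reference_set, gm, spec, band, connectivity)
    mat = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    cond = fit_conditioning(mat)
    X = cond.transform(mat)
    y = (table.index.to_numpy() == reference_id).astype(float)
    if sigma is None:
        sigma = estimate_sigma(X, seed=seed)
    svr = SVR(kernel="rbf", C=cost, gamma=sigma, epsilon=epsilon)
    svr.fit(X, y)
    return TrackerModel(
        reference_id=int(reference_id),
        reference_nic=reference_set.nic,
        support_vectors=np.asarray(svr.support_vectors_, dtype=float),
        dual_coefficients=np.asarray(svr.dual_coef_[0], dtype=float),
        bias=float(svr.intercept_[0]),
        sigma=float(sigma),
        epsilon=float(epsilon),
        conditioning=cond,
    )


def rank_components(
    model: TrackerModel,
    target_set: ICASet,
    gm: BinaryMask,
    spec: ThresholdSpec | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    connectivity: int = 6,
) -> TrackingResult:
    """Score every component of a target set and rank by probability.

    Raw SVR outputs are clipped to [0, 1]; ties are broken by component id.
    """
    if target_set.nic == 0:
        raise ValueError("empty target set")
    table = extract_feature_table(target_set, gm, spec, band, connectivity)
    X = model.conditioning.transform(table[list(model.feature_names)].to_numpy(dtype=float))
    probs = np.clip(model.predict(X), 0.0, 1.0)
    ids = table.index.to_numpy()
    order = sorted(range(len(ids)), key=lambda i: (-probs[i], ids[i]))
    ranking = [int(ids[i]) for i in order]
    return TrackingResult(
        probabilities={int(cid): float(p) for cid, p in zip(ids, probs)},
        ranking=ranking,
        matched_id=ranking[0],
    )


def spatial_overlap(reference: BinaryMask, candidate: BinaryMask) -> float:
    """Fraction of the reference pattern covered by the candidate."""
    check_same_grid(reference.grid, candidate.grid, "overlap masks")
    n_ref = reference.n_true
    if n_ref == 0:
        raise ValueError("reference mask is empty")
    return float((reference.membership & candidate.membership).sum() / n_ref)


def _timecourse_r(a: Component, b: Component, absolute: bool) -> float:
    x, y = a.timecourse.samples, b.timecourse.samples
    if x.size != y.size:
        raise ValueError("time courses must have the same length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) time course")
    r = float(np.corrcoef(x, y)[0, 1])
    return abs(r) if absolute else r


def cisota(
    reference: Component,
    candidate: Component,
    spec: ThresholdSpec | None = None,
    connectivity: int = 6,
    absolute_r: bool = False,
) -> CisotaValue:
    """Change index of the candidate relative to the reference component.

    Both maps are binarized with the classification filtering rule
    (threshold + cluster extent) before the overlap is computed.
    ``absolute_r=True`` ignores the ICA sign ambiguity of time courses.
    """
    spec = spec or ThresholdSpec()
    check_same_grid(reference.map.grid, candidate.map.grid, "reference and candidate maps")
    ref_mask, _ = threshold_and_cluster(reference.map, spec, connectivity)
    cand_mask, _ = threshold_and_cluster(candidate.map, spec, connectivity)
    overlap = spatial_overlap(ref_mask, cand_mask)
    r = _timecourse_r(reference, candidate, absolute_r)
    product = overlap * r
    if product <= 0:
        warnings.warn("non-positive overlap x correlation: no association, CISOTA undefined")
        return CisotaValue(overlap, r, float("inf"))
    return CisotaValue(overlap, r, 1.0 / product)


@dataclass
class TrackingTable:
    """Per-NIC tracking summary for one reference component."""

    model: TrackerModel
    table: pd.DataFrame = field(repr=False)


def track_across_nic(
    series: list[ICASet],
    reference_nic: int,
    reference_id: int,
    gm: BinaryMask,
    spec: ThresholdSpec | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    epsilon: float = 0.1,
    cost: float = 100.0,
    sigma: float | None = None,
    seed: int | None = None,
    connectivity: int = 6,
    absolute_r: bool = False,
) -> TrackingTable:
    """Track a reference component through a series of decompositions.

    For every set other than the reference one, components are ranked by the
    SVR tracker and the top match is scored with CISOTA against the
    reference component.  Rows: nic, matched_id, probability, rank,
    spatial_overlap, timecourse_r, cisota.
    """
    if not series:
        raise ValueError("empty series")
    by_nic = {s.nic: s for s in series}
    if reference_nic not in by_nic:
        raise KeyError(f"no set with NIC={reference_nic} in the series")
    reference_set = by_nic[reference_nic]
    reference = reference_set.component(reference_id)
    model = train_tracker(
        reference_set, reference_id, gm, spec, band, epsilon, cost, sigma, seed, connectivity
    )
    rows = []
    for nic in sorted(by_nic):
        if nic == reference_nic:
            continue
        result = rank_components(model, by_nic[nic], gm, spec, band, connectivity)
        match = by_nic[nic].component(result.matched_id)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            change = cisota(reference, match, spec, connectivity, absolute_r)
        rows.append(
            {
                "nic": nic,
                "matched_id": result.matched_id,
                "probability": result.probabilities[result.matched_id],
                "rank": 1,
                "spatial_overlap": change.spatial_overlap,
                "timecourse_r": change.timecourse_r,
                "cisota": change.cisota,
            }
        )
    return TrackingTable(model, pd.DataFrame(rows))


def cross_sectional_change(
    series: list[ICASet],
    spec: ThresholdSpec | None = None,
    change_threshold: float = 2.0,
    connectivity: int = 6,
    absolute_r: bool = False,
) -> pd.DataFrame:
    """Count changed components between consecutive decompositions.

    For each consecutive NIC pair, every component of the lower-order set is
    matched to the candidate in the higher-order set with the strongest
    association (largest overlap x correlation, i.e. smallest CISOTA); a
    component counts as changed when its best-match CISOTA exceeds
    ``change_threshold`` (undefined CISOTA counts as changed).
    """
    spec = spec or ThresholdSpec()
    ordered = sorted(series, key=lambda s: s.nic)
    rows = []
    masks_cache: dict[int, dict[int, BinaryMask]] = {}

    def masks_for(ica_set: ICASet) -> dict[int, BinaryMask]:
        key = id(ica_set)
        if key not in masks_cache:
            masks_cache[key] = {
                c.id: threshold_and_cluster(c.map, spec, connectivity)[0]
                for c in ica_set.components
            }
        return masks_cache[key]

    for low, high in zip(ordered[:-1], ordered[1:]):
        low_masks, high_masks = masks_for(low), masks_for(high)
        n_changed = 0
        per_comp = {}
        for comp in low.components:
            ref_mask = low_masks[comp.id]
            best = float("inf")
            for cand in high.components:
                if ref_mask.n_true == 0:
                    break
                overlap = spatial_overlap(ref_mask, high_masks[cand.id])
                try:
                    r = _timecourse_r(comp, cand, absolute_r)
                except ValueError:
                    continue
                product = overlap * r
                if product > 0:
                    best = min(best, 1.0 / product)
            per_comp[comp.id] = best
            if best > change_threshold:
                n_changed += 1
        rows.append(
            {
                "nic": low.nic,
                "next_nic": high.nic,
                "n_components": low.nic,
                "n_changed": n_changed,
                "cisota_max_defined": max(
                    (v for v in per_comp.values() if np.isfinite(v)), default=float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
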