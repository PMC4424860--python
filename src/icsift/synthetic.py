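"""Seeded synthetic ICA result sets for testing and demonstration.

The generator emits pseudo-t statistic maps paired with time courses that
reproduce the qualitative signatures raters use to sort components:

* RFN-like components: one compact Gaussian blob centred inside the
  gray-matter shell, suprathreshold well beyond the 20-voxel extent rule,
  with a slow (0.01-0.05 Hz) band-limited time course.
* Artifact-like components, four styles: ``rim`` (a thin suprathreshold
  shell hugging the brain contour, the classic motion signature),
  ``ventricle`` (a blob inside the CSF region), ``spike`` (white-matter blob
  with large isolated time-course deviations), ``highfreq`` (white-matter
  blob with dominant power well above 0.08 Hz).

Tissue templates are nested ellipsoids: brain, a gray-matter shell and a
central ventricle (CSF) region.  Maps are generated directly as statistic
maps - no BOLD simulation or actual ICA decomposition is run, since the
framework consumes ICA outputs.  All outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ART, RFN, BinaryMask, Component, ICASet, ICTimeCourse, LabelTable, StatMap, VolumeGrid

__all__ = [
    "GeneratorConfig",
    "SplitPlan",
    "NicSeries",
    "make_templates",
    "make_rfn_component",
    "make_artifact_component",
    "make_ica_set",
    "make_nic_series",
]

ARTIFACT_STYLES = ("rim", "ventricle", "spike", "highfreq")

# ellipsoid radius fractions delimiting the nested tissue templates
_CSF_FRAC = 0.25
_GM_INNER = 0.52
_GM_OUTER = 0.95
_RIM_INNER = 0.97
_RIM_OUTER = 1.06
_WM_FRAC = 0.38  # radius fraction used for deep (white-matter) artifact blobs
_RFN_FRAC = 0.73  # radius fraction where RFN blobs are centred (mid gray matter)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate a small 3 mm isotropic acquisition: a 32x32x16 grid,
    200 timepoints at TR 2 s, blob amplitude 8 (t-like units) over unit
    noise so every planted pattern passes p < 0.001 with a cluster of well
    over 20 voxels.
    """

    dims: tuple[int, int, int] = (32, 32, 16)
    voxel_size: float = 3.0
    n_rfn: int = 10
    n_art: int = 20
    tr: float = 2.0
    n_timepoints: int = 200
    rfn_blob_radius: float = 2.0
    artifact_styles: tuple[str, ...] = ARTIFACT_STYLES
    effect_amplitude: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rfn + self.n_art < 2:
            raise ValueError("need at least 2 components in total")
        if self.effect_amplitude <= 0 or self.noise_sd <= 0:
            raise ValueError("amplitudes must be positive")
        bad = set(self.artifact_styles) - set(ARTIFACT_STYLES)
        if bad:
            raise ValueError(f"unknown artifact styles: {sorted(bad)}")

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid.isotropic(self.dims, self.voxel_size)


def _radius_fraction(dims: tuple[int, int, int]) -> np.ndarray:
    """Normalized ellipsoidal radius of every voxel (1.0 = brain surface)."""
    center = (np.asarray(dims) - 1) / 2.0
    semi = np.asarray(dims) * 0.45
    coords = np.indices(dims).astype(float)
    frac2 = sum(((coords[ax] - center[ax]) / semi[ax]) ** 2 for ax in range(3))
    return np.sqrt(frac2)


def make_templates(cfg: GeneratorConfig) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Nested ellipsoid tissue templates: (gray matter, CSF, brain).

    brain = central ellipsoid; CSF = small central (ventricle) ellipsoid;
    gray matter = outer shell of the brain, disjoint from CSF.
    """
    grid = cfg.grid
    frac = _radius_fraction(cfg.dims)
    brain = frac <= 1.0
    csf = frac <= _CSF_FRAC
    gm = (frac >= _GM_INNER) & (frac <= _GM_OUTER)
    if not (csf.any() and gm.any() and brain.any()):
        raise ValueError(f"grid {cfg.dims} too small for nested tissue templates")
    return BinaryMask(grid, gm), BinaryMask(grid, csf), BinaryMask(grid, brain)


def _blob(dims: tuple[int, int, int], center: np.ndarray, sigma: float) -> np.ndarray:
    coords = np.indices(dims).astype(float)
    d2 = sum((coords[ax] - center[ax]) ** 2 for ax in range(3))
    return np.exp(-d2 / (2.0 * sigma**2))


def _grid_center(dims: tuple[int, int, int]) -> np.ndarray:
    return (np.asarray(dims) - 1) / 2.0


def _shell_center(cfg: GeneratorConfig, frac: float, theta: float, z_jitter: float = 0.0) -> np.ndarray:
    center = _grid_center(cfg.dims)
    semi = np.asarray(cfg.dims) * 0.45
    offset = np.array([np.cos(theta) * semi[0] * frac, np.sin(theta) * semi[1] * frac, z_jitter])
    return center + offset


def _slow_timecourse(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(cfg.n_timepoints) * cfg.tr
    freqs = rng.uniform(0.012, 0.05, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    weights = rng.uniform(0.6, 1.0, size=3)
    sig = sum(w * np.sin(2 * np.pi * f * t + p) for w, f, p in zip(weights, freqs, phases))
    return sig + 0.2 * rng.standard_normal(t.size)


def _fast_timecourse(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(cfg.n_timepoints) * cfg.tr
    f = rng.uniform(0.15, min(0.22, 0.9 / (2 * cfg.tr)))
    sig = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return sig + 0.3 * rng.standard_normal(t.size)


def _spiky_timecourse(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    tc = 0.3 * rng.standard_normal(cfg.n_timepoints)
    n_spikes = max(4, cfg.n_timepoints // 25)
    where = rng.choice(cfg.n_timepoints, size=n_spikes, replace=False)
    tc[where] += rng.choice([-6.0, 6.0], size=n_spikes)
    return tc


def _noise_map(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    return cfg.noise_sd * rng.standard_normal(cfg.dims)


def make_rfn_component(
    cfg: GeneratorConfig,
    templates: tuple[BinaryMask, BinaryMask, BinaryMask],
    seed: int | np.random.Generator,
    comp_id: int = 0,
    blob_radius: float | None = None,
    theta: float | None = None,
) -> Component:
    """A gray-matter-centred compact blob with a slow time course."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi) if theta is None else theta
    sigma = blob_radius if blob_radius is not None else cfg.rfn_blob_radius + rng.uniform(-0.3, 0.3)
    center = _shell_center(cfg, _RFN_FRAC, theta, z_jitter=rng.uniform(-1.0, 1.0))
    values = _noise_map(cfg, rng) + cfg.effect_amplitude * _blob(cfg.dims, center, sigma)
    tc = _slow_timecourse(cfg, rng)
    return Component(comp_id, StatMap(cfg.grid, values), ICTimeCourse(tc, cfg.tr))


def make_artifact_component(
    cfg: GeneratorConfig,
    templates: tuple[BinaryMask, BinaryMask, BinaryMask],
    style: str,
    seed: int | np.random.Generator,
    comp_id: int = 0,
) -> Component:
    """An artifact-like component of the requested style."""
    if style not in ARTIFACT_STYLES:
        raise ValueError(f"unknown style {style!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frac = _radius_fraction(cfg.dims)
    values = _noise_map(cfg, rng)
    if style == "rim":
        shell = (frac >= _RIM_INNER) & (frac <= _RIM_OUTER)
        values[shell] += cfg.effect_amplitude * rng.uniform(0.6, 0.9, size=int(shell.sum()))
        tc = _fast_timecourse(cfg, rng)
    elif style == "ventricle":
        center = _grid_center(cfg.dims)
        values += cfg.effect_amplitude * _blob(cfg.dims, center, 1.5)
        tc = _fast_timecourse(cfg, rng)
    elif style == "spike":
        center = _shell_center(cfg, _WM_FRAC, rng.uniform(0, 2 * np.pi))
        values += cfg.effect_amplitude * _blob(cfg.dims, center, 2.0)
        tc = _spiky_timecourse(cfg, rng)
    else:  # highfreq
        center = _shell_center(cfg, _WM_FRAC, rng.uniform(0, 2 * np.pi))
        values += cfg.effect_amplitude * _blob(cfg.dims, center, 2.0)
        tc = _fast_timecourse(cfg, rng)
    return Component(comp_id, StatMap(cfg.grid, values), ICTimeCourse(tc, cfg.tr))


def make_ica_set(cfg: GeneratorConfig) -> tuple[ICASet, LabelTable]:
    """A shuffled labeled decomposition of n_rfn + n_art components."""
    rng = np.random.default_rng(cfg.seed)
    templates = make_templates(cfg)
    comps: list[tuple[Component, str]] = []
    for _ in range(cfg.n_rfn):
        comps.append((make_rfn_component(cfg, templates, rng), RFN))
    for k in range(cfg.n_art):
        style = cfg.artifact_styles[k % len(cfg.artifact_styles)]
        comps.append((make_artifact_component(cfg, templates, style, rng), ART))
    order = rng.permutation(len(comps))
    components = []
    entries = {}
    for new_id, idx in enumerate(order):
        comp, label = comps[idx]
        components.append(Component(new_id, comp.map, comp.timecourse))
        entries[new_id] = label
    return ICASet(components, source_tag=f"synthetic(seed={cfg.seed})"), LabelTable(entries)


@dataclass(frozen=True)
class SplitPlan:
    """Planted split: the reference blob appears intact below ``split_nic``
    and as two spatially complementary children at and above it."""

    split_nic: int | None = None


@dataclass
class NicSeries:
    """A series of decompositions of ascending model order with truth info."""

    sets: list[ICASet]
    labels: list[LabelTable]
    reference_ids: dict[int, list[int]] = field(default_factory=dict)  # nic -> ids

    def nics(self) -> list[int]:
        return [s.nic for s in self.sets]


@dataclass
class _Blueprint:
    kind: str  # "rfn" or an artifact style
    seed: int


def make_nic_series(
    cfg: GeneratorConfig,
    nic_list: list[int],
    split_plan: SplitPlan | None = None,
) -> NicSeries:
    """Generate decompositions at several model orders from one blueprint pool.

    The reference component (an RFN blob with a fixed time course) appears
    verbatim in every set below the planned split order; at and above it,
    the reference is replaced by two children whose suprathreshold regions
    partition the parent's (half-space masking of the parent signal), each
    sharing the parent's time course up to small noise.  All other
    components persist across model orders with fresh low-level noise only.
    """
    if list(nic_list) != sorted(nic_list):
        raise ValueError("nic_list must be ascending")
    split_plan = split_plan or SplitPlan()
    master = np.random.default_rng(cfg.seed)
    templates = make_templates(cfg)
    max_nic = max(nic_list)

    # deterministic blueprint pool: index 0 is the reference RFN
    blueprints: list[_Blueprint] = []
    art_cycle = 0
    for b in range(max_nic):
        bp_seed = int(master.integers(2**31 - 1))
        if b == 0 or b % 3 == 1:
            blueprints.append(_Blueprint("rfn", bp_seed))
        else:
            style = cfg.artifact_styles[art_cycle % len(cfg.artifact_styles)]
            art_cycle += 1
            blueprints.append(_Blueprint(style, bp_seed))

    # reference rendered once: fixed map and time course reused verbatim.
    # The reference is deliberately distinctive (larger blob, slower dominant
    # frequency) - it models tracking one specific named network.
    ref_rng = np.random.default_rng(blueprints[0].seed)
    ref_theta = ref_rng.uniform(0, 2 * np.pi)
    ref_sigma = cfg.rfn_blob_radius + 0.6
    ref_center = _shell_center(cfg, _RFN_FRAC, ref_theta)
    ref_signal = cfg.effect_amplitude * _blob(cfg.dims, ref_center, ref_sigma)
    ref_noise = _noise_map(cfg, ref_rng)
    t = np.arange(cfg.n_timepoints) * cfg.tr
    ref_tc = sum(
        w * np.sin(2 * np.pi * f * t + p)
        for w, f, p in zip(
            (1.0, 0.8, 0.6),
            (0.013, 0.016, 0.021),
            ref_rng.uniform(0, 2 * np.pi, size=3),
        )
    ) + 0.15 * ref_rng.standard_normal(t.size)
    reference = Component(0, StatMap(cfg.grid, ref_noise + ref_signal), ICTimeCourse(ref_tc, cfg.tr))

    x_index = np.indices(cfg.dims)[0]
    left_half = x_index <= ref_center[0]

    sets: list[ICASet] = []
    label_tables: list[LabelTable] = []
    reference_ids: dict[int, list[int]] = {}
    for nic in nic_list:
        per_nic = np.random.default_rng(np.random.SeedSequence([cfg.seed, nic, 7]))
        split = split_plan.split_nic is not None and nic >= split_plan.split_nic
        rendered: list[tuple[Component, str, bool]] = []  # (component, label, is_reference)
        if split:
            # children reuse the parent's noise field so their suprathreshold
            # regions partition the parent's exactly (complementary halves)
            child1 = Component(
                0,
                StatMap(cfg.grid, ref_noise + ref_signal * left_half),
                ICTimeCourse(ref_tc + 0.15 * per_nic.standard_normal(ref_tc.size), cfg.tr),
            )
            child2 = Component(
                0,
                StatMap(cfg.grid, ref_noise + ref_signal * ~left_half),
                ICTimeCourse(ref_tc + 0.15 * per_nic.standard_normal(ref_tc.size), cfg.tr),
            )
            rendered.append((child1, RFN, True))
            rendered.append((child2, RFN, True))
            others = blueprints[1 : nic - 1]
        else:
            rendered.append((reference, RFN, True))
            others = blueprints[1:nic]
        for bp in others:
            # intrinsic signal parameters come from the blueprint's own seed,
            # so a component persists across model orders; only a small
            # perturbation is fresh per NIC
            bp_rng = np.random.default_rng(bp.seed)
            if bp.kind == "rfn":
                comp = make_rfn_component(cfg, templates, bp_rng)
                # pool networks span a range of spectral quality (noisier
                # time courses), so the clean reference stays identifiable
                extra = bp_rng.uniform(0.5, 1.0)
                comp = Component(
                    comp.id,
                    comp.map,
                    ICTimeCourse(
                        comp.timecourse.samples
                        + extra * bp_rng.standard_normal(comp.timecourse.n_samples),
                        cfg.tr,
                    ),
                )
                label = RFN
            else:
                comp = make_artifact_component(cfg, templates, bp.kind, bp_rng)
                label = ART
            jitter_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, nic, bp.seed]))
            perturbed = Component(
                comp.id,
                StatMap(cfg.grid, comp.map.values + 0.2 * jitter_rng.standard_normal(cfg.dims)),
                ICTimeCourse(
                    comp.timecourse.samples
                    + 0.05 * jitter_rng.standard_normal(comp.timecourse.n_samples),
                    cfg.tr,
                ),
            )
            rendered.append((perturbed, label, False))
        order = per_nic.permutation(len(rendered))
        components, entries, ref_ids = [], {}, []
        for new_id, idx in enumerate(order):
            comp, label, is_ref = rendered[idx]
            components.append(Component(new_id, comp.map, comp.timecourse))
            entries[new_id] = label
            if is_ref:
                ref_ids.append(new_id)
        sets.append(ICASet(components, source_tag=f"synthetic nic={nic} seed={cfg.seed}"))
        label_tables.append(LabelTable(entries))
        reference_ids[nic] = ref_ids
    return NicSeries(sets, label_tables, reference_ids)
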