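"""Synthetic three-dendrite bundle phantoms with known ground truth.

The study system is a bundle of three labeled sensory dendrites, each about
0.5 µm in diameter, fasciculated into a tract roughly 0.9–1.5 µm wide that
runs tens of µm through the head.  No public microscopy accompanies the
method, so validation uses phantoms: three tubes offset on a slowly rotating
triangular frame around a gently curving centerline.  The frame is flattened
so the planned "middle" dendrite sits at the apex opposite the longest
triangle side — the planned order is realized geometrically, giving ground
truth for every downstream call.  Phantoms can be rendered to blurred, noisy
multi-channel stacks to exercise the tracer, or populations of middle-dendrite
labels can be drawn directly to exercise the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import LABELS, bin_boundaries, resample_polyline
from .order_stats import MiddlePopulation
from .tracing import DendriteTrace, VoxelStack

__all__ = [
    "BundleSpec",
    "GroundTruth",
    "generate_bundle_traces",
    "render_stack",
    "generate_population",
]

#: rendering photon budget: background mean, foreground = snr × background
_BACKGROUND_PHOTONS = 10.0
_READ_NOISE_PHOTONS = 1.0
#: noiseless (snr = inf) rendering uses these flat values
_NOISELESS_FG = 255.0
_NOISELESS_BG = 0.0


@dataclass
class BundleSpec:
    """Parameters of one synthetic bundle.

    Geometry defaults emulate a late-larval bundle: 0.5 µm-diameter dendrites
    (``tube_radius_um = 0.25``) at a nominal 1.1 µm center spacing, so the
    rendered bundle width (longest pairwise distance) averages ~1.1 µm with
    ~0.2 µm spread, contributed by a bounded along-bundle wobble
    (``spacing_wobble``) plus a smaller animal-to-animal scale factor
    (``spacing_cv``).

    ``order_model`` is one of ``fixed`` (one middle identity throughout),
    ``switch`` (``switch_from`` middle before ``switch_bin``, ``switch_to``
    from that bin on), or ``random`` (independent uniform identity per
    position).  ``noise_rate`` replaces each position's planned identity by a
    uniform draw with that probability.  ``defasc_segments`` lists
    ``(start_bin, end_bin, extra_width_um)`` stretches (1-based inclusive
    bins) where one outer dendrite is displaced outward, widening the bundle.
    """

    n_positions: int = 200
    n_bins: int = 100
    length_um: float = 60.0
    tube_radius_um: float = 0.25
    center_spacing_um: float = 1.1
    order_model: str = "fixed"
    middle_label: str = "AFD"
    switch_bin: int | None = None
    switch_from: str = "AFD"
    switch_to: str = "ASE"
    noise_rate: float = 0.0
    defasc_segments: tuple[tuple[int, int, float], ...] = ()
    voxel_spacing_um: tuple[float, float, float] = (0.15, 0.15, 0.3)
    psf_sigma_um: float = 0.15
    snr: float = 10.0
    apex_ratio: float = 0.35
    frame_rotations: float = 1.5
    curve_amp_um: float = 2.0
    spacing_cv: float = 0.08
    spacing_wobble: float = 0.22
    jitter_um: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order_model not in ("fixed", "switch", "random"):
            raise ValueError(f"unknown order model {self.order_model!r}")
        if (self.switch_bin is not None) != (self.order_model == "switch"):
            raise ValueError("switch_bin must be given iff order_model == 'switch'")
        if self.order_model == "switch" and not 1 <= self.switch_bin <= self.n_bins:
            raise ValueError(f"switch_bin must lie in [1, {self.n_bins}]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        for name in ("length_um", "tube_radius_um", "center_spacing_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacings must be positive")
        if self.center_spacing_um < 2 * self.tube_radius_um:
            raise ValueError(
                "infeasible geometry: center_spacing_um "
                f"({self.center_spacing_um}) < 2 × tube_radius_um "
                f"({2 * self.tube_radius_um}); tubes would merge"
            )
        if self.n_positions < max(2, self.n_bins):
            raise ValueError("n_positions must be at least n_bins (and ≥ 2)")


@dataclass
class GroundTruth:
    """Generator output: three traces plus the planted per-position truth."""

    traces: tuple[DendriteTrace, DendriteTrace, DendriteTrace]
    middle_labels: list[str]
    defasc_flags: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(t) for t in self.traces}
        if len(lengths) != 1:
            raise ValueError("ground-truth traces must have equal position counts")
        if len(self.middle_labels) != lengths.pop():
            raise ValueError("one middle label per position required")
        bad = set(self.middle_labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown middle labels: {sorted(bad)}")

    def trace(self, label: str) -> DendriteTrace:
        for t in self.traces:
            if t.label == label:
                return t
        raise KeyError(label)


def _planned_labels(
    order_model: str,
    n_units: int,
    rng: np.random.Generator,
    *,
    middle_label: str,
    switch_bin: int | None,
    switch_from: str,
    switch_to: str,
    noise_rate: float,
    unit_bins: np.ndarray | None = None,
) -> list[str]:
    """Planned middle identity per unit (bin or position), with label noise.

    ``unit_bins`` maps each unit to its 1-based bin for the switch model;
    identity when units are bins themselves.
    """
    if unit_bins is None:
        unit_bins = np.arange(1, n_units + 1)
    if order_model == "fixed":
        labels = np.array([middle_label] * n_units, dtype=object)
    elif order_model == "switch":
        labels = np.where(unit_bins < switch_bin, switch_from, switch_to).astype(object)
    else:  # random
        labels = rng.choice(LABELS, size=n_units).astype(object)
    if noise_rate > 0:
        flip = rng.random(n_units) < noise_rate
        labels[flip] = rng.choice(LABELS, size=int(flip.sum()))
    return list(labels)


def generate_bundle_traces(spec: BundleSpec) -> GroundTruth:
    """Build the three ground-truth polylines for one phantom animal.

    The centerline is a low-frequency 3D curve; at each axial sample the three
    dendrites sit on a triangular frame in the normal plane that rotates
    slowly along the bundle (``frame_rotations`` full turns), so middle calls
    are exercised under twisting.  The planned middle dendrite is placed at
    the apex of a flattened isoceles triangle whose base (length = local
    center spacing) is its longest side, which realizes the planned label
    geometrically.  Within ``defasc_segments`` one outer dendrite is displaced
    outward by the segment's ``extra_width_um``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    n = spec.n_positions
    t = np.linspace(0.0, 1.0, n)

    # gently curving centerline; base offset keeps everything at positive y/z
    base = spec.curve_amp_um + spec.center_spacing_um + 2.0
    amps = rng.uniform(0.3, 1.0, size=2) * spec.curve_amp_um
    freqs = rng.uniform(0.5, 1.2, size=2)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    center = np.column_stack(
        [
            1.0 + t * spec.length_um,
            base + amps[0] * np.sin(2 * np.pi * freqs[0] * t + phases[0]),
            base + amps[1] * np.sin(2 * np.pi * freqs[1] * t + phases[1]),
        ]
    )

    # orthonormal frame in the local normal plane, plus deliberate slow twist
    tangent = np.gradient(center, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    ref = np.array([0.0, 1.0, 0.0])
    u = ref - tangent * (tangent @ ref)[:, None]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(tangent, u)
    angle = 2 * np.pi * spec.frame_rotations * t + rng.uniform(0, 2 * np.pi)
    b_dir = np.cos(angle)[:, None] * u + np.sin(angle)[:, None] * v
    q_dir = -np.sin(angle)[:, None] * u + np.cos(angle)[:, None] * v

    # local center spacing: animal scale factor × bounded along-bundle wobble
    scale = max(rng.normal(1.0, spec.spacing_cv),
                2 * spec.tube_radius_um / spec.center_spacing_um + 0.05)
    wobble = spec.spacing_wobble * np.sin(
        2 * np.pi * rng.uniform(1.5, 3.5) * t + rng.uniform(0, 2 * np.pi)
    )
    s_local = spec.center_spacing_um * scale * (1.0 + wobble)

    edges = bin_boundaries(n, spec.n_bins)
    pos_bins = np.searchsorted(edges[1:], np.arange(n), side="right") + 1
    labels = _planned_labels(
        spec.order_model, n, rng,
        middle_label=spec.middle_label, switch_bin=spec.switch_bin,
        switch_from=spec.switch_from, switch_to=spec.switch_to,
        noise_rate=spec.noise_rate, unit_bins=pos_bins,
    )

    defasc_flags = np.zeros(n, dtype=bool)
    extra = np.zeros(n)
    for start_bin, end_bin, extra_width in spec.defasc_segments:
        in_seg = (pos_bins >= start_bin) & (pos_bins <= end_bin)
        defasc_flags |= in_seg
        extra[in_seg] = np.maximum(extra[in_seg], extra_width)

    points = {lab: np.empty((n, 3)) for lab in LABELS}
    h = spec.apex_ratio
    for i in range(n):
        mid = labels[i]
        o1, o2 = sorted(set(LABELS) - {mid})
        s = s_local[i]
        points[o1][i] = center[i] - 0.5 * s * b_dir[i]
        points[o2][i] = center[i] + (0.5 * s + extra[i]) * b_dir[i]
        points[mid][i] = center[i] + h * s * q_dir[i]
    if spec.jitter_um > 0:
        for lab in LABELS:
            points[lab] += rng.normal(0.0, spec.jitter_um, size=(n, 3))

    traces = tuple(
        DendriteTrace(points=points[lab], label=lab, source="ground_truth")
        for lab in LABELS
    )
    return GroundTruth(traces=traces, middle_labels=labels, defasc_flags=defasc_flags)


def render_stack(
    truth: GroundTruth,
    spec: BundleSpec,
    shape_zyx: tuple[int, int, int] | None = None,
) -> tuple[VoxelStack, VoxelStack, VoxelStack]:
    """Render one blurred, noisy image stack per dendrite channel.

    Tubes of ``tube_radius_um`` are drawn around each trace, blurred with an
    isotropic Gaussian of ``psf_sigma_um``, and corrupted with Poisson signal
    noise plus Gaussian read noise at the requested signal-to-background
    ratio.  ``snr = inf`` renders a noiseless binary stack.  Voxel indices map
    to physical coordinates as ``index × spacing``; ground-truth traces live
    in the same frame.
    """
    sx, sy, sz = spec.voxel_spacing_um
    margin = 3 * spec.tube_radius_um + 3 * spec.psf_sigma_um + 0.5
    all_pts = np.vstack([t.points for t in truth.traces])
    if shape_zyx is None:
        hi = all_pts.max(axis=0) + margin
        shape_zyx = (
            int(np.ceil(hi[2] / sz)) + 1,
            int(np.ceil(hi[1] / sy)) + 1,
            int(np.ceil(hi[0] / sx)) + 1,
        )
    nz, ny, nx = shape_zyx
    bounds_um = np.array([(nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz])
    for t in truth.traces:
        out = (t.points < 0).any(axis=1) | (t.points > bounds_um).any(axis=1)
        if out.any():
            bad = t.points[np.flatnonzero(out)[0]]
            raise ValueError(
                f"trace {t.label!r} exits stack bounds at (x={bad[0]:.2f}, "
                f"y={bad[1]:.2f}, z={bad[2]:.2f}) µm; stack extent is "
                f"{tuple(np.round(bounds_um, 2))} µm"
            )

    noiseless = np.isinf(spec.snr)
    fg = _NOISELESS_FG if noiseless else spec.snr * _BACKGROUND_PHOTONS
    bg = _NOISELESS_BG if noiseless else _BACKGROUND_PHOTONS
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    spacing = np.array([sx, sy, sz])
    step = min(sx, sy, sz) / 2.0

    stacks = []
    for trace in truth.traces:
        n_dense = max(len(trace), int(np.ceil(trace.arc_length_um / step)) + 1)
        dense = (
            resample_polyline(trace.points, n_dense) if len(trace) > 1 else trace.points
        )
        idx = np.round(dense / spacing).astype(int)
        seed_mask = np.zeros(shape_zyx, dtype=bool)
        seed_mask[idx[:, 2], idx[:, 1], idx[:, 0]] = True
        dist = ndimage.distance_transform_edt(~seed_mask, sampling=(sz, sy, sx))
        img = np.where(dist <= spec.tube_radius_um, fg, bg).astype(float)
        if spec.psf_sigma_um > 0:
            img = ndimage.gaussian_filter(
                img, sigma=(spec.psf_sigma_um / sz, spec.psf_sigma_um / sy, spec.psf_sigma_um / sx)
            )
        if not noiseless:
            img = rng.poisson(img).astype(float) + rng.normal(
                0.0, _READ_NOISE_PHOTONS, size=img.shape
            )
            img = np.clip(img, 0.0, None)
        stacks.append(
            VoxelStack(
                intensities=img.astype(np.float32),
                spacing_um=spec.voxel_spacing_um,
                channel_label=trace.label,
            )
        )
    return tuple(stacks)


def generate_population(
    order_model: str,
    n_animals: int,
    n_bins: int = 100,
    seed: int | None = None,
    switch_bin: int | None = None,
    noise_rate: float = 0.0,
    middle_label: str = "AFD",
    switch_from: str = "AFD",
    switch_to: str = "ASE",
    cohort: str = "",
) -> MiddlePopulation:
    """Draw a cohort of per-bin middle labels directly, bypassing imaging.

    ``random`` draws every animal × bin label independently and uniformly over
    the three identities — the simulated random cohort the order statistics
    are compared against.  ``fixed``/``switch`` follow the planned identity
    with per-label replacement probability ``noise_rate``.
    """
    if order_model not in ("fixed", "switch", "random"):
        raise ValueError(f"unknown order model {order_model!r}")
    if (switch_bin is not None) != (order_model == "switch"):
        raise ValueError("switch_bin must be given iff order_model == 'switch'")
    if n_animals < 0:
        raise ValueError("n_animals must be non-negative")
    rng = np.random.default_rng(seed)
    idx = {lab: k for k, lab in enumerate(LABELS)}
    counts = np.zeros((n_bins, 3), dtype=int)
    animal_labels = np.empty((n_animals, n_bins), dtype=object)
    for a in range(n_animals):
        labels = _planned_labels(
            order_model, n_bins, rng,
            middle_label=middle_label, switch_bin=switch_bin,
            switch_from=switch_from, switch_to=switch_to, noise_rate=noise_rate,
        )
        animal_labels[a] = labels
        for b, lab in enumerate(labels):
            counts[b, idx[lab]] += 1
    return MiddlePopulation(
        counts=counts, n_animals=n_animals, cohort=cohort, animal_labels=animal_labels
    )
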