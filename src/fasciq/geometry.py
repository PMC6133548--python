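"""Cross-section geometry of a three-dendrite bundle.

Three traced dendrites are cropped to a matched extent, averaged into a
centroid line, and sliced into cross-sections.  Each section is a triangle
whose vertices are the nearest trace points to the centroid sample; its side
lengths are the pairwise inter-dendrite distances, the longest side is the
bundle-width proxy, and the vertex opposite the longest side is the dendrite
"in the middle".  Distances are finally averaged into 100 equal bins of
normalized bundle length so positions can be compared across animals of
different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .tracing import DendriteTrace

__all__ = [
    "CrossSection",
    "BundleProfile",
    "crop_to_common_extent",
    "centroid_line",
    "cross_sections",
    "middle_dendrite",
    "bin_profile",
    "bin_boundaries",
]

#: canonical dendrite identities (and plotting order)
LABELS = ("AWA", "AFD", "ASE")

#: unordered label pairs, canonical column order of the distance spreadsheet
PAIRS = (("AWA", "ASE"), ("AWA", "AFD"), ("AFD", "ASE"))

#: two pairwise distances closer than this (µm) count as an exact tie
TIE_TOL_UM = 1e-9


@dataclass
class CrossSection:
    """One triangle slice through the bundle.

    ``points`` maps dendrite label to its (x, y, z) µm coordinate (``None``
    when the section was re-read from a distance CSV, which stores only the
    side lengths).  ``d_pairs`` maps each unordered label pair to its
    Euclidean distance in µm.
    """

    position_index: int
    d_pairs: dict[tuple[str, str], float]
    points: dict[str, np.ndarray] | None = None
    width: float = field(init=False)
    middle: str = field(init=False)
    ambiguous: bool = field(init=False)

    def __post_init__(self) -> None:
        if set(self.d_pairs) != {tuple(p) for p in PAIRS}:
            raise ValueError(f"d_pairs must be keyed by {PAIRS}")
        self.width = max(self.d_pairs.values())
        self.middle, self.ambiguous = middle_dendrite(self.d_pairs)


@dataclass
class BundleProfile:
    """Length-normalized per-bin summary of one animal's bundle."""

    animal_id: str
    bin_d_pairs: dict[tuple[str, str], np.ndarray]
    bin_width: np.ndarray
    bin_middle: list[str]
    bin_ambiguous: np.ndarray
    head_length_um: float | None = None
    stage: str = ""
    defasciculated: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.bin_width)


def _tips(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return points[0], points[-1]


def crop_to_common_extent(
    t1: DendriteTrace, t2: DendriteTrace, t3: DendriteTrace
) -> tuple[DendriteTrace, DendriteTrace, DendriteTrace]:
    """Crop three traces so they span a matched extent of the bundle.

    At each end in turn: average the three tip coordinates at the *opposite*
    end, pick the dendrite whose tip at this end lies nearest that average
    (the dendrite reaching least far), and re-anchor the other two traces at
    their points closest to the chosen tip.  This reproduces the
    shortest-dendrite cropping used before centroid construction.
    """
    pts = [t.points.copy() for t in (t1, t2, t3)]

    for end in (1, 0):  # crop the far (end) side first, then the near (start) side
        other = 1 - end
        avg_opposite = np.mean([_tips(p)[other] for p in pts], axis=0)
        reach = [np.linalg.norm(_tips(p)[end] - avg_opposite) for p in pts]
        chosen = int(np.argmin(reach))
        anchor = _tips(pts[chosen])[end]
        for i in range(3):
            if i == chosen:
                continue
            j = int(np.argmin(np.linalg.norm(pts[i] - anchor, axis=1)))
            pts[i] = pts[i][: j + 1] if end == 1 else pts[i][j:]
        for i, p in enumerate(pts):
            if len(p) < 2:
                raise ValueError(
                    f"cropping reduced trace {i + 1} to fewer than 2 points; "
                    "traces may not overlap"
                )

    return tuple(
        DendriteTrace(points=p, label=t.label, source=t.source)
        for p, t in zip(pts, (t1, t2, t3))
    )


def resample_polyline(points: np.ndarray, n_samples: int) -> np.ndarray:
    """Resample a polyline to ``n_samples`` points equally spaced in arc length."""
    points = np.asarray(points, dtype=float)
    if n_samples < 2 or len(points) < 2:
        raise ValueError("need at least 2 samples and 2 points")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_samples)
    return np.column_stack([np.interp(targets, s, points[:, k]) for k in range(3)])


def centroid_line(
    t1: DendriteTrace, t2: DendriteTrace, t3: DendriteTrace, n_samples: int | None = None
) -> np.ndarray:
    """Mean polyline of three (cropped) traces.

    Each trace is resampled to a common number of equal-arc-length samples —
    by default the finest of the three native resolutions — and corresponding
    samples are averaged.
    """
    if n_samples is None:
        n_samples = max(len(t1), len(t2), len(t3))
    if n_samples < 2:
        raise ValueError("centroid line needs at least 2 samples")
    rs = [resample_polyline(t.points, n_samples) for t in (t1, t2, t3)]
    return np.mean(rs, axis=0)


def middle_dendrite(
    d_pairs: dict[tuple[str, str], float], tie_tol: float = TIE_TOL_UM
) -> tuple[str, bool]:
    """Identity of the dendrite opposite the longest triangle side.

    Returns ``(label, ambiguous)``.  When the two largest distances agree
    within ``tie_tol`` (including the fully degenerate zero-distance case)
    the call is flagged ambiguous and resolved by fixed alphabetical priority
    among the candidate middles.
    """
    items = sorted(d_pairs.items(), key=lambda kv: -kv[1])
    (pair_max, d_max), (_, d_second) = items[0], items[1]
    all_labels = set(LABELS)
    if d_max - d_second <= tie_tol:
        tied_pairs = [p for p, d in items if d_max - d <= tie_tol]
        # each tied longest side nominates the vertex opposite it; resolve by priority
        label = sorted(set().union(*[all_labels - set(p) for p in tied_pairs]))[0]
        return label, True
    (label,) = all_labels - set(pair_max)
    return label, False


def cross_sections(
    t1: DendriteTrace,
    t2: DendriteTrace,
    t3: DendriteTrace,
    centroid: np.ndarray | None = None,
) -> list[CrossSection]:
    """Slice the bundle into per-centroid-sample triangles.

    Walking the centroid line point by point, the Euclidean-nearest point on
    each trace forms the section triangle.  Pairwise distances and the middle
    call are invariant to rigid motion of the whole bundle, so twisting of the
    bundle does not corrupt the order readout.
    """
    traces = (t1, t2, t3)
    labels = [t.label for t in traces]
    if len(set(labels)) != 3:
        raise ValueError(f"traces must carry three distinct labels, got {labels}")
    if centroid is None:
        centroid = centroid_line(t1, t2, t3)
    centroid = np.asarray(centroid, dtype=float)

    trees = {t.label: cKDTree(t.points) for t in traces}
    nearest = {
        lab: tree.data[tree.query(centroid)[1]] for lab, tree in trees.items()
    }

    sections: list[CrossSection] = []
    for i in range(len(centroid)):
        pts = {lab: np.asarray(nearest[lab][i]) for lab in labels}
        d_pairs = {
            tuple(p): float(np.linalg.norm(pts[p[0]] - pts[p[1]])) for p in PAIRS
        }
        sections.append(CrossSection(position_index=i, d_pairs=d_pairs, points=pts))
    return sections


def bin_boundaries(n_positions: int, n_bins: int = 100) -> np.ndarray:
    """Bin edges over positions: bin k spans [round((k-1)N/B), round(kN/B))."""
    return np.round(np.arange(n_bins + 1) * n_positions / n_bins).astype(int)


def bin_profile(
    sections: list[CrossSection],
    n_bins: int = 100,
    animal_id: str = "",
    head_length_um: float | None = None,
    stage: str = "",
) -> BundleProfile:
    """Average pairwise distances within ``n_bins`` equal segments of the bundle.

    Bin 1 is the distal (nose-tip) end.  The bin's middle label is derived
    from the binned mean distances, and bin means conserve the global mean
    when weighted by bin size.  With 200 sections each bin holds exactly two
    adjacent positions.
    """
    n = len(sections)
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} sections, got {n}")
    edges = bin_boundaries(n, n_bins)

    series = {
        tuple(p): np.array([s.d_pairs[tuple(p)] for s in sections]) for p in PAIRS
    }
    width_series = np.array([s.width for s in sections])

    bin_d = {p: np.empty(n_bins) for p in series}
    bin_w = np.empty(n_bins)
    bin_mid: list[str] = []
    bin_amb = np.zeros(n_bins, dtype=bool)
    for k in range(n_bins):
        lo, hi = edges[k], edges[k + 1]
        means = {p: float(series[p][lo:hi].mean()) for p in series}
        for p in series:
            bin_d[p][k] = means[p]
        bin_w[k] = float(width_series[lo:hi].mean())
        label, amb = middle_dendrite(means)
        bin_mid.append(label)
        bin_amb[k] = amb

    return BundleProfile(
        animal_id=animal_id,
        bin_d_pairs=bin_d,
        bin_width=bin_w,
        bin_middle=bin_mid,
        bin_ambiguous=bin_amb,
        head_length_um=head_length_um,
        stage=stage,
    )
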