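"""Defasciculation classification against an age-matched reference cohort.

A bundle is called defasciculated when its width (longest pairwise
inter-dendrite distance) exceeds the reference mean by more than 3.5 standard
deviations for at least 10 consecutive normalized positions.  Under a normal
model a 3.5-SD two-sided exceedance is roughly a 1-in-2000 event per data
point, so a sustained 10-bin run is far outside chance for cohorts of
hundreds of bundles.  Defasciculated bundles are excluded from dendrite-order
statistics (they still appear, highlighted, on width plots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BundleProfile

__all__ = [
    "ReferenceProfile",
    "DefascResult",
    "reference_stats",
    "classify_defasciculation",
    "exclude_defasciculated",
]

Z_THRESHOLD = 3.5
RUN_LENGTH = 10


@dataclass
class ReferenceProfile:
    """Per-bin width distribution of an age-matched (wild-type) cohort."""

    mean: np.ndarray
    sd: np.ndarray
    cohort_size: int
    stage: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")
        if self.cohort_size < 2:
            raise ValueError("reference cohort needs at least 2 animals")

    @property
    def n_bins(self) -> int:
        return len(self.mean)


@dataclass
class DefascResult:
    defasciculated: bool
    flagged_runs: list[tuple[int, int]]  # 1-based inclusive bin ranges
    z_scores: np.ndarray


def reference_stats(profiles: list[BundleProfile], stage: str = "") -> ReferenceProfile:
    """Per-bin sample mean and SD (ddof=1) of bundle width across a cohort."""
    if len(profiles) < 2:
        raise ValueError("reference cohort needs at least 2 profiles")
    n_bins = {p.n_bins for p in profiles}
    if len(n_bins) != 1:
        raise ValueError(f"profiles have mixed bin counts: {sorted(n_bins)}")
    widths = np.vstack([p.bin_width for p in profiles])
    return ReferenceProfile(
        mean=widths.mean(axis=0),
        sd=widths.std(axis=0, ddof=1),
        cohort_size=len(profiles),
        stage=stage,
    )


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 1-based inclusive (start, end) bin ranges."""
    runs = []
    padded = np.concatenate([[False], mask, [False]])
    changes = np.flatnonzero(np.diff(padded.astype(int)))
    for lo, hi in zip(changes[::2], changes[1::2]):
        runs.append((int(lo) + 1, int(hi)))
    return runs


def classify_defasciculation(
    profile: BundleProfile,
    ref: ReferenceProfile,
    z_threshold: float = Z_THRESHOLD,
    run_length: int = RUN_LENGTH,
) -> DefascResult:
    """Apply the sustained width-excursion rule.

    z(bin) = (width − ref.mean) / ref.sd, one-sided: only excursions above the
    mean count.  Zero-SD bins get z = 0 when width ≤ mean and z = +inf
    otherwise, so a degenerate reference never divides by zero.
    """
    if profile.n_bins != ref.n_bins:
        raise ValueError(
            f"profile has {profile.n_bins} bins but reference has {ref.n_bins}"
        )
    w = profile.bin_width
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w - ref.mean) / ref.sd
    degenerate = ref.sd == 0
    z[degenerate & (w <= ref.mean)] = 0.0
    z[degenerate & (w > ref.mean)] = np.inf

    exceed = z > z_threshold
    flagged = [r for r in _runs_of_true(exceed) if r[1] - r[0] + 1 >= run_length]
    return DefascResult(
        defasciculated=bool(flagged), flagged_runs=flagged, z_scores=z
    )


def exclude_defasciculated(
    profiles: list[BundleProfile], results: list[DefascResult]
) -> tuple[list[BundleProfile], list[BundleProfile]]:
    """Partition a cohort into (retained, excluded) by the classification.

    Retained profiles feed the order statistics; excluded ones appear only on
    width plots.  The ``defasciculated`` flag is set on each profile.
    """
    if len(profiles) != len(results):
        raise ValueError(
            f"{len(profiles)} profiles but {len(results)} classification results"
        )
    retained, excluded = [], []
    for p, r in zip(profiles, results):
        p.defasciculated = r.defasciculated
        (excluded if r.defasciculated else retained).append(p)
    return retained, excluded
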