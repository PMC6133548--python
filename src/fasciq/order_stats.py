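"""Population-level statistics of dendrite order.

The order readout per animal is categorical: which of the three dendrites is
"in the middle" at each of 100 normalized positions along the bundle.  Cohorts
are compared position by position.  Against an idealized random arrangement a
chi-squared test with expected counts n/3 applies when counts are large
enough; the workhorse, valid at any counts, is a permutation test that uses
the Fisher 3×2 exact test as its statistic: the two cohorts are merged,
randomly re-split 500 times, and the nominal p-value is ranked among the 501
resulting p-values.  Low ranks (< 25/501 ~ p<0.05, < 5/501 ~ p<0.01) mean the
cohorts differ by more than sampling error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .geometry import LABELS, BundleProfile

__all__ = [
    "MiddlePopulation",
    "PermutationResult",
    "SwitchPoint",
    "tabulate_population",
    "chi_squared_vs_random",
    "fisher_exact_3x2",
    "simulate_random_counts",
    "permutation_rank",
    "compare_populations",
    "rank_threshold",
    "rank_to_significance",
    "majority_profile",
    "detect_switch_point",
    "compare_switch_points",
]

DEFAULT_ITERATIONS = 500

#: relative slack when comparing enumerated hypergeometric probabilities;
#: same role as the relative error guard in standard exact-test implementations
_REL_TOL = 1e-7


@dataclass
class MiddlePopulation:
    """Per-bin counts of which dendrite is in the middle across a cohort.

    ``counts`` has shape (n_bins, 3) with columns in ``LABELS`` order
    (AWA, AFD, ASE); rows sum to ``n_animals``.  ``animal_labels`` (optional,
    shape (n_animals, n_bins)) keeps per-animal calls for population plots.
    """

    counts: np.ndarray
    n_animals: int
    cohort: str = ""
    animal_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must be an (n_bins, 3) array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        sums = self.counts.sum(axis=1)
        if np.any(sums != self.n_animals):
            raise ValueError("per-bin counts must sum to n_animals at every bin")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def fractions(self) -> np.ndarray:
        return self.counts / max(self.n_animals, 1)


@dataclass
class PermutationResult:
    """Permutation-rank outcome for one bin."""

    nominal_p: float
    resampled_p: np.ndarray
    rank: int
    iterations: int = DEFAULT_ITERATIONS
    seed: int | None = None

    @property
    def total(self) -> int:
        return self.iterations + 1

    @property
    def tier(self) -> str:
        return rank_to_significance(self.rank, self.total)


@dataclass
class SwitchPoint:
    bin_index: int  # 1-based
    from_label: str
    to_label: str


def tabulate_population(
    profiles: Sequence[BundleProfile], cohort: str = ""
) -> MiddlePopulation:
    """Count middle-dendrite identities per bin across retained animals."""
    if not profiles:
        raise ValueError("cannot tabulate an empty cohort")
    n_bins = {p.n_bins for p in profiles}
    if len(n_bins) != 1:
        raise ValueError(f"profiles have mixed bin counts: {sorted(n_bins)}")
    flagged = [p.animal_id for p in profiles if p.defasciculated]
    if flagged:
        raise ValueError(
            f"defasciculated bundles must be excluded before tabulation: {flagged}"
        )
    nb = n_bins.pop()
    idx = {lab: k for k, lab in enumerate(LABELS)}
    counts = np.zeros((nb, 3), dtype=int)
    animal_labels = np.empty((len(profiles), nb), dtype=object)
    for i, p in enumerate(profiles):
        for b, lab in enumerate(p.bin_middle):
            counts[b, idx[lab]] += 1
            animal_labels[i, b] = lab
    return MiddlePopulation(
        counts=counts, n_animals=len(profiles), cohort=cohort, animal_labels=animal_labels
    )


def chi_squared_vs_random(counts: Sequence[int], n: int | None = None) -> tuple[float, float]:
    """Chi-squared test of the observed middle counts against uniform n/3.

    Refuses when the expected count n/3 falls below 5, where the chi-squared
    approximation breaks down — use the permutation test instead.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3,) or np.any(counts < 0):
        raise ValueError("counts must be three non-negative values")
    total = float(counts.sum())
    if n is None:
        n = total
    elif n != total:
        raise ValueError(f"counts sum to {total}, not the stated n={n}")
    expected = n / 3.0
    if expected < 5:
        raise ValueError(
            f"expected count n/3 = {expected:.2f} < 5; the chi-squared "
            "approximation is invalid — use the permutation test"
        )
    stat = float(((counts - expected) ** 2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=2))


@lru_cache(maxsize=200_000)
def _fisher_p_cached(r1: int, a: int, b: int, c1: int, c2: int, c3: int) -> float:
    """Exact 2×3 Fisher p for the table [[a, b, r1-a-b], [c1-a, c2-b, ...]].

    Enumerates every table with the same margins; p is the total probability
    of tables no more probable than the observed one under the multivariate
    hypergeometric null.
    """
    n = c1 + c2 + c3
    denom = math.comb(n, r1)
    p_obs = (
        math.comb(c1, a) * math.comb(c2, b) * math.comb(c3, r1 - a - b) / denom
    )
    total = 0.0
    cutoff = p_obs * (1 + _REL_TOL)
    for aa in range(min(c1, r1) + 1):
        rem = r1 - aa
        comb_a = math.comb(c1, aa)
        for bb in range(max(0, rem - c3), min(c2, rem) + 1):
            prob = comb_a * math.comb(c2, bb) * math.comb(c3, rem - bb) / denom
            if prob <= cutoff:
                total += prob
    return min(total, 1.0)


def fisher_exact_3x2(table: Sequence[Sequence[int]]) -> float:
    """Fisher's exact test for a 2-cohort × 3-category count table.

    Computed by full enumeration of margin-consistent tables (no asymptotic
    fallback); feasible for the cohort sizes this pipeline uses (tens of
    animals).  Invariant to row order and to permuting the three categories.
    """
    t = np.asarray(table, dtype=int)
    if t.shape == (3, 2):
        t = t.T
    if t.shape != (2, 3) or np.any(t < 0):
        raise ValueError("table must be 2×3 (or 3×2) with non-negative integers")
    if t.sum() == 0:
        return 1.0
    r1 = int(t[0].sum())
    c1, c2, c3 = (int(c) for c in t.sum(axis=0))
    return _fisher_p_cached(r1, int(t[0, 0]), int(t[0, 1]), c1, c2, c3)


def simulate_random_counts(
    n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """One random cohort: n animals, middle identity uniform over the three."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, [1 / 3] * 3)


def permutation_rank(
    obs: Sequence[int],
    test: Sequence[int],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator | None = None,
    ties: str = "conservative",
) -> PermutationResult:
    """Permutation test for one bin's middle-dendrite counts.

    The nominal p comes from the Fisher 3×2 test of obs vs. test.  Each
    iteration merges the two cohorts' animals, re-splits them uniformly at
    random into two equal-sized groups (⌈N/2⌉ / ⌊N/2⌋ when N is odd) and
    recomputes the Fisher p; re-splitting is drawn directly from the
    multivariate hypergeometric distribution, which is equivalent to shuffling
    individual animal labels.  The rank places the nominal p among all
    ``iterations + 1`` p-values.

    Fisher p-values are discrete, so resampled values tie with the nominal
    one.  ``ties='conservative'`` (default, used for reporting) counts tied
    values below the nominal — identical cohorts then rank maximally (501)
    and the rank never overstates significance.  ``ties='randomized'`` draws
    the position within the tie block uniformly, which makes null ranks
    exactly uniform on {1..iterations+1}; use it for calibration studies.
    """
    obs = np.asarray(obs, dtype=int)
    test = np.asarray(test, dtype=int)
    if obs.shape != (3,) or test.shape != (3,):
        raise ValueError("obs and test must each be three counts")
    if ties not in ("conservative", "randomized"):
        raise ValueError(f"unknown tie rule {ties!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    nominal = fisher_exact_3x2([obs, test])
    merged = obs + test
    n_total = int(merged.sum())
    n1 = (n_total + 1) // 2
    g1 = rng.multivariate_hypergeometric(merged, n1, size=iterations)
    resampled = np.array(
        [fisher_exact_3x2([row, merged - row]) for row in g1]
    )
    n_below = int(np.sum(resampled < nominal * (1 - 1e-12)))
    n_tied = int(np.sum(np.abs(resampled - nominal) <= nominal * 1e-12))
    if ties == "conservative":
        rank = 1 + n_below + n_tied
    else:
        rank = 1 + n_below + int(rng.integers(0, n_tied + 1))
    return PermutationResult(
        nominal_p=float(nominal),
        resampled_p=resampled,
        rank=rank,
        iterations=iterations,
        seed=seed if isinstance(seed, int) else None,
    )


def compare_populations(
    pop_a: MiddlePopulation,
    pop_b: MiddlePopulation,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    ties: str = "conservative",
) -> list[PermutationResult]:
    """Per-bin permutation ranks comparing two cohorts.

    One master seed; each bin gets an independent child stream so bins are
    reproducible in isolation and mutually independent.
    """
    if pop_a.n_bins != pop_b.n_bins:
        raise ValueError("populations must have the same number of bins")
    streams = np.random.SeedSequence(seed).spawn(pop_a.n_bins)
    return [
        permutation_rank(
            pop_a.counts[b], pop_b.counts[b], iterations=iterations,
            seed=np.random.default_rng(streams[b]), ties=ties,
        )
        for b in range(pop_a.n_bins)
    ]


def rank_threshold(alpha: float, total: int = DEFAULT_ITERATIONS + 1) -> int:
    """Largest rank r with r/total < alpha (e.g. 25 for alpha=0.05, total=501)."""
    return int(math.ceil(alpha * total)) - 1


def rank_to_significance(rank: int, total: int = DEFAULT_ITERATIONS + 1) -> str:
    """Map a permutation rank to a tier: 'p<0.01', 'p<0.05' or 'ns'."""
    if not 1 <= rank <= total:
        raise ValueError(f"rank must lie in [1, {total}], got {rank}")
    if rank <= rank_threshold(0.01, total):
        return "p<0.01"
    if rank <= rank_threshold(0.05, total):
        return "p<0.05"
    return "ns"


def majority_profile(pop: MiddlePopulation) -> list[str]:
    """Per-bin majority middle label (alphabetical priority on exact ties)."""
    out = []
    for row in pop.counts:
        top = row.max()
        out.append(sorted(LABELS[k] for k in range(3) if row[k] == top)[0])
    return out


def detect_switch_point(labels: Sequence[str]) -> SwitchPoint | None:
    """First position where the middle dendrite changes and persists.

    Returns the first bin (1-based) whose label differs from bin 1's label
    and holds for at least 2 consecutive bins; single-bin blips are ignored.
    ``None`` when the middle identity never durably changes.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("label sequence is empty")
    first = labels[0]
    n = len(labels)
    for i in range(1, n):
        if labels[i] != first and i + 1 < n and labels[i + 1] == labels[i]:
            return SwitchPoint(bin_index=i + 1, from_label=first, to_label=labels[i])
    return None


def compare_switch_points(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of switch-point positions.

    Used because switch positions are not normally distributed.  Returns the
    KS statistic and asymptotic p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
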