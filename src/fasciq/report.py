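"""Figure and table generation.

Plot conventions follow the study's figures: identity colors yellow (AWA),
blue (AFD), red (ASE); per-animal color columns for population plots; three
fraction curves for summary plots; permutation ranks as a log-scale color bar
(blue for comparison to random, red for comparison to a reference cohort);
width plots with a 2 µm gray guide inside a 6 µm box, defasciculated animals
overlaid in pink.  Every figure gets a machine-readable CSV twin — no number
appears only in a plot.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap, LogNorm

from .geometry import LABELS, BundleProfile
from .fasciculation import ReferenceProfile
from .order_stats import MiddlePopulation, PermutationResult

__all__ = [
    "IDENTITY_COLORS",
    "save_width_plot",
    "save_population_plot",
    "save_summary_plot",
    "save_rank_bars",
]

IDENTITY_COLORS = {"AWA": "#f2c200", "AFD": "#2e5fe8", "ASE": "#d62728"}
_EXCLUDED_COLOR = "#f781bf"  # pink overlay for defasciculated animals


def _twin_csv(df: pd.DataFrame, png_path: Path) -> Path:
    csv_path = png_path.with_suffix(".csv")
    df.to_csv(csv_path, index=False)
    return csv_path


def save_width_plot(
    retained: list[BundleProfile],
    excluded: list[BundleProfile],
    path: str | Path,
    ref: ReferenceProfile | None = None,
    y_max_um: float = 6.0,
    guide_um: float = 2.0,
) -> Path:
    """Overlay per-animal bundle-width traces; excluded animals in pink."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.axhspan(0, guide_um, color="0.88", zorder=0)
    rows = []
    for p in retained:
        bins = np.arange(1, p.n_bins + 1)
        ax.plot(bins, p.bin_width, color="0.3", lw=0.8)
        rows.append(pd.DataFrame({"animal_id": p.animal_id, "bin": bins,
                                  "width_um": p.bin_width, "excluded": False}))
    for p in excluded:
        bins = np.arange(1, p.n_bins + 1)
        ax.plot(bins, p.bin_width, color=_EXCLUDED_COLOR, lw=1.0)
        rows.append(pd.DataFrame({"animal_id": p.animal_id, "bin": bins,
                                  "width_um": p.bin_width, "excluded": True}))
    if ref is not None:
        bins = np.arange(1, ref.n_bins + 1)
        ax.plot(bins, ref.mean, color="k", lw=1.5, label="reference mean")
        ax.fill_between(bins, ref.mean - ref.sd, ref.mean + ref.sd, alpha=0.2, color="k")
    ax.set(xlabel="bundle position (bin)", ylabel="bundle width (µm)",
           ylim=(0, y_max_um))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    _twin_csv(pd.concat(rows, ignore_index=True) if rows else
              pd.DataFrame(columns=["animal_id", "bin", "width_um", "excluded"]), path)
    return path


def save_population_plot(pop: MiddlePopulation, path: str | Path) -> Path:
    """One color column per animal: the middle dendrite at each bin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if pop.animal_labels is None:
        raise ValueError("population carries no per-animal labels")
    idx = {lab: k for k, lab in enumerate(LABELS)}
    grid = np.vectorize(idx.get)(pop.animal_labels).T  # bins × animals
    cmap = ListedColormap([IDENTITY_COLORS[lab] for lab in LABELS])
    fig, ax = plt.subplots(figsize=(max(2, 0.25 * pop.n_animals + 1), 4))
    ax.imshow(grid, aspect="auto", cmap=cmap, vmin=-0.5, vmax=2.5,
              origin="upper", interpolation="nearest")
    ax.set(xlabel="animal", ylabel="bundle position (bin)", title=pop.cohort)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    df = pd.DataFrame(
        pop.animal_labels.T,
        columns=[f"animal_{i + 1}" for i in range(pop.n_animals)],
    )
    df.insert(0, "bin", np.arange(1, pop.n_bins + 1))
    _twin_csv(df, path)
    return path


def save_summary_plot(pop: MiddlePopulation, path: str | Path) -> Path:
    """Fraction of animals with each dendrite in the middle, per bin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frac = pop.fractions()
    bins = np.arange(1, pop.n_bins + 1)
    fig, ax = plt.subplots(figsize=(5, 3))
    for k, lab in enumerate(LABELS):
        ax.plot(bins, frac[:, k], color=IDENTITY_COLORS[lab], label=lab)
    ax.set(xlabel="bundle position (bin)", ylabel="fraction in middle",
           ylim=(-0.02, 1.02), title=pop.cohort)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    df = pd.DataFrame({"bin": bins, **{lab: frac[:, k] for k, lab in enumerate(LABELS)}})
    _twin_csv(df, path)
    return path


def save_rank_bars(
    results: list[PermutationResult], path: str | Path, color: str = "blue"
) -> Path:
    """Permutation ranks per bin as a log-scale color bar.

    ``color='blue'`` marks a comparison against random, ``'red'`` against a
    reference cohort.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ranks = np.array([r.rank for r in results], dtype=float)
    total = results[0].total if results else 501
    cmap = {"blue": "Blues_r", "red": "Reds_r"}.get(color, color)
    fig, ax = plt.subplots(figsize=(5, 1.2))
    im = ax.imshow(ranks[None, :], aspect="auto", cmap=cmap,
                   norm=LogNorm(vmin=1, vmax=total), interpolation="nearest")
    ax.set_yticks([])
    ax.set_xlabel("bundle position (bin)")
    fig.colorbar(im, ax=ax, label=f"rank (of {total})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    df = pd.DataFrame(
        {
            "bin": np.arange(1, len(results) + 1),
            "nominal_p": [r.nominal_p for r in results],
            "rank": [r.rank for r in results],
            "total": [r.total for r in results],
            "tier": [r.tier for r in results],
        }
    )
    _twin_csv(df, path)
    return path
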