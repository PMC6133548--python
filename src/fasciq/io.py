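"""File formats and run configuration.

Stacks travel as multi-page TIFF with a JSON sidecar carrying the voxel
spacing; traces and per-position pairwise distances as CSV (comma-separated,
'.' decimal, UTF-8, header row); ground truth, manifests, configs and
summaries as JSON (configs also as YAML).  The distance CSV is the pivot of
the workflow: downstream statistics can run from it without re-tracing, which
is what makes trim-by-row-deletion corrections possible.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .geometry import PAIRS, CrossSection
from .synthetic import GroundTruth
from .tracing import DendriteTrace, VoxelStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_trace_csv",
    "read_trace_csv",
    "write_distance_csv",
    "read_distance_csv",
    "write_ground_truth",
    "read_ground_truth",
    "AnimalManifest",
    "RunConfig",
    "load_config",
]

_DIST_COLUMNS = ["position", "d_AWA_ASE", "d_AWA_AFD", "d_AFD_ASE"]
_PAIR_BY_COLUMN = {"d_AWA_ASE": ("AWA", "ASE"), "d_AWA_AFD": ("AWA", "AFD"),
                   "d_AFD_ASE": ("AFD", "ASE")}


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write one channel as multi-page TIFF plus a spacing sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.intensities, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps(
            {"spacing_um": list(stack.spacing_um), "channel_label": stack.channel_label},
            indent=1,
        )
    )
    return path


def read_stack(path: str | Path, channel: int | None = None) -> VoxelStack:
    """Read a TIFF stack; spacing must come from the JSON sidecar.

    ``channel`` selects one channel of a 4D (channel-first) file.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 4:
        if channel is None:
            raise ValueError(
                f"{path} holds {arr.shape[0]} channels; a channel index is required"
            )
        arr = arr[channel]
    if arr.ndim != 3:
        raise ValueError(
            f"{path} is {arr.ndim}D; expected a 3D (z, y, x) image stack"
        )
    side = _sidecar(path)
    if not side.exists():
        raise ValueError(
            f"no voxel-spacing metadata for {path}: sidecar {side.name} is required"
        )
    meta = json.loads(side.read_text())
    return VoxelStack(
        intensities=arr,
        spacing_um=tuple(meta["spacing_um"]),
        channel_label=meta.get("channel_label", ""),
    )


def write_trace_csv(trace: DendriteTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_um", "y_um", "z_um"])
        for p in trace.points:
            w.writerow([repr(float(v)) for v in p])
    return path


def read_trace_csv(path: str | Path, label: str = "") -> DendriteTrace:
    pts = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            pts.append([float(v) for v in row[:3]])
    return DendriteTrace(points=np.asarray(pts), label=label, source="imported")


def write_distance_csv(sections: list[CrossSection], path: str | Path) -> Path:
    """Per-position pairwise distances, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_DIST_COLUMNS)
        for s in sections:
            w.writerow(
                [s.position_index]
                + [repr(float(s.d_pairs[_PAIR_BY_COLUMN[c]])) for c in _DIST_COLUMNS[1:]]
            )
    return path


def read_distance_csv(path: str | Path) -> list[CrossSection]:
    """Rebuild cross-sections (distances, width, middle calls) from CSV.

    Vertex coordinates are not stored in the spreadsheet, so ``points`` is
    ``None`` on the returned sections.  Malformed rows raise with their line
    number.  A header-only file yields an empty list.
    """
    sections: list[CrossSection] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _DIST_COLUMNS:
            raise ValueError(f"{path}: expected header {','.join(_DIST_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                pos = int(row[0])
                vals = [float(v) for v in row[1:4]]
                if len(row) < 4:
                    raise ValueError
            except (ValueError, IndexError):
                raise ValueError(f"{path}: malformed row at line {lineno}: {row!r}")
            d_pairs = dict(zip((_PAIR_BY_COLUMN[c] for c in _DIST_COLUMNS[1:]), vals))
            sections.append(CrossSection(position_index=pos, d_pairs=d_pairs))
    return sections


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "traces": {t.label: t.points.tolist() for t in truth.traces},
        "middle_labels": list(truth.middle_labels),
        "defasc_flags": truth.defasc_flags.astype(bool).tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    traces = tuple(
        DendriteTrace(points=np.asarray(pts), label=lab, source="ground_truth")
        for lab, pts in payload["traces"].items()
    )
    return GroundTruth(
        traces=traces,
        middle_labels=list(payload["middle_labels"]),
        defasc_flags=np.asarray(payload["defasc_flags"], dtype=bool),
    )


@dataclass
class AnimalManifest:
    """Where one animal's data lives and how to trace it.

    Encodes the manual steps of the original workflow: per-channel stack
    paths, clicked start/end voxels (x, y, z), trim counts for the
    row-deletion correction, and the head-length normalizer.
    """

    animal_id: str
    stacks: dict[str, str]
    endpoints: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]]
    trim: dict[str, tuple[int, int]] = field(default_factory=dict)
    head_length_um: float | None = None
    stage: str = ""

    def __post_init__(self) -> None:
        if set(self.stacks) != set(self.endpoints):
            raise ValueError("manifest must give endpoints for every channel")
        if len(self.stacks) != 3:
            raise ValueError("manifest must list exactly three channels")


def load_manifests(path: str | Path) -> list[AnimalManifest]:
    entries = json.loads(Path(path).read_text())
    return [
        AnimalManifest(
            animal_id=e["animal_id"],
            stacks=e["stacks"],
            endpoints={
                lab: (tuple(se[0]), tuple(se[1])) for lab, se in e["endpoints"].items()
            },
            trim={lab: tuple(v) for lab, v in e.get("trim", {}).items()},
            head_length_um=e.get("head_length_um"),
            stage=e.get("stage", ""),
        )
        for e in entries
    ]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run over simulated cohorts."""

    outdir: str = "fasciq_out"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "trace", "quantify", "classify", "stats", "report")
    trace_mode: str = "ground_truth"  # or "image": render stacks and run the tracer
    n_bins: int = 100
    iterations: int = 500
    z_threshold: float = 3.5
    run_length: int = 10
    reference_cohort: str | None = None
    cohorts: tuple[dict, ...] = (
        {"label": "wildtype", "n_animals": 6, "order_model": "switch", "switch_bin": 40},
    )

    def __post_init__(self) -> None:
        if self.trace_mode not in ("ground_truth", "image"):
            raise ValueError(f"unknown trace_mode {self.trace_mode!r}")
        known = {"simulate", "trace", "quantify", "classify", "stats", "report"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "cohorts" in data:
        data["cohorts"] = tuple(data["cohorts"])
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    return RunConfig(**data)
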