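"""End-to-end orchestration: simulate → trace → quantify → classify → stats → report.

All randomness flows from the config seed through per-cohort, per-animal
child streams, so the same config and seed reproduce byte-identical outputs.
Any stage failure aborts with the stage name and the animal involved.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io as fio
from .fasciculation import classify_defasciculation, exclude_defasciculated, reference_stats
from .geometry import bin_profile, centroid_line, crop_to_common_extent, cross_sections
from .order_stats import (
    compare_populations,
    detect_switch_point,
    majority_profile,
    tabulate_population,
)
from .report import save_population_plot, save_rank_bars, save_summary_plot, save_width_plot
from .synthetic import BundleSpec, generate_bundle_traces, generate_population, render_stack
from .tracing import brightest_path

__all__ = ["run_pipeline"]

_SPEC_KEYS = {f for f in BundleSpec.__dataclass_fields__} - {"seed", "n_bins"}


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _stage(name: str, animal: str = ""):
    """Context manager that prefixes failures with stage and animal."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                where = f"stage '{name}'" + (f", animal '{animal}'" if animal else "")
                raise RuntimeError(f"{where} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: fio.RunConfig) -> dict:
    """Run the requested stages over simulated cohorts; return the summary.

    The summary (also written as ``summary.json`` when the report stage is
    requested) holds per-cohort animal counts, excluded animals, per-bin
    permutation ranks and tiers versus a simulated random cohort (and versus
    the reference cohort for the others), and switch points.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    order = ("simulate", "trace", "quantify", "classify", "stats", "report")
    last = max(order.index(s) for s in stages)

    master = np.random.SeedSequence(config.seed)
    cohort_streams = master.spawn(len(config.cohorts) + 1)
    stats_stream = cohort_streams[-1]

    summary: dict = {
        "schema_version": 1,
        "seed": config.seed,
        "parameters": {
            "n_bins": config.n_bins,
            "iterations": config.iterations,
            "z_threshold": config.z_threshold,
            "run_length": config.run_length,
            "trace_mode": config.trace_mode,
        },
        "cohorts": {},
    }

    cohort_profiles: dict[str, list] = {}
    cohort_truths: dict[str, list] = {}
    for ci, cohort in enumerate(config.cohorts):
        label = cohort["label"]
        n_animals = int(cohort["n_animals"])
        per_animal = cohort.get("animals", [{}] * n_animals)
        if len(per_animal) != n_animals:
            raise ValueError(
                f"cohort '{label}': 'animals' must list {n_animals} override dicts"
            )
        animal_streams = cohort_streams[ci].spawn(n_animals)
        profiles, truths = [], []
        for ai in range(n_animals):
            animal_id = f"{label}_{ai + 1:02d}"
            overrides = {
                k: v
                for k, v in {**cohort, **per_animal[ai]}.items()
                if k in _SPEC_KEYS
            }
            if "defasc_segments" in overrides:
                overrides["defasc_segments"] = tuple(
                    tuple(seg) for seg in overrides["defasc_segments"]
                )
            with _stage("simulate", animal_id):
                spec = BundleSpec(
                    n_bins=config.n_bins, seed=_child_seed(animal_streams[ai]), **overrides
                )
                truth = generate_bundle_traces(spec)
                adir = outdir / label / animal_id
                if "simulate" in stages:
                    fio.write_ground_truth(truth, adir / "ground_truth.json")

            with _stage("trace", animal_id):
                if config.trace_mode == "image":
                    channel_stacks = render_stack(truth, spec)
                    spacing = np.asarray(spec.voxel_spacing_um)
                    traced = []
                    for stack in channel_stacks:
                        if "simulate" in stages:
                            fio.write_stack(stack, adir / f"{stack.channel_label}.tif")
                        gt = truth.trace(stack.channel_label)
                        start = np.round(gt.points[0] / spacing).astype(int)
                        end = np.round(gt.points[-1] / spacing).astype(int)
                        traced.append(brightest_path(stack, start, end))
                else:
                    traced = list(truth.traces)
                if "trace" in stages:
                    for tr in traced:
                        fio.write_trace_csv(tr, adir / f"trace_{tr.label}.csv")

            with _stage("quantify", animal_id):
                cropped = crop_to_common_extent(*traced)
                sections = cross_sections(*cropped, centroid_line(*cropped))
                if "quantify" in stages:
                    fio.write_distance_csv(sections, adir / "distances.csv")
                profiles.append(
                    bin_profile(
                        sections, n_bins=config.n_bins, animal_id=animal_id, stage=label
                    )
                )
            truths.append(truth)
        cohort_profiles[label] = profiles
        cohort_truths[label] = truths
        summary["cohorts"][label] = {"n_animals": n_animals}

    if last < 3:  # classify and beyond not requested
        return summary

    ref_label = config.reference_cohort or config.cohorts[0]["label"]
    with _stage("classify"):
        ref = reference_stats(cohort_profiles[ref_label], stage=ref_label)
        retained_by_cohort, excluded_by_cohort = {}, {}
        for label, profiles in cohort_profiles.items():
            results = [
                classify_defasciculation(
                    p, ref, z_threshold=config.z_threshold, run_length=config.run_length
                )
                for p in profiles
            ]
            retained, excluded = exclude_defasciculated(profiles, results)
            retained_by_cohort[label] = retained
            excluded_by_cohort[label] = excluded
            summary["cohorts"][label]["excluded"] = sorted(p.animal_id for p in excluded)

    if last < 4:
        return summary

    with _stage("stats"):
        stat_children = stats_stream.spawn(len(config.cohorts))
        populations = {}
        for label in cohort_profiles:
            retained = retained_by_cohort[label]
            if not retained:
                raise ValueError(
                    f"cohort '{label}': every bundle was classified defasciculated; "
                    "no animals remain for order statistics"
                )
            populations[label] = tabulate_population(retained, cohort=label)

        rank_results = {}
        for k, label in enumerate(cohort_profiles):
            pop = populations[label]
            sub = stat_children[k].spawn(3)
            random_pop = generate_population(
                "random", pop.n_animals, n_bins=pop.n_bins, seed=_child_seed(sub[0]),
                cohort="random",
            )
            vs_random = compare_populations(
                pop, random_pop, iterations=config.iterations, seed=_child_seed(sub[1])
            )
            vs_ref = None
            if label != ref_label:
                vs_ref = compare_populations(
                    pop, populations[ref_label], iterations=config.iterations,
                    seed=_child_seed(sub[2]),
                )
            rank_results[label] = (vs_random, vs_ref)

            majority = majority_profile(pop)
            sp = detect_switch_point(majority)
            per_animal = []
            for row in pop.animal_labels:
                asp = detect_switch_point(list(row))
                per_animal.append(asp.bin_index if asp else None)
            summary["cohorts"][label].update(
                {
                    "switch_point": (
                        {"bin": sp.bin_index, "from": sp.from_label, "to": sp.to_label}
                        if sp
                        else None
                    ),
                    "per_animal_switch_bins": per_animal,
                    "vs_random": {
                        "ranks": [r.rank for r in vs_random],
                        "tiers": [r.tier for r in vs_random],
                    },
                    "vs_reference": (
                        {
                            "ranks": [r.rank for r in vs_ref],
                            "tiers": [r.tier for r in vs_ref],
                        }
                        if vs_ref
                        else None
                    ),
                }
            )

    if last < 5 or "report" not in stages:
        return summary

    with _stage("report"):
        for label in cohort_profiles:
            cdir = outdir / label
            save_width_plot(
                retained_by_cohort[label], excluded_by_cohort[label],
                cdir / "width.png", ref=ref,
            )
            save_population_plot(populations[label], cdir / "population.png")
            save_summary_plot(populations[label], cdir / "summary.png")
            vs_random, vs_ref = rank_results[label]
            save_rank_bars(vs_random, cdir / "rank_vs_random.png", color="blue")
            if vs_ref is not None:
                save_rank_bars(vs_ref, cdir / "rank_vs_reference.png", color="red")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        (outdir / "run_log.json").write_text(
            json.dumps({"seed": config.seed, "config": asdict(config)},
                       indent=2, sort_keys=True, default=list)
        )

    return summary
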