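# fasciq

Quantification of dendrite **order** and **fasciculation** in a three-neuron
nerve bundle from multi-channel 3D fluorescence stacks.

In the *C. elegans* amphid, sensory dendrites run to the nose tip as a single
tightly fasciculated bundle roughly 1 µm wide. When three of those dendrites
(AWA, AFD, ASE) carry different fluorophores, each cross-section of the
bundle is a triangle whose vertices are the three dendrites. `fasciq`
implements a semi-automated pipeline that turns image stacks of such bundles
into population-level statistics of how the dendrites are arranged:

1. **Tracing** — each dendrite is extracted from its channel as the
   *brightest path* between user-chosen endpoints: Dijkstra's shortest path
   on the 26-connected voxel graph with edge cost
   ½·(1/(I(u)+ε) + 1/(I(v)+ε))·‖p(u) − p(v)‖, i.e. inverse intensity weighted
   by physical step length.
2. **Bundle geometry** — the three traces are cropped to a common extent,
   averaged into a centroid line, and sliced into cross-sections. Each
   section gives the three pairwise distances (d₁, d₂, d₃); the longest is
   the **bundle width** proxy, and the dendrite opposite the longest side is
   the dendrite **"in the middle"**. Distances are averaged into 100 bins of
   normalized bundle length so positions compare across animals.
3. **Defasciculation screen** — a bundle whose width exceeds the age-matched
   reference mean by > 3.5 SD for ≥ 10 consecutive bins is classified
   defasciculated and excluded from order statistics.
4. **Order statistics** — per bin, cohorts are summarized as counts
   (c_AWA, c_AFD, c_ASE) of animals with each dendrite in the middle.
   Comparisons use a chi-squared test against uniform n/3 (when n/3 ≥ 5) and,
   generally, a permutation test with Fisher's 3×2 exact test as the
   statistic: the two cohorts are merged and randomly re-split 500 times, and
   the nominal p is ranked among the 501 resulting p-values. Ranks below
   25/501 and 5/501 correspond to p < 0.05 and p < 0.01. Switch points
   (where the predominant middle identity durably changes) are compared with
   a two-sample Kolmogorov–Smirnov test.

No public microscopy accompanies the method, so the package ships a
**synthetic phantom generator**: three ~0.5 µm tubes on a slowly twisting
triangular frame around a curving centerline, with a configurable middle
order (fixed / switch / random), label noise, planted defasciculation
segments, Gaussian PSF blur and Poisson + read noise. Every phantom carries
its ground truth, which is what the test suite validates against.

## Worked example

Six simulated wild-type-like animals with a planted AFD→ASE switch at bin 40,
run through the full geometry pipeline:

```python
from fasciq import (BundleSpec, generate_bundle_traces, crop_to_common_extent,
                    centroid_line, cross_sections, bin_profile,
                    tabulate_population, detect_switch_point, majority_profile)

profiles = []
for seed in range(6):
    spec = BundleSpec(order_model="switch", switch_bin=40, seed=seed)
    truth = generate_bundle_traces(spec)
    cropped = crop_to_common_extent(*truth.traces)
    sections = cross_sections(*cropped, centroid_line(*cropped))
    profiles.append(bin_profile(sections, animal_id=f"wt_{seed}"))

pop = tabulate_population(profiles, cohort="wildtype")
print("counts at bin 20 (AWA, AFD, ASE):", pop.counts[19])
print("counts at bin 80 (AWA, AFD, ASE):", pop.counts[79])
sp = detect_switch_point(majority_profile(pop))
print(f"switch point: bin {sp.bin_index} ({sp.from_label} -> {sp.to_label})")
```

prints

```
counts at bin 20 (AWA, AFD, ASE): [0 6 0]
counts at bin 80 (AWA, AFD, ASE): [0 0 6]
switch point: bin 40 (AFD -> ASE)
```

— every animal has AFD in the middle before the switch and ASE after it, and
the majority profile recovers the planted switch bin exactly. Comparing an
18-animal switch cohort against a same-size random cohort:

```python
from fasciq import generate_population, compare_populations

wt = generate_population("switch", 18, switch_bin=40, noise_rate=0.05, seed=7)
rand = generate_population("random", 18, seed=99)
ranks = compare_populations(wt, rand, iterations=500, seed=0)
r = ranks[19]
print(f"bin 20 vs random: Fisher p = {r.nominal_p:.2e}, rank {r.rank}/501 -> {r.tier}")
```

prints

```
bin 20 vs random: Fisher p = 7.42e-06, rank 1/501 -> p<0.01
```

— at a typical cohort size (n = 18) the ordered arrangement is sharply
distinguishable from random: the nominal Fisher p ranks first among the 501
permutation p-values, i.e. beyond the p < 0.01 tier.

A full config-driven run (simulate → trace → quantify → classify → stats →
report, with figures and a machine-readable summary) is available from the
shell:

```sh
fasciq run config.yaml --seed 1
```

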