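# Methods

## The measurement model

The object of study is a bundle of three labeled dendrites imaged in three
channels of one 3D stack. The pipeline's categorical readout at each position
along the bundle is *which dendrite lies in the middle of the other two*,
defined purely from the cross-section triangle: the vertex opposite the
longest side. This definition is invariant under rigid motion and under
twisting of the bundle (asserted in the tests to 1e-9 µm), which matters
because the triangular frame genuinely rotates along the bundle. The longest
pairwise distance doubles as the bundle-width proxy used for fasciculation
screening.

Assumptions the pipeline inherits from this design:

- exactly three dendrites, one per channel, each traceable as a single bright
  ridge between two user-supplied endpoints;
- the three traces overlap over a common extent after cropping;
- cross-sections are meaningful, i.e. each trace is intersected once per
  centroid sample (guaranteed by taking the Euclidean-nearest trace point to
  each centroid sample).

## Tracing

Dijkstra's algorithm runs on the 26-connected voxel graph. An edge between
voxels u, v costs `((1/(I(u)+ε) + 1/(I(v)+ε))/2) · ‖p(u) − p(v)‖` with
ε = 1 intensity unit; the physical step length makes anisotropic z-spacing
behave correctly. Intensities are first rescaled so the stack maximum is 255,
which makes the result exactly invariant to multiplying all intensities by a
positive constant (the rescaling also fixes the meaning of ε across input bit
depths). Zero-intensity voxels are merely expensive, never infinite. 26- vs
6-connectivity is a genuine choice: diagonal moves avoid staircase artifacts
on oblique tubes. The search itself is `scipy.sparse.csgraph.dijkstra` on a
vectorized graph; its scan order is fixed, so traces are reproducible
run-to-run. Endpoints come from a manifest (or the phantom ground truth), not
interactive clicking; mistraced trace ends are corrected by deleting rows
(`trim_trace`), mirroring a spreadsheet-editing workflow.

## Cropping, centroid, cross-sections, binning

Cropping to a common extent follows the shortest-dendrite rule: for each end
in turn, average the three tips at the *opposite* end, pick the dendrite
whose tip at this end lies nearest that average (the dendrite reaching least
far), and re-anchor the other two traces at their points nearest the chosen
tip. The centroid line is the per-arc-position mean of the three traces after
resampling each to a common number of equal-arc-length samples (the finest of
the three native resolutions). Cross-sections take, for every centroid
sample, the Euclidean-nearest point on each trace; a KD-tree computes what an
exhaustive per-vertex search would (the tests check this equivalence). An
alternative correspondence — re-running a shortest-path search from the
centroid to each trace — was considered and rejected in favor of plain
nearest points, which is simpler and rotation-safe.

Binning: positions are divided into `n_bins = 100` contiguous bins with
boundaries at `round(k·N/100)`; each pairwise-distance series and the width
series are averaged within bins, and the bin's middle label is derived from
the *binned mean distances* (not a vote over per-section calls), because all
downstream analysis operates on the binned distance spreadsheet. Uneven
division conserves the global mean when bins are weighted by size (tested).
Bin 1 is the distal (nose-tip) end. Binning itself is the length
normalization: bin 50 is the same *relative* anatomical position in every
animal; the measured head length is carried as metadata only.

Ties: when the two longest sides agree within 1e-9 µm (including the fully
degenerate zero-distance section) the middle call is flagged ambiguous and
resolved by fixed alphabetical priority (AFD < ASE < AWA), so counts always
sum to the cohort size.

## Defasciculation rule

Per bin, z = (width − reference mean)/reference SD, with the reference built
from ≥ 2 age-matched animals (sample SD, ddof = 1). A bundle is
defasciculated iff z > 3.5 on ≥ 10 consecutive bins, one-sided — only
excursions *above* the mean count. Under a normal model a two-sided 3.5-SD
exceedance is ≈ 1 in 2000 data points, so a sustained 10-bin run is far
outside chance. Zero-SD bins (degenerate synthetic references) define z = 0
at or below the mean and +∞ above it, so classification is monotone in width
and never divides by zero. "Positions" in the run rule are the 100 normalized
bins. The original workflow's parallel manual visual classification is out of
scope; only the automated rule is implemented.

## Order statistics

Counts per bin are (c_AWA, c_AFD, c_ASE) over retained (fasciculated)
animals. Against an idealized uniform arrangement, the chi-squared statistic
Σ(o − n/3)²/(n/3) with 2 df applies when n/3 ≥ 5; below that the function
refuses and points to the permutation test.

Fisher's 3×2 exact test is computed by full enumeration of margin-consistent
tables (p = total probability of tables no more probable than the observed
one under the multivariate hypergeometric null, with a 1e-7 relative guard on
the probability comparison, as in standard exact-test implementations).
Enumeration is exact and fast for cohort sizes up to several dozen animals;
there is deliberately no asymptotic fallback. Results are cached per table,
which is what keeps 501 × 100-bin permutation runs cheap.

The permutation test merges the two cohorts and re-splits them uniformly at
random into ⌈N/2⌉ / ⌊N/2⌋ groups 500 times. Re-splitting is drawn directly
from the multivariate hypergeometric distribution, which is exactly the
distribution of counts obtained by shuffling individual animal labels —
equivalent and much faster. The simulated "random" comparison cohort is an
explicit same-size multinomial draw (not the expected-count vector), because
the permutation machinery needs individual animals to shuffle. One master
seed spawns independent child streams per bin, so bins are independent and
each is reproducible in isolation. Per-bin results are not
multiplicity-corrected across bins; ranks are reported per position.

**Rank and ties.** The rank of the nominal p among the 501 values is the
reported statistic; rank ≤ 25 (of 501) corresponds to p < 0.05 and rank ≤ 5
to p < 0.01 (thresholds are the largest r with r/total < α). Fisher p-values
are discrete, so resampled values tie with the nominal one, and the tie
policy matters:

- `ties="conservative"` (default, used for all reporting): tied values count
  below the nominal, so identical cohorts rank maximally (501) and the rank
  never overstates significance. Measured null flagging at the p < 0.05 tier
  is ≈ 4% (counting ties above the nominal instead would give ≈ 5.3%,
  overstating significance).
- `ties="randomized"`: the nominal value's position within its tie block is
  drawn uniformly, the standard device that makes null ranks *exactly*
  uniform on {1..501}. No deterministic rule achieves this — conservative,
  anti-conservative and mid-rank placements all show strong
  goodness-of-fit departures from uniformity under the null — so the
  calibration suite uses this mode, while reported ranks stay conservative.

Switch points: the first bin whose majority middle label differs from bin 1's
label and persists for ≥ 2 consecutive bins (single-bin blips are ignored).
Cohorts of per-animal switch positions are compared with the two-sample
Kolmogorov–Smirnov test (asymptotic p), chosen because switch positions are
not normally distributed.

## The phantom generator

`BundleSpec` defaults describe a late-larval bundle: tube radius 0.25 µm
(0.5 µm-diameter dendrites), nominal center spacing 1.1 µm, bundle length
60 µm sampled at 200 positions (two per bin). The three tubes ride a
triangular frame in the normal plane of a low-frequency 3D centerline; the
frame makes 1.5 full turns along the bundle so middle calls are exercised
under twisting. The planned middle dendrite sits at the apex of a flattened
isoceles triangle (apex height 0.35 × the base), so the base is strictly the
longest side and the planned label is realized geometrically at every
position. Width variability is split into a bounded along-bundle wobble
(±22%, 1.5–3.5 cycles) plus a smaller animal-to-animal scale factor
(CV 8%) and sub-voxel point jitter (0.02 µm); together these give per-bin
width SD ≈ 0.19 µm around a 1.1 µm mean, matching the reported
late-larval spread, while keeping tails light enough that clean phantoms are
never flagged by the 3.5-SD rule. Defasciculation segments displace one outer
dendrite outward by `extra_width_um` over a 1-based inclusive bin range.

Rendering draws tubes via an exact Euclidean distance transform at the
anisotropic voxel spacing (default 0.15 × 0.15 × 0.3 µm), blurs with an
isotropic Gaussian PSF (σ = 0.15 µm) and adds Poisson signal noise plus
Gaussian read noise at the requested signal-to-background ratio
(background 10 photons, foreground snr × 10). `snr = inf` renders a
noiseless binary stack. The same spec seed always reproduces bit-identical
traces and stacks.

What the phantoms do **not** emulate: realistic PSF anisotropy or
camera-specific noise, autofluorescent background structure, channel
crosstalk, more than three dendrites, and gradual (rather than stepwise)
changes of middle identity. Passing tests therefore demonstrate correctness
of the measurement and statistics on geometry the model assumes, not
robustness to every artifact of real microscopy.

## Numerical notes and known limitations

- **Edge smearing of width excursions.** A displaced (defasciculated) trace
  is genuinely longer, which warps the equal-arc-length correspondence used
  by the centroid line; the measured excursion loses roughly two bins at each
  edge per µm of displacement. A planted 12-bin excursion can therefore
  measure as ~9 elevated bins and escape the 10-run rule. The validation
  suite plants 20-bin, 2 µm excursions (comfortably within what mutant
  defasciculation looks like) and observes 100% sensitivity with zero false
  positives; users screening for excursions near the 10-bin limit should
  expect reduced sensitivity at the edges.
- **Discrete p-values.** Exact-test p-values take few distinct values at
  small n; see the tie policy above. Ranks, not raw p-values, are the
  intended readout.
- **Degenerate inputs.** Zero-intensity voxels, zero-SD reference bins,
  zero-distance sections, empty cohorts and over-trimming all fail loudly or
  follow the documented conventions rather than producing NaNs.
- **Problem sizes.** The shipped tests and the acceptance script run phantoms
  at 100–200 positions, 50–100 bins, cohorts of 6–20, and stacks of a few
  hundred × tens of voxels — the scale at which every property is already
  decisively measurable; all generators accept larger sizes.
- The tracer's optimality is verified against an independent Dijkstra
  implementation on random stacks, and its accuracy on rendered phantoms
  (≤ 1 voxel deviation at snr ≥ 10) against ground truth; both bounds are
  empirical, not worst-case guarantees.
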