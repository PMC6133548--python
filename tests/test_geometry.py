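"""Cross-section geometry: cropping, centroid, triangles, middle calls, binning."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fasciq.geometry import (
    LABELS,
    PAIRS,
    bin_boundaries,
    bin_profile,
    centroid_line,
    crop_to_common_extent,
    cross_sections,
    middle_dendrite,
    resample_polyline,
)
from fasciq.tracing import DendriteTrace

from _oracles import brute_middle, brute_nearest_points
from conftest import random_smooth_triplet


def _line(x0, y0, length, n, label):
    """Straight trace along z starting at (x0, y0, 0)."""
    z = np.linspace(0.0, length, n)
    pts = np.column_stack([np.full(n, x0, float), np.full(n, y0, float), z])
    return DendriteTrace(points=pts, label=label)


class TestCrop:
    def test_identical_traces_unchanged(self):
        traces = [_line(0, 0, 50, 51, lab) for lab in LABELS]
        out = crop_to_common_extent(*traces)
        for o, t in zip(out, traces):
            np.testing.assert_array_equal(o.points, t.points)

    def test_shared_end_lines_crop_to_shortest(self):
        """Lines of length 100/90/80 sharing one end all crop to the 80 µm extent."""
        t1 = _line(0.0, 0.0, 100, 101, "AWA")
        t2 = _line(0.3, 0.0, 90, 91, "AFD")
        t3 = _line(0.0, 0.3, 80, 81, "ASE")
        out = crop_to_common_extent(t1, t2, t3)
        for o in out:
            assert o.points[0, 2] == pytest.approx(0.0)
            assert o.points[-1, 2] == pytest.approx(80.0)

    def test_axially_offset_lines_keep_overlap(self):
        """Traces shifted 5 µm along the bundle retain the common region."""
        n = 101
        z1 = np.linspace(0, 100, n)
        z2 = np.linspace(5, 105, n)
        z3 = np.linspace(2, 102, n)
        mk = lambda z, x, lab: DendriteTrace(
            np.column_stack([np.full(n, x), np.zeros(n), z]), label=lab)
        out = crop_to_common_extent(mk(z1, 0.0, "AWA"), mk(z2, 0.3, "AFD"),
                                    mk(z3, 0.6, "ASE"))
        for o in out:
            assert o.points[0, 2] == pytest.approx(5.0, abs=1.0)
            assert o.points[-1, 2] == pytest.approx(100.0, abs=1.0)

    def test_disjoint_traces_error(self):
        t1 = _line(0, 0, 10, 11, "AWA")
        t2 = _line(0.1, 0, 10, 11, "AFD")
        t3 = DendriteTrace(
            np.column_stack([np.zeros(11), np.zeros(11), np.linspace(50, 60, 11)]),
            label="ASE",
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            crop_to_common_extent(t1, t2, t3)


class TestCentroid:
    def test_mean_of_parallel_lines(self):
        t1 = _line(0, 0, 20, 21, "AWA")
        t2 = _line(1, 0, 20, 21, "AFD")
        t3 = _line(0, 1, 20, 21, "ASE")
        c = centroid_line(t1, t2, t3)
        np.testing.assert_allclose(c[:, 0], 1 / 3)
        np.testing.assert_allclose(c[:, 1], 1 / 3)

    def test_identical_traces_give_the_trace(self):
        t = _line(2, 3, 20, 21, "AWA")
        c = centroid_line(t, DendriteTrace(t.points, label="AFD"),
                          DendriteTrace(t.points, label="ASE"))
        np.testing.assert_allclose(c, t.points, atol=1e-12)

    def test_centroid_inside_triplet_hull(self):
        """For a winding triplet every centroid sample stays within the
        per-sample convex hull (here: coordinate-wise envelope) of the traces."""
        traces = random_smooth_triplet(5)
        n = max(len(t) for t in traces)
        rs = np.stack([resample_polyline(t.points, n) for t in traces])
        c = centroid_line(*traces)
        assert np.all(c >= rs.min(axis=0) - 1e-9)
        assert np.all(c <= rs.max(axis=0) + 1e-9)


class TestCrossSections:
    def _parallel_sections(self):
        t1 = _line(0, 0, 20, 21, "AWA")
        t2 = _line(1, 0, 20, 21, "AFD")
        t3 = _line(0, 1, 20, 21, "ASE")
        return cross_sections(t1, t2, t3)

    def test_parallel_lines_plane_geometry(self):
        for s in self._parallel_sections():
            assert s.d_pairs[("AWA", "AFD")] == pytest.approx(1.0)
            assert s.d_pairs[("AWA", "ASE")] == pytest.approx(1.0)
            assert s.d_pairs[("AFD", "ASE")] == pytest.approx(np.sqrt(2))
            assert s.width == pytest.approx(np.sqrt(2))
            assert s.middle == "AWA"  # opposite the AFD–ASE diagonal

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        """Rotating and translating the whole bundle changes no distances or
        middle calls — twisting cannot corrupt the order readout."""
        traces = random_smooth_triplet(seed)
        base = cross_sections(*traces)
        rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        shift = np.random.default_rng(seed + 1).uniform(-40, 40, 3)
        moved = tuple(
            DendriteTrace(t.points @ rot.T + shift, label=t.label) for t in traces
        )
        transformed = cross_sections(*moved)
        assert len(base) == len(transformed)
        for a, b in zip(base, transformed):
            for pair in a.d_pairs:
                assert b.d_pairs[pair] == pytest.approx(a.d_pairs[pair], abs=1e-9)
            assert b.middle == a.middle

    def test_nearest_points_match_bruteforce(self):
        traces = random_smooth_triplet(9)
        centroid = centroid_line(*traces)
        sections = cross_sections(*traces, centroid)
        for t in traces:
            expected = brute_nearest_points(centroid, t.points)
            got = np.array([s.points[t.label] for s in sections])
            np.testing.assert_allclose(got, expected)

    def test_reversing_all_traces_reverses_sections_only(self):
        traces = random_smooth_triplet(3)
        fwd = cross_sections(*traces)
        rev = cross_sections(
            *(DendriteTrace(t.points[::-1].copy(), label=t.label) for t in traces)
        )
        widths_f = [s.width for s in fwd]
        widths_r = [s.width for s in rev]
        np.testing.assert_allclose(widths_r, widths_f[::-1], atol=1e-8)
        assert [s.middle for s in rev] == [s.middle for s in fwd][::-1]

    def test_degenerate_section_is_tie_flagged(self):
        d = {("AWA", "ASE"): 0.0, ("AWA", "AFD"): 0.0, ("AFD", "ASE"): 0.0}
        label, ambiguous = middle_dendrite(d)
        assert ambiguous and label == "AFD"  # alphabetical priority


class TestMiddleDendrite:
    def test_longest_awa_ase_side_puts_afd_in_middle(self):
        d = {("AWA", "ASE"): 1.5, ("AWA", "AFD"): 0.9, ("AFD", "ASE"): 0.8}
        label, ambiguous = middle_dendrite(d)
        assert label == "AFD" and not ambiguous

    def test_equilateral_triangle_resolved_by_priority(self):
        d = {p: 1.0 for p in (("AWA", "ASE"), ("AWA", "AFD"), ("AFD", "ASE"))}
        label, ambiguous = middle_dendrite(d)
        assert ambiguous and label == "AFD"

    def test_thousand_random_triangles_match_enumeration_oracle(self, rng):
        for _ in range(1000):
            pts = rng.uniform(0, 5, size=(3, 2))
            d = {
                ("AWA", "ASE"): float(np.linalg.norm(pts[0] - pts[2])),
                ("AWA", "AFD"): float(np.linalg.norm(pts[0] - pts[1])),
                ("AFD", "ASE"): float(np.linalg.norm(pts[1] - pts[2])),
            }
            label, _ = middle_dendrite(d)
            assert label == brute_middle(d)


class TestBinProfile:
    def _sections_from_series(self, series):
        from fasciq.geometry import CrossSection

        out = []
        for i, (a, b, c) in enumerate(series):
            out.append(
                CrossSection(
                    position_index=i,
                    d_pairs={("AWA", "ASE"): a, ("AWA", "AFD"): b, ("AFD", "ASE"): c},
                )
            )
        return out

    def test_200_sections_pair_adjacent_positions(self):
        vals = np.arange(200, dtype=float)
        secs = self._sections_from_series(np.column_stack([vals, vals + 0.1, vals + 0.2]))
        prof = bin_profile(secs, n_bins=100)
        # bin k holds positions 2k-1 and 2k (1-based): mean of consecutive pairs
        expected = vals.reshape(100, 2).mean(axis=1)
        np.testing.assert_allclose(prof.bin_d_pairs[("AWA", "ASE")], expected)

    def test_constant_distances_give_constant_bins(self):
        secs = self._sections_from_series([(1.0, 2.0, 2.5)] * 137)
        prof = bin_profile(secs, n_bins=100)
        np.testing.assert_allclose(prof.bin_d_pairs[("AFD", "ASE")], 2.5)
        np.testing.assert_allclose(prof.bin_width, 2.5)

    def test_uneven_bins_conserve_the_global_mean(self, rng):
        vals = rng.uniform(0.5, 3.0, size=(250, 3))
        secs = self._sections_from_series(vals)
        prof = bin_profile(secs, n_bins=100)
        edges = bin_boundaries(250, 100)
        sizes = np.diff(edges)
        for col, pair in enumerate(PAIRS):
            weighted = np.sum(prof.bin_d_pairs[tuple(pair)] * sizes) / 250
            assert weighted == pytest.approx(vals[:, col].mean())

    def test_fewer_sections_than_bins_is_an_error(self):
        secs = self._sections_from_series([(1, 1, 1)] * 50)
        with pytest.raises(ValueError, match="at least"):
            bin_profile(secs, n_bins=100)
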