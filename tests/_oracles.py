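"""Independent reference computations used only by the tests.

Each oracle re-derives a quantity by a route disjoint from the library code:
networkx Dijkstra on an explicitly built voxel graph, exact rational
enumeration of Fisher tables, and brute-force geometric searches.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, sqrt

import networkx as nx
import numpy as np


def nx_brightest_cost(intensities_zyx: np.ndarray, spacing_xyz, start_xyz, end_xyz) -> float:
    """Minimum brightest-path cost via networkx Dijkstra.

    Edge weights are rebuilt from scratch: mean inverse of max-normalized
    intensity (+1 offset) times the physical step length, 26-connectivity.
    """
    inten = np.asarray(intensities_zyx, dtype=float)
    peak = inten.max()
    if peak > 0:
        inten = inten * (255.0 / peak)
    inv = 1.0 / (inten + 1.0)
    nz, ny, nx_ = inten.shape
    sx, sy, sz = spacing_xyz
    g = nx.Graph()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx_):
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            z2, y2, x2 = z + dz, y + dy, x + dx
                            if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx_):
                                continue
                            w = 0.5 * (inv[z, y, x] + inv[z2, y2, x2]) * sqrt(
                                (dx * sx) ** 2 + (dy * sy) ** 2 + (dz * sz) ** 2
                            )
                            g.add_edge((x, y, z), (x2, y2, z2), weight=w)
    return nx.dijkstra_path_length(g, tuple(start_xyz), tuple(end_xyz), weight="weight")


def fisher_3x2_exact_fraction(table) -> Fraction:
    """Fisher 3×2 p-value by exact rational enumeration (no floats).

    Sums the multivariate hypergeometric probabilities of every table with
    the observed margins whose probability is ≤ the observed table's, with
    both sides held as exact Fractions.
    """
    t = np.asarray(table, dtype=int)
    r1 = int(t[0].sum())
    c = [int(v) for v in t.sum(axis=0)]
    n = sum(c)
    denom = comb(n, r1)

    def prob(a: int, b: int) -> Fraction:
        cc = r1 - a - b
        return Fraction(comb(c[0], a) * comb(c[1], b) * comb(c[2], cc), denom)

    p_obs = prob(int(t[0, 0]), int(t[0, 1]))
    total = Fraction(0)
    for a in range(min(c[0], r1) + 1):
        for b in range(max(0, r1 - a - c[2]), min(c[1], r1 - a) + 1):
            pr = prob(a, b)
            if pr <= p_obs:
                total += pr
    return total


def brute_middle(d_pairs: dict) -> str:
    """Middle call by an independent rule: the vertex with the smallest sum
    of incident side lengths is opposite the strictly longest side."""
    labels = {"AWA", "AFD", "ASE"}
    incident = {
        lab: sum(d for pair, d in d_pairs.items() if lab in pair) for lab in labels
    }
    return min(incident, key=lambda lab: (incident[lab], lab))


def brute_nearest_points(centroid: np.ndarray, trace_points: np.ndarray) -> np.ndarray:
    """Exhaustive per-vertex nearest trace point for every centroid sample."""
    out = np.empty((len(centroid), 3))
    for i, c in enumerate(centroid):
        d = np.linalg.norm(trace_points - c, axis=1)
        out[i] = trace_points[int(np.argmin(d))]
    return out
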