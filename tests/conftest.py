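"""Shared fixtures and independent oracles.

The tessellation oracle is deliberately a different code path from the
package: a Delaunay triangulation (not a Voronoi diagram) of the 3x3
periodic tiling, whose adjacency equals Voronoi adjacency for points in
general position.
"""
from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import Delaunay

from xylembubbles import MonolayerFrame, SyntheticMonolayerSpec, gen_hexagonal_patch
from xylembubbles.phases import GAS, LC, LE


def tile_3x3(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Independent 3x3 tiling (primary copy first, blocks of n)."""
    offsets = [
        (ix, iy) for ix in (-1, 0, 1) for iy in (-1, 0, 1) if not (ix == 0 and iy == 0)
    ]
    return np.concatenate([coords] + [coords + np.array(o) * box for o in offsets], axis=0)


def oracle_neighbors(frame: MonolayerFrame) -> list[set[int]]:
    """Brute-force periodic Voronoi adjacency via Delaunay on the full tiling."""
    n = frame.n_atoms
    box = np.array(frame.box_lengths)
    tiled = tile_3x3(frame.coords, box)
    tri = Delaunay(tiled)
    indptr, indices = tri.vertex_neighbor_vertices
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for a in range(len(tiled)):
        oa = a % n
        for b in indices[indptr[a] : indptr[a + 1]]:
            b = int(b)
            if a < n:
                nbrs[oa].add(b % n)
            elif b < n:
                nbrs[b].add(oa)
    return nbrs


def min_image_distance(frame: MonolayerFrame, a: int, b: int) -> float:
    box = np.array(frame.box_lengths)
    if a == b:
        # shortest nonzero self-image translation
        return float(min(box))
    d = frame.coords[a] - frame.coords[b]
    d -= box * np.round(d / box)
    return float(np.linalg.norm(d))


def oracle_labels(frame: MonolayerFrame, lc_cutoff=0.8, gas_cutoff=1.5) -> np.ndarray:
    """Phase labels recomputed from the oracle adjacency and brute-force distances."""
    nbrs = oracle_neighbors(frame)
    labels = np.empty(frame.n_atoms, dtype=object)
    for i, nb in enumerate(nbrs):
        dists = [min_image_distance(frame, i, j) for j in nb]
        if sum(d <= lc_cutoff for d in dists) >= 6:
            labels[i] = LC
        elif not dists or max(dists) > gas_cutoff:
            labels[i] = GAS
        else:
            labels[i] = LE
    return labels


def random_frame(rng: np.random.Generator, n: int | None = None) -> MonolayerFrame:
    n = n if n is not None else int(rng.integers(20, 300))
    box = (float(rng.uniform(6.0, 14.0)), float(rng.uniform(6.0, 14.0)))
    coords = rng.uniform(0.0, 1.0, size=(n, 2)) * np.array(box)
    return MonolayerFrame(coords=coords, box_lengths=box)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240611)


@pytest.fixture
def dense_lattice() -> MonolayerFrame:
    """12x12 nm triangular lattice at 0.5 nm spacing (LC-like packing)."""
    return gen_hexagonal_patch(
        SyntheticMonolayerSpec(box_lengths=(12.0, 12.0), lattice_spacing=0.5)
    )
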