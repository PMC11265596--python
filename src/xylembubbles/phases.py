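"""2D phase classification, pore detection and pair correlations for lipid monolayers.

A monolayer frame is the set of xy positions of one tail-marker atom per
lipid chain in a periodic rectangular box.  Atoms are classified into the
two-dimensional phases of a Langmuir monolayer from a periodic Voronoi
tessellation:

* liquid condensed (LC): at least ``lc_min_neighbors`` Voronoi neighbours
  within ``lc_cutoff`` (default 6 within 0.8 nm);
* gas (pore edge): otherwise, if any Voronoi neighbour lies beyond
  ``gas_cutoff`` (default 1.5 nm);
* liquid expanded (LE): otherwise.

Rule precedence is LC, then GAS, then LE: an atom at a pore edge that still
has six close neighbours is condensed.  "Neighbour" always means a
Voronoi-adjacent atom, with the adjacency computed on a full 3x3 periodic
tiling of the box so that atoms at the box edge see their periodic images.

The largest-pore estimator follows the grid construction used for cavitation
analysis: the pore radius of a frame is the maximum over a regular grid of
cell centres of the distance to the nearest atom under the minimum-image
convention (default grid 40 x 40).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Voronoi, cKDTree

__all__ = [
    "MonolayerFrame",
    "PhaseAssignment",
    "PoreEstimate",
    "TrajectoryStats",
    "PbcTessellation",
    "LC",
    "LE",
    "GAS",
    "build_pbc_tessellation",
    "classify_phases",
    "largest_pore_radius",
    "trajectory_statistics",
    "rdf_2d",
]

LC = "LC"
LE = "LE"
GAS = "GAS"

#: Label precedence applied by :func:`classify_phases` (documented constant).
LABEL_PRECEDENCE = (LC, GAS, LE)

DEFAULT_LC_CUTOFF = 0.8  # nm
DEFAULT_GAS_CUTOFF = 1.5  # nm
DEFAULT_LC_MIN_NEIGHBORS = 6


@dataclass
class MonolayerFrame:
    """One time point of tail-marker xy coordinates in a periodic box.

    coords are wrapped into [0, Lx) x [0, Ly) on construction.
    ``metadata`` carries synthetic ground truth (planted pores/labels) when
    the frame came from a generator.
    """

    coords: np.ndarray  # (n, 2), nm
    box_lengths: Tuple[float, float]  # (Lx, Ly), nm
    time: float = 0.0  # ns
    species: Optional[np.ndarray] = None  # per-atom tag, e.g. "PE"/"DGDG"
    leaflet_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = np.empty((0, 2), dtype=float)
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        lx, ly = float(self.box_lengths[0]), float(self.box_lengths[1])
        if not (lx > 0 and ly > 0):
            raise ValueError("box lengths must be positive")
        self.box_lengths = (lx, ly)
        box = np.array(self.box_lengths)
        self.coords = np.mod(self.coords, box)
        # np.mod can return exactly L for tiny negative inputs; fold onto 0
        self.coords = np.where(self.coords >= box, self.coords - box, self.coords)
        if self.species is not None:
            self.species = np.asarray(self.species)
            if len(self.species) != len(self.coords):
                raise ValueError("species length must match coords")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def min_image_vectors(self, point: Sequence[float]) -> np.ndarray:
        """Minimum-image displacement vectors from ``point`` to every atom."""
        box = np.array(self.box_lengths)
        d = self.coords - np.asarray(point, dtype=float)
        return d - box * np.round(d / box)

    def min_image_distances(self, point: Sequence[float]) -> np.ndarray:
        return np.linalg.norm(self.min_image_vectors(point), axis=1)


@dataclass
class PhaseAssignment:
    """Per-atom LC/LE/GAS labels plus aggregate fractions for one frame."""

    labels: np.ndarray  # (n,) of {"LC", "LE", "GAS"}
    n_atoms: int
    fractions: Optional[Tuple[float, float, float]]  # (f_LC, f_LE, f_GAS); None if n == 0

    @property
    def defined(self) -> bool:
        return self.fractions is not None

    def fraction(self, label: str) -> float:
        if self.fractions is None:
            raise ValueError("fractions undefined for an empty frame")
        return dict(zip((LC, LE, GAS), self.fractions))[label]


@dataclass
class PoreEstimate:
    radius: float  # nm
    grid_shape: Tuple[int, int]
    argmax_point: Tuple[float, float]  # nm


@dataclass
class TrajectoryStats:
    mean: float
    sd: float
    frames_used: int


@dataclass
class PbcTessellation:
    """Voronoi adjacency of the primary-cell atoms under periodic boundaries.

    ``neighbors[i]`` maps neighbour atom index -> distance in nm.  The
    distance is the minimum over all periodic images through which the pair
    is Voronoi-adjacent; an atom can neighbour its own periodic image in a
    very sparse frame, in which case the image distance (a box length) is
    recorded under its own index.
    """

    neighbors: List[Dict[int, float]]
    n_atoms: int


_TILE_OFFSETS = np.array(
    [(ix, iy) for ix in (-1, 0, 1) for iy in (-1, 0, 1) if not (ix == 0 and iy == 0)]
)


def _tile_3x3(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Primary copy first, then the eight ghost copies; index % n is the original."""
    ghosts = [coords + off * box for off in _TILE_OFFSETS]
    return np.concatenate([coords] + ghosts, axis=0)


def build_pbc_tessellation(frame: MonolayerFrame, *, perturb_seed: int = 2024) -> PbcTessellation:
    """Voronoi tessellation of a periodic frame via full 3x3 ghost tiling.

    Neighbour relations of primary-cell atoms equal those of a Voronoi
    diagram of the infinite periodic point set.  Degenerate inputs
    (duplicate points, which qhull rejects) are perturbed deterministically
    by at most 1e-9 nm with a warning.

    Raises
    ------
    ValueError
        If the frame has fewer than 4 atoms (tessellation undefined).
    """
    n = frame.n_atoms
    if n < 4:
        raise ValueError(f"Voronoi tessellation requires >= 4 atoms, got {n}")
    box = np.array(frame.box_lengths)
    coords = frame.coords
    # duplicate points make qhull facets degenerate; nudge deterministically
    rounded = np.round(coords / 1e-9).astype(np.int64)
    if len(np.unique(rounded, axis=0)) < n:
        warnings.warn(
            "duplicate/near-duplicate points perturbed by <= 1e-9 nm for tessellation",
            stacklevel=2,
        )
        rng = np.random.default_rng(perturb_seed)
        coords = np.mod(coords + rng.uniform(-1e-9, 1e-9, size=coords.shape), box)

    tiled = _tile_3x3(coords, box)
    vor = Voronoi(tiled)
    neighbors: List[Dict[int, float]] = [dict() for _ in range(n)]
    for (i, j) in vor.ridge_points:
        a, b = int(i), int(j)
        if a >= n and b >= n:
            continue
        oa, ob = a % n, b % n
        if oa == ob:
            # atom adjacent to its own periodic image: the image distance
            # (a box translation) is the physically meaningful separation
            dist = float(np.linalg.norm(tiled[a] - tiled[b]))
        else:
            d = coords[oa] - coords[ob]
            d -= box * np.round(d / box)
            dist = float(np.linalg.norm(d))
        if a < n:
            prev = neighbors[oa].get(ob)
            if prev is None or dist < prev:
                neighbors[oa][ob] = dist
        if b < n:
            prev = neighbors[ob].get(oa)
            if prev is None or dist < prev:
                neighbors[ob][oa] = dist
    return PbcTessellation(neighbors=neighbors, n_atoms=n)


def classify_phases(
    frame: MonolayerFrame,
    tessellation: Optional[PbcTessellation] = None,
    *,
    lc_cutoff: float = DEFAULT_LC_CUTOFF,
    gas_cutoff: float = DEFAULT_GAS_CUTOFF,
    lc_min_neighbors: int = DEFAULT_LC_MIN_NEIGHBORS,
) -> PhaseAssignment:
    """Assign each tail-marker atom a 2D phase label.

    An empty frame yields ``fractions=None`` (undefined, not 0/0).
    """
    n = frame.n_atoms
    if n == 0:
        return PhaseAssignment(labels=np.array([], dtype=object), n_atoms=0, fractions=None)
    if tessellation is None:
        tessellation = build_pbc_tessellation(frame)
    if tessellation.n_atoms != n:
        raise ValueError("tessellation does not match frame")
    labels = np.empty(n, dtype=object)
    for i, nbrs in enumerate(tessellation.neighbors):
        dists = np.fromiter(nbrs.values(), dtype=float, count=len(nbrs))
        if np.count_nonzero(dists <= lc_cutoff) >= lc_min_neighbors:
            labels[i] = LC
        elif dists.size and dists.max() > gas_cutoff:
            labels[i] = GAS
        elif dists.size == 0:
            labels[i] = GAS  # isolated atom: no neighbour at all
        else:
            labels[i] = LE
    counts = np.array([np.sum(labels == lab) for lab in (LC, LE, GAS)], dtype=float)
    fractions = tuple(counts / n)
    return PhaseAssignment(labels=labels, n_atoms=n, fractions=fractions)


def _grid_centers(box: Tuple[float, float], grid_shape: Tuple[int, int]) -> np.ndarray:
    nx, ny = grid_shape
    xs = (np.arange(nx) + 0.5) * box[0] / nx
    ys = (np.arange(ny) + 0.5) * box[1] / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def largest_pore_radius(
    frame: MonolayerFrame, grid_shape: Tuple[int, int] = (40, 40)
) -> PoreEstimate:
    """Largest distance from a grid of cell centres to the nearest atom.

    This is a grid-resolution estimate of the radius of the largest empty
    circle (pore) in the frame under periodic boundaries; the true largest
    empty radius lies within one grid-cell diagonal above the estimate.
    For an empty frame the half box diagonal is returned with a warning.
    """
    box = frame.box_lengths
    if frame.n_atoms == 0:
        warnings.warn("empty frame: pore radius set to half the box diagonal", stacklevel=2)
        r = 0.5 * float(np.hypot(*box))
        return PoreEstimate(radius=r, grid_shape=grid_shape, argmax_point=(box[0] / 2, box[1] / 2))
    grid = _grid_centers(box, grid_shape)
    tree = cKDTree(frame.coords, boxsize=box)
    dists, _ = tree.query(grid)
    k = int(np.argmax(dists))
    return PoreEstimate(
        radius=float(dists[k]), grid_shape=tuple(grid_shape), argmax_point=tuple(grid[k])
    )


def trajectory_statistics(
    frames: Sequence[MonolayerFrame],
    reducer: Callable[[MonolayerFrame], float],
    *,
    t_min: float = 10.0,
    stride: float = 2.5,
) -> TrajectoryStats:
    """Mean and sd of a per-frame scalar over an analysis window.

    The reducer is applied to each leaflet separately; leaflets sharing a
    time point are averaged, then the per-time values are sampled on the
    grid ``t_min, t_min + stride, ...`` (nearest time within half a stride)
    and reduced to mean and standard deviation (ddof=1 when more than one
    frame is retained).
    """
    if not frames:
        raise ValueError("no frames supplied")
    by_time: Dict[float, List[float]] = {}
    for fr in frames:
        by_time.setdefault(round(float(fr.time), 9), []).append(reducer(fr))
    times = np.array(sorted(by_time))
    values = np.array([np.mean(by_time[t]) for t in times])
    targets = np.arange(t_min, times.max() + stride / 2, stride)
    picked: List[float] = []
    used = set()
    for tt in targets:
        j = int(np.argmin(np.abs(times - tt)))
        if abs(times[j] - tt) <= stride / 2 + 1e-9 and j not in used:
            used.add(j)
            picked.append(values[j])
    if not picked:
        raise ValueError(f"no frames at or after t_min = {t_min}")
    arr = np.array(picked)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return TrajectoryStats(mean=float(arr.mean()), sd=sd, frames_used=arr.size)


def rdf_2d(frame: MonolayerFrame, r_max: float, n_bins: int = 100) -> Tuple[np.ndarray, np.ndarray]:
    """2D radial distribution function g(r) under minimum image.

    Normalised by the ideal-gas annulus expectation so that g -> 1 at large
    r for a disordered system.  Requires ``r_max`` at most half the smaller
    box length (minimum-image validity) and at least two atoms.

    Returns (bin centres, g) arrays of length ``n_bins``.
    """
    n = frame.n_atoms
    if n < 2:
        raise ValueError("rdf undefined for fewer than 2 atoms")
    lx, ly = frame.box_lengths
    if r_max > min(lx, ly) / 2 + 1e-12:
        raise ValueError(
            f"r_max = {r_max} exceeds half the smaller box length "
            f"({min(lx, ly) / 2}); minimum-image distances are invalid beyond it"
        )
    box = np.array(frame.box_lengths)
    d = frame.coords[:, None, :] - frame.coords[None, :, :]
    d -= box * np.round(d / box)
    dist = np.linalg.norm(d, axis=-1)
    iu = np.triu_indices(n, k=1)
    pair_d = dist[iu]
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts, _ = np.histogram(pair_d, bins=edges)
    area = lx * ly
    rho = n / area
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    # counts are unique pairs; expected unique pairs per bin = n/2 * rho * annulus
    expected = 0.5 * n * rho * annulus
    g = counts / expected
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, g
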