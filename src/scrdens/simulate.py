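"""Synthetic trap configurations, populations and encounter histories.

The field layouts these generators emulate are a spatially extensive
design (snares allocated over a 10x10 km sighting grid proportional to a
clustered sighting-intensity surface, with a ~3 km minimum spacing) and a
spatially intensive design (five 9x9 snare arrays of 2.6 km² cells).  The
original snare coordinates are not published, so the generators reproduce
the designs' statistical structure: counts, spacing rules and clustered
allocation, not the exact field geometry.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection import build_behavior_covariates, halfnormal_p
from .io import CaptureData, TrapArray
from .spatial import HabitatMask, mask_area, pairwise_distances

__all__ = [
    "SightingSurface",
    "Population",
    "gen_intensive_traps",
    "gen_extensive_traps",
    "sim_population",
    "sim_captures",
]

log = logging.getLogger(__name__)

# snares allocated per cell as a step function of the cell's sighting count
ALLOCATION_RULE = ((1, 3, 1), (4, 5, 4), (6, 7, 5), (8, np.inf, 6))


def snares_for_sightings(count: int) -> int:
    """Cells with 1-3 sightings get one snare, 4-5 get four, 6-7 five,
    >=8 six; cells with zero sightings get none."""
    if count <= 0:
        return 0
    for lo, hi, n in ALLOCATION_RULE:
        if lo <= count <= hi:
            return n
    raise AssertionError("unreachable")


@dataclass
class SightingSurface:
    """Relative sighting intensity: isotropic Gaussian clusters + a floor.

    Stands in for a historical-sightings kernel surface; intensity is in
    arbitrary units and only its shape matters (allocation is scaled to a
    target snare total).
    """

    centers: np.ndarray              # (C, 2) km
    sds: np.ndarray                  # (C,) km
    weights: np.ndarray              # (C,) positive
    region: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    floor: float = 0.02              # uniform background fraction
    mean_total_sightings: float = 450.0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0) or np.any(self.sds <= 0):
            raise ValueError("cluster weights and SDs must be positive")
        xmin, xmax, ymin, ymax = self.region
        inside = (
            (self.centers[:, 0] >= xmin) & (self.centers[:, 0] <= xmax)
            & (self.centers[:, 1] >= ymin) & (self.centers[:, 1] <= ymax)
        )
        if not inside.all():
            raise ValueError("all cluster centers must lie inside the region")

    def density(self, points: np.ndarray) -> np.ndarray:
        """Unnormalised intensity at planar points (N, 2)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        dens = (self.weights[None, :] * np.exp(-d2 / (2 * self.sds[None, :] ** 2))).sum(axis=1)
        return dens + self.floor * self.weights.sum()

    @classmethod
    def default(cls) -> "SightingSurface":
        """Three-cluster surface over a 120x120 km region (clustered, like
        sightings of a recolonising population concentrated in core areas)."""
        return cls(
            centers=np.array([[35.0, 75.0], [80.0, 40.0], [95.0, 95.0]]),
            sds=np.array([16.0, 20.0, 12.0]),
            weights=np.array([1.0, 0.8, 0.5]),
            region=(0.0, 120.0, 0.0, 120.0),
        )


@dataclass
class Population:
    """Activity centers and sexes of a simulated population."""

    xy: np.ndarray                   # (N, 2) km
    sex: np.ndarray                  # (N,) of {"F", "M"}
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.xy.shape[0]


# ---------------------------------------------------------------------------
# trap generators

_DEFAULT_ORIGINS = ((0.0, 0.0), (45.0, 10.0), (90.0, -6.0), (135.0, 12.0), (180.0, 4.0))


def gen_intensive_traps(
    n_arrays: int = 5,
    dim: int = 9,
    cell_area: float = 2.6,
    origins: Optional[Sequence[tuple[float, float]]] = None,
    jitter: bool = False,
    dropout: Optional[dict] = None,
    seed: Optional[int] = None,
) -> TrapArray:
    """Square snare arrays on a grid of ``sqrt(cell_area)`` km spacing.

    By default five 9x9 arrays (labelled A..E west to east) are laid along
    an east-west band with ~45 km between array origins.  With ``jitter``
    each snare is displaced uniformly within its grid cell (one snare per
    cell, position chosen in the field).  ``dropout`` maps an array label
    to a number of snares removed at random (e.g. ``{"B": 2}``).
    """
    if origins is None:
        if n_arrays > len(_DEFAULT_ORIGINS):
            raise ValueError("supply origins for more than 5 arrays")
        origins = _DEFAULT_ORIGINS[:n_arrays]
    if len(origins) != n_arrays:
        raise ValueError("origins length must equal n_arrays")
    spacing = float(np.sqrt(cell_area))
    extent = (dim - 1) * spacing
    # reject overlapping arrays (bounding boxes padded by one cell)
    for i in range(n_arrays):
        for j in range(i + 1, n_arrays):
            dx = abs(origins[i][0] - origins[j][0])
            dy = abs(origins[i][1] - origins[j][1])
            if dx < extent + spacing and dy < extent + spacing:
                raise ValueError(f"arrays {i} and {j} overlap")
    order = np.argsort([o[0] for o in origins])  # labels west to east
    rng = np.random.default_rng(seed)
    ids, xy, labels = [], [], []
    for rank, idx in enumerate(order):
        label = string.ascii_uppercase[rank]
        ox, oy = origins[idx]
        pts = []
        for r in range(dim):
            for c in range(dim):
                px, py = ox + c * spacing, oy + r * spacing
                if jitter:
                    px += rng.uniform(-spacing / 2, spacing / 2)
                    py += rng.uniform(-spacing / 2, spacing / 2)
                pts.append((px, py))
        keep = np.arange(len(pts))
        if dropout and label in dropout:
            n_drop = int(dropout[label])
            keep = np.sort(rng.choice(len(pts), size=len(pts) - n_drop, replace=False))
        for c, k in enumerate(keep):
            ids.append(f"{label}{c + 1:02d}")
            xy.append(pts[k])
            labels.append(label)
    return TrapArray(ids, np.array(xy), np.array(labels, dtype=object),
                     meta={"design": "intensive", "spacing": spacing})


def gen_extensive_traps(
    surface: Optional[SightingSurface] = None,
    cell_size: float = 10.0,
    n_snares: int = 378,
    min_spacing: float = 3.0,
    seed: Optional[int] = None,
    max_attempts: int = 200,
) -> TrapArray:
    """Snares allocated over a sighting grid proportional to intensity.

    Sighting counts per ``cell_size`` km cell are Poisson draws from the
    surface; the allocation rule converts counts to snares per cell (zero
    sightings -> none) and the total is rescaled to ``n_snares`` by
    largest-remainder proportional rounding.  Snare positions are uniform
    within their cell subject to a best-effort global ``min_spacing``; when
    rejection sampling cannot satisfy it the constraint is relaxed with a
    logged warning.  The per-cell allocation table is attached as
    ``meta["allocation"]``.
    """
    surface = surface or SightingSurface.default()
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = surface.region
    nx = int(round((xmax - xmin) / cell_size))
    ny = int(round((ymax - ymin) / cell_size))
    cx, cy = np.meshgrid(
        xmin + (np.arange(nx) + 0.5) * cell_size,
        ymin + (np.arange(ny) + 0.5) * cell_size,
        indexing="ij",
    )
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    dens = surface.density(centers)
    lam = dens / dens.sum() * surface.mean_total_sightings
    sightings = rng.poisson(lam)
    alloc = np.array([snares_for_sightings(int(s)) for s in sightings])
    if alloc.sum() == 0:
        raise ValueError("no cell received any snare; surface too flat or sparse")
    # largest-remainder rescaling to the target snare total
    scaled = alloc * (n_snares / alloc.sum())
    n_cell = np.floor(scaled).astype(int)
    short = n_snares - n_cell.sum()
    order = np.argsort(-(scaled - np.floor(scaled)))
    for idx in order[:short]:
        if alloc[idx] > 0:
            n_cell[idx] += 1
    placed: list[tuple[float, float]] = []
    ids, relaxed = [], 0
    for ci in np.nonzero(n_cell)[0]:
        x0, y0 = centers[ci] - cell_size / 2
        for _ in range(n_cell[ci]):
            best = None
            for _attempt in range(max_attempts):
                cand = (x0 + rng.uniform(0, cell_size), y0 + rng.uniform(0, cell_size))
                if placed:
                    dmin = np.min(np.hypot(
                        np.array([p[0] for p in placed]) - cand[0],
                        np.array([p[1] for p in placed]) - cand[1],
                    ))
                else:
                    dmin = np.inf
                if dmin >= min_spacing:
                    best = cand
                    break
            if best is None:
                relaxed += 1
                best = (x0 + rng.uniform(0, cell_size), y0 + rng.uniform(0, cell_size))
            placed.append(best)
            ids.append(f"E{len(ids) + 1:03d}")
    if relaxed:
        log.warning("min spacing of %.1f km relaxed for %d snares", min_spacing, relaxed)
    allocation = pd.DataFrame({
        "cell_x": centers[:, 0], "cell_y": centers[:, 1],
        "intensity": dens, "sightings": sightings,
        "snares_rule": alloc, "snares_final": n_cell,
    })
    return TrapArray(ids, np.array(placed), None,
                     meta={"design": "extensive", "allocation": allocation,
                           "n_relaxed": relaxed})


# ---------------------------------------------------------------------------
# population and capture simulation

def sim_population(
    D: float,
    mask: HabitatMask,
    n_dist: str = "poisson",
    sex_ratio: float = 0.5,
    seed=None,
) -> Population:
    """Simulate activity centers uniformly over a habitat mask.

    ``D`` is animals per 100 km².  ``N`` is Poisson with mean
    ``D * area / 100`` (matching the full likelihood's Poisson-N
    assumption) or fixed at the rounded mean.  Centers land uniformly in a
    uniformly chosen mask cell; sexes are Bernoulli(``sex_ratio`` female).
    """
    if D <= 0:
        raise ValueError("density must be positive")
    if n_dist not in ("poisson", "fixed"):
        raise ValueError("n_dist must be 'poisson' or 'fixed'")
    rng = np.random.default_rng(seed)
    mean_N = D * mask_area(mask) / 100.0
    N = int(rng.poisson(mean_N)) if n_dist == "poisson" else int(round(mean_N))
    cells = rng.integers(0, mask.n_points, size=N)
    dx, dy = mask.spacing
    xy = mask.points[cells] + np.column_stack([
        rng.uniform(-dx / 2, dx / 2, size=N),
        rng.uniform(-dy / 2, dy / 2, size=N),
    ])
    sex = np.where(rng.random(N) < sex_ratio, "F", "M").astype(object)
    return Population(xy=xy, sex=sex, meta={"true_D": D, "n_dist": n_dist})


def sim_captures(
    pop: Population,
    traps: TrapArray,
    g0: float,
    sigma: float,
    n_occasions: int = 6,
    behavior: Optional[tuple[str, float]] = None,
    seed=None,
    session_label: str = "sim",
) -> CaptureData:
    """Bernoulli half-normal encounter histories for a simulated population.

    Detection of each animal at each detector on each occasion is
    Bernoulli with ``halfnormal_p`` at the center-detector distance.  An
    optional behavioural response ``(type, effect)`` shifts logit(g0) by
    ``effect`` wherever the prior-detection state indicator is 1.  Animals
    never detected are dropped; the count dropped is reported in
    ``meta["n_undetected"]``.
    """
    rng = np.random.default_rng(seed)
    N, J, K = pop.n, traps.n_detectors, n_occasions
    d = pairwise_distances(pop.xy, traps.xy) if N else np.zeros((0, J))
    p_base = halfnormal_p(d, g0, sigma)
    y = np.zeros((N, J, K), dtype=np.uint8)
    if behavior is None:
        y[:] = rng.random((N, J, K)) < p_base[:, :, None]
    else:
        kind, effect = behavior
        from scipy.special import expit, logit
        kern = np.exp(-(d ** 2) / (2 * sigma ** 2))
        # behavioural shift acts on logit(g0); rebuild p each occasion from
        # the running prior-detection state
        for k in range(K):
            z = build_behavior_covariates(y[:, :, : k + 1], kind).z[:, :, -1]
            g0_eff = expit(logit(g0) + effect * z)
            y[:, :, k] = rng.random((N, J)) < g0_eff * kern
    detected = y.reshape(N, -1).any(axis=1)
    n_undetected = int(N - detected.sum())
    y = y[detected]
    ids = [f"a{i + 1:04d}" for i in range(int(detected.sum()))]
    sex = pop.sex[detected].copy()
    data = CaptureData(ids, y, sex, session_label=session_label,
                       detector_ids=list(traps.detector_ids))
    data.meta["n_undetected"] = n_undetected
    data.meta["true_params"] = {"g0": g0, "sigma": sigma,
                                "behavior": behavior, "n_occasions": K}
    return data
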