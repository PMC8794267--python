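"""Morphometric quantification: deformation, areas, contact maps,
conserved-contact classification, path signatures, planarization width and
the simulation-to-experiment time-scale fit.

Conventions: surface area is the |grad(phi)| integral (exact for a
monotone 0-to-1 interface profile), cross-checkable against a marching-
cubes triangulation; contacts are counted on the argmax label volume as
shared voxel faces; a pair "contacts" when its shared area reaches a
threshold (default 1 um^2, a few voxel faces at the reference pitch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage.measure import marching_cubes

from .errors import DegenerateFieldError, FitError
from .phase_fields import CellState, EmbryoState, gradient

DEFAULT_CONTACT_THRESHOLD_UM2 = 1.0

Pair = frozenset


# ---------------------------------------------------------------------------
# shape metrics


def deformation_alpha(cell: CellState) -> float:
    """Dimensionless departure of the cell shape from its equal-volume sphere.

    With rbar = (3V / 4 pi)^(1/3) from the field volume and R the distance
    of each surface element of the phi = 0.5 isosurface to the mass centre:

        alpha = surface integral of (R - rbar)^2 / (rbar^2 R^2) ds

    Zero for a perfect sphere; invariant under uniform scaling.
    """
    phi = cell.field
    v_lattice = phi.volume_lattice()
    if not v_lattice > 0:
        raise DegenerateFieldError(f"cell {cell.name}: zero-mass field")
    rbar = (3.0 * v_lattice / (4.0 * np.pi)) ** (1.0 / 3.0)  # lattice units
    rc = (phi.center_of_mass() - np.asarray(phi.grid.origin)) / phi.grid.dl
    try:
        verts, faces, _, _ = marching_cubes(phi.values, level=0.5)
    except (ValueError, RuntimeError) as exc:
        raise DegenerateFieldError(
            f"cell {cell.name}: empty phi=0.5 isosurface"
        ) from exc
    tri = verts[faces]  # (n_faces, 3, 3) in voxel units
    centroids = tri.mean(axis=1)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    radii = np.linalg.norm(centroids - rc, axis=1)
    good = radii > 1e-9
    integrand = (radii[good] - rbar) ** 2 / (rbar**2 * radii[good] ** 2)
    return float((integrand * areas[good]).sum())


def surface_area(cell: CellState) -> float:
    """Cell surface area in um^2 via the |grad(phi)| integral."""
    g = gradient(cell.field.values)
    norm = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
    return float(norm.sum()) * cell.field.grid.dl**2


def surface_area_isosurface(cell: CellState) -> float:
    """Cross-check estimator: triangulated area of the phi = 0.5 isosurface."""
    verts, faces, _, _ = marching_cubes(cell.field.values, level=0.5)
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float((0.5 * np.linalg.norm(cross, axis=1)).sum()) * cell.field.grid.dl**2


def positional_variation_eta(
    sim: Sequence[np.ndarray], exp: Sequence[np.ndarray]
) -> float:
    """Mean squared positional deviation (um^2) between matched cell lists."""
    sim = np.asarray(sim, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if sim.shape != exp.shape:
        raise ValueError(f"mismatched position lists: {sim.shape} vs {exp.shape}")
    return float(((sim - exp) ** 2).sum(axis=-1).mean())


def relative_error_delta(inferred: float, measured: float) -> float:
    """delta = |inferred / measured - 1| (absolute relative error)."""
    if measured == 0:
        raise ZeroDivisionError("measured value must be non-zero")
    return abs(inferred / measured - 1.0)


def embryo_width(positions: Iterable[np.ndarray]) -> float:
    """Maximum pairwise distance along y / L-R (um) — the planarization probe."""
    ys = [np.asarray(p, dtype=float)[1] for p in positions]
    if not ys:
        raise ValueError("need at least one position")
    return float(max(ys) - min(ys))


# ---------------------------------------------------------------------------
# contact maps


@dataclass
class ContactMap:
    """Contacting cell pairs at one time point, with shared areas (um^2)."""

    pairs: set
    areas: dict
    threshold: float
    cells: tuple[str, ...] = ()

    def pair_set(self) -> frozenset:
        return frozenset(self.pairs)

    def has(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.pairs

    def area(self, a: str, b: str) -> float:
        return self.areas.get(frozenset((a, b)), 0.0)


def label_volume(embryo: EmbryoState) -> np.ndarray:
    """Argmax segmentation: 0 = exterior, i+1 = cell i (winning phi > 0.5)."""
    stack = np.stack([c.field.values for c in embryo.cells])
    winner = np.argmax(stack, axis=0)
    winning = np.take_along_axis(stack, winner[None], axis=0)[0]
    return np.where(winning > 0.5, winner + 1, 0).astype(np.int32)


def _face_counts(labels: np.ndarray) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        a = labels[tuple(lo)].ravel()
        b = labels[tuple(hi)].ravel()
        diff = a != b
        a, b = a[diff], b[diff]
        key = np.stack([np.minimum(a, b), np.maximum(a, b)], axis=1)
        uniq, n = np.unique(key, axis=0, return_counts=True)
        for (la, lb), c in zip(uniq, n):
            counts[(int(la), int(lb))] = counts.get((int(la), int(lb)), 0) + int(c)
    return counts


def contact_area(a: CellState, b: CellState) -> float:
    """Shared interface area (um^2) between two cells: voxel faces between
    their argmax labels times dl^2."""
    grid = a.field.grid
    stack = np.stack([a.field.values, b.field.values])
    winner = np.argmax(stack, axis=0)
    winning = np.take_along_axis(stack, winner[None], axis=0)[0]
    labels = np.where(winning > 0.5, winner + 1, 0).astype(np.int32)
    counts = _face_counts(labels)
    return counts.get((1, 2), 0) * grid.dl**2


def contact_map(
    embryo: EmbryoState, threshold: float = DEFAULT_CONTACT_THRESHOLD_UM2
) -> ContactMap:
    """All pairwise contacts of the embryo from one label volume."""
    labels = label_volume(embryo)
    names = embryo.names
    dl2 = embryo.grid.dl**2
    counts = _face_counts(labels)
    areas = {}
    for (la, lb), n in counts.items():
        if la == 0:
            continue  # cell-exterior interface
        pair = frozenset((names[la - 1], names[lb - 1]))
        areas[pair] = n * dl2
    pairs = {p for p, area in areas.items() if area >= threshold}
    return ContactMap(pairs=pairs, areas=areas, threshold=threshold, cells=tuple(names))


# ---------------------------------------------------------------------------
# conserved-contact classification and path signatures

CONSERVED_CONTACT = "conserved_contact"
CONSERVED_NON_CONTACT = "conserved_non_contact"
UNCONSERVED = "unconserved"


@dataclass
class ConservedClassification:
    """Ternary per-pair contact conservation across replicate samples."""

    labels: dict
    n_contact: dict
    n_samples: int

    def of(self, a: str, b: str) -> str:
        return self.labels[frozenset((a, b))]

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)


def classify_conserved(maps: Sequence[ContactMap]) -> ConservedClassification:
    """Classify every cell pair over replicate contact maps.

    A pair present in all samples is a conserved contact, in none a
    conserved non-contact, otherwise unconserved. The pair universe is all
    unordered pairs of the union cell set.
    """
    if not maps:
        raise ValueError("need at least one contact map")
    cells = sorted(set().union(*(m.cells for m in maps)))
    if not cells:
        cells = sorted({n for m in maps for p in m.pairs for n in p})
    n = len(maps)
    counts: dict[frozenset, int] = {}
    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            counts[frozenset((a, b))] = sum(1 for m in maps if m.has(a, b))
    labels = {}
    for pair, c in counts.items():
        if c == n:
            labels[pair] = CONSERVED_CONTACT
        elif c == 0:
            labels[pair] = CONSERVED_NON_CONTACT
        else:
            labels[pair] = UNCONSERVED
    return ConservedClassification(labels, counts, n)


def path_signature(maps: Sequence[ContactMap]) -> list[frozenset]:
    """Deduplicated temporal sequence of contact-pair sets.

    Two runs follow the same developmental path iff their signatures are
    equal.
    """
    signature: list[frozenset] = []
    for m in maps:
        ps = m.pair_set()
        if not signature or signature[-1] != ps:
            signature.append(ps)
    return signature


# ---------------------------------------------------------------------------
# time-scale conversion


@dataclass(frozen=True)
class TimescaleFit:
    """Proportional steps-per-minute conversion between model and embryo time."""

    k: float
    r_squared: float
    delta_t0: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise FitError("conversion ratio k must be positive")


#: experimental cytokinesis lag (min) absent from the instantaneous-division model
DEFAULT_DELTA_T0 = 2.2784


def fit_timescale(
    sim_durations: Sequence[float],
    exp_durations: Sequence[float],
    delta_t0: float = DEFAULT_DELTA_T0,
) -> TimescaleFit:
    """Least-squares slope of sim steps vs (experimental minutes - delta_t0).

    The line passes through the origin: the predetermined intercept
    ``delta_t0`` removes the cytokinesis time absent in silico. R^2 is
    reported on the same through-origin model.
    """
    y = np.asarray(sim_durations, dtype=float)
    x = np.asarray(exp_durations, dtype=float) - delta_t0
    if y.size != x.size or y.size < 2:
        raise FitError("need >= 2 matched stage durations")
    sxx = float((x * x).sum())
    if sxx <= 0 or np.ptp(x) == 0:
        raise FitError("degenerate experimental durations (zero variance)")
    k = float((x * y).sum()) / sxx
    resid = y - k * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise FitError("degenerate simulated durations (zero variance)")
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return TimescaleFit(k=k, r_squared=min(max(r2, 0.0), 1.0), delta_t0=delta_t0)


def steps_to_minutes(steps: float, fit: TimescaleFit | float) -> float:
    """Convert a within-stage step count to minutes (no intercept needed)."""
    k = fit.k if isinstance(fit, TimescaleFit) else float(fit)
    return steps / k
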