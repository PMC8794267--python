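"""Cell division as instantaneous bisection of the mother's phase field.

Cytokinesis is reduced to one event: the mother field is multiplied by a
sigmoid of the signed distance to a splitting plane
``n . (r - r_c) - b = 0`` through the mother's mass centre. The plane
normal ``n`` is the volume segregation direction and the offset ``b`` is
chosen so the daughter volumes hit a prescribed ratio; the sigmoid width
``epsilon`` defaults to 2**-52 (a numerically sharp step). The two factors
sum to 1 algebraically, so the daughters partition the mother's mass
exactly at any epsilon.

Lineage nomenclature: germline cells P0..P4 divide asymmetrically
(P0 -> AB + P1, P1 -> EMS + P2, P2 -> C + P3, P3 -> D + P4,
EMS -> MS + E); AB descendants append a/p/l/r by position relative to the
sister (ABa -> ABal + ABar, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .errors import DivisionError, LineageError
from .phase_fields import CellState, EmbryoState, PhaseField

#: epsilon default: the split saturates to a {0, 1/2, 1} step mask
DEFAULT_EPSILON = 2.0**-52

_FOUNDER_PARENTS = {
    "AB": "P0",
    "P1": "P0",
    "EMS": "P1",
    "P2": "P1",
    "MS": "EMS",
    "E": "EMS",
    "C": "P2",
    "P3": "P2",
    "D": "P3",
    "P4": "P3",
}

EIGHT_CELL_NAMES = frozenset({"ABal", "ABar", "ABpl", "ABpr", "MS", "E", "C", "P3"})


def parent_of(name: str) -> str | None:
    """Parent cell name under the standard nomenclature; None for P0 / unknown."""
    if name in _FOUNDER_PARENTS:
        return _FOUNDER_PARENTS[name]
    if name.startswith("AB") and len(name) > 2 and all(c in "aplr" for c in name[2:]):
        return name[:-1]
    return None


@dataclass
class Lineage:
    """Parent/child bookkeeping; nomenclature-derived with explicit overrides."""

    parents: dict[str, str] = dataclass_field(default_factory=dict)

    def parent(self, name: str) -> str | None:
        if name in self.parents:
            return self.parents[name]
        return parent_of(name)

    def register(self, child: str, parent: str) -> None:
        known = parent_of(child)
        if known is not None and known != parent:
            raise LineageError(
                f"{child} is the daughter of {known} by nomenclature, not {parent}"
            )
        if child in self.parents and self.parents[child] != parent:
            raise LineageError(f"{child} already has parent {self.parents[child]}")
        self.parents[child] = parent

    def are_sisters(self, a: str, b: str) -> bool:
        """True iff the two (distinct) cells share a parent."""
        if a == b:
            return False
        pa, pb = self.parent(a), self.parent(b)
        return pa is not None and pa == pb


def are_sisters(a: str, b: str, lin: Lineage | None = None) -> bool:
    return (lin or Lineage()).are_sisters(a, b)


@dataclass(frozen=True)
class DivisionSpec:
    """One cytokinesis event.

    ``direction`` is the unit volume-segregation vector; ``daughters[0]``
    receives the half space on the positive side of ``direction`` and the
    ratio is ``volume_ratio[0] : volume_ratio[1]`` for daughters[0] :
    daughters[1].
    """

    mother: str
    daughters: tuple[str, str]
    direction: tuple[float, float, float]
    volume_ratio: tuple[float, float] = (1.0, 1.0)
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if abs(norm - 1.0) > 1e-6:
            if norm == 0:
                raise DivisionError(f"division direction of {self.mother} is zero")
            d = d / norm
        object.__setattr__(self, "direction", tuple(float(v) for v in d))
        if len(self.daughters) != 2 or self.daughters[0] == self.daughters[1]:
            raise LineageError(f"division of {self.mother} needs two distinct daughters")
        if min(self.volume_ratio) <= 0:
            raise DivisionError("volume ratio components must be positive")
        if not self.epsilon > 0:
            raise DivisionError("epsilon must be positive")


def _plane_coordinate(phi: PhaseField, direction: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """n . (r - r_c) over the grid, in physical units (um)."""
    x, y, z = phi.grid.meshgrid()
    return (
        direction[0] * (x - rc[0])
        + direction[1] * (y - rc[1])
        + direction[2] * (z - rc[2])
    )


def _positive_mass(phi_values: np.ndarray, coord: np.ndarray, b: float, eps_um: float) -> float:
    s = 0.5 * np.tanh((coord - b) / eps_um) + 0.5
    return float((phi_values * s).sum())


def find_offset_b(
    phi: PhaseField,
    direction,
    ratio: tuple[float, float],
    *,
    epsilon: float = DEFAULT_EPSILON,
    rc: np.ndarray | None = None,
    tol_voxels: float = 1e-3,
) -> float:
    """Plane offset ``b`` (um) hitting the requested daughter-volume ratio.

    The positive-side mass fraction is monotone non-increasing in ``b``, so a
    bisection over the field's extent converges to the offset minimizing
    |achieved - target|. With the default sharp epsilon the achievable
    fractions are quantized by voxel planes (a plane crossed exactly
    contributes half its mass), so the achieved ratio matches the target up
    to that lattice granularity; a gross mismatch signals a degenerate
    field and raises.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    total = phi.volume_lattice()
    if not total > 0:
        raise DivisionError("cannot divide a zero-mass field")
    if rc is None:
        rc = phi.center_of_mass()
    coord = _plane_coordinate(phi, direction, rc)
    eps_um = epsilon * phi.grid.dl
    target_fraction = ratio[0] / (ratio[0] + ratio[1])

    support = phi.values > 1e-6
    r_max = float(np.abs(coord[support]).max()) + phi.grid.dl

    def excess(b: float) -> float:
        # positive-side fraction minus target; decreasing in b
        return _positive_mass(phi.values, coord, b, eps_um) / total - target_fraction

    lo, hi = -r_max, r_max
    if excess(lo) < 0 or excess(hi) > 0:
        raise DivisionError(
            f"volume ratio {ratio} unreachable along the given direction"
        )
    while hi - lo > tol_voxels * phi.grid.dl:
        mid = 0.5 * (lo + hi)
        if excess(mid) >= 0:
            lo = mid
        else:
            hi = mid

    # With a sharp epsilon the fraction is a step function of b; a voxel
    # plane crossed exactly contributes half its mass, so the exact plane
    # coordinates bracketed by the bisection are candidate minimizers of
    # L(b) alongside the interval ends.
    candidates = [lo, hi]
    vals = coord[support]
    near = np.unique(vals[(vals >= lo - 0.5 * phi.grid.dl) & (vals <= hi + 0.5 * phi.grid.dl)])
    if near.size <= 64:
        candidates.extend(float(v) for v in near)
    b = min(
        candidates,
        key=lambda c: abs(_positive_mass(phi.values, coord, c, eps_um) / total
                          - target_fraction),
    )

    achieved = _positive_mass(phi.values, coord, b, eps_um) / total
    if not (0.0 < achieved < 1.0) or abs(achieved / target_fraction - 1.0) > 0.25:
        raise DivisionError(
            f"volume fraction {achieved:.4f} far from target {target_fraction:.4f}: "
            f"degenerate field along this direction"
        )
    return b


def bisect_cell(embryo: EmbryoState, spec: DivisionSpec) -> EmbryoState:
    """Apply one division and return the post-mitotic embryo.

    Daughter fields are ``phi_m * s`` and ``phi_m * (1 - s)`` with ``s`` the
    plane sigmoid; prescribed volumes split the mother's by the achieved
    (not nominal) mass ratio so the volume constraint does not fight the
    split when dynamics resume.
    """
    names = set(embryo.names)
    if spec.mother not in names:
        raise LineageError(f"mother {spec.mother} not present in embryo")
    for d in spec.daughters:
        if d in names:
            raise LineageError(f"daughter name collision: {d} already present")

    mother = embryo.cell(spec.mother)
    direction = np.asarray(spec.direction, dtype=float)
    rc = mother.field.center_of_mass()
    b = find_offset_b(
        mother.field, direction, spec.volume_ratio, epsilon=spec.epsilon, rc=rc
    )
    coord = _plane_coordinate(mother.field, direction, rc)
    eps_um = spec.epsilon * mother.field.grid.dl
    s = 0.5 * np.tanh((coord - b) / eps_um) + 0.5

    phi_pos = PhaseField(mother.field.values * s, embryo.grid)
    phi_neg = PhaseField(mother.field.values * (1.0 - s), embryo.grid)
    mass_pos, mass_neg = phi_pos.volume_lattice(), phi_neg.volume_lattice()
    total = mass_pos + mass_neg
    if not (mass_pos > 0 and mass_neg > 0):
        raise DivisionError(f"degenerate split of {spec.mother}")

    v_pos = mother.prescribed_volume * mass_pos / total
    v_neg = mother.prescribed_volume * mass_neg / total

    new_cells = [c for c in embryo.cells if c.name != spec.mother]
    new_cells.append(CellState(spec.daughters[0], phi_pos, v_pos, embryo.step))
    new_cells.append(CellState(spec.daughters[1], phi_neg, v_neg, embryo.step))

    lineage = dict(embryo.lineage)
    new_state = EmbryoState(
        cells=new_cells,
        eggshell=embryo.eggshell,
        grid=embryo.grid,
        step=embryo.step,
        lineage=lineage,
    )
    lin = Lineage(lineage)
    for d in spec.daughters:
        lin.register(d, spec.mother)
    new_state.lineage = lin.parents
    return new_state
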