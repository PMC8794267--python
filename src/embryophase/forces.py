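"""The four force fields acting on each cell's phase field.

Per cell i the overdamped dynamics balance four interface force densities:

* surface tension   F_ten = -gamma * (lap(phi_i) - c W'(phi_i)) * grad(phi_i) / |grad(phi_i)|^2
* repulsion         F_rep = (g_e phi_i phi_e^2 + g phi_i sum_{j!=i} phi_j^2) * grad(phi_i) / |grad(phi_i)|^2
* attraction        F_atr = sum_{j!=i} sigma_ij grad(phi_j)
* volume constraint F_vol = M (int phi_i - V_i) * grad(phi_i) / |grad(phi_i)|

with W(phi) = phi^2 (phi - 1)^2 the double-well potential. The formal
expressions are 0/0 away from interfaces, so denominators carry a small
regularizer and forces are masked to the interface band where
|grad(phi)|^2 exceeds a threshold (they are line densities defined on the
membrane). All quantities are in lattice units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phase_fields import (
    CellState,
    EmbryoState,
    PhaseField,
    gradient,
    gradient_squared_norm,
    laplacian,
)


@dataclass(frozen=True)
class ForceParams:
    """Mechanical coefficients (dimensionless, lattice units).

    Defaults are the fitted wild-type values: surface tension gamma = 0.25,
    cortex-thickness coefficient c = 1, eggshell stiffness g_e = 16, cell
    stiffness g = 1.6 (the shell is taken one magnitude stiffer than a
    cell), volume-constraint strength M = 0.0012.
    """

    gamma: float = 0.25
    c: float = 1.0
    g_e: float = 16.0
    g: float = 1.6
    M: float = 0.0012
    grad_eps: float = 1e-6
    interface_grad2_min: float = 1e-8

    def __post_init__(self) -> None:
        for key in ("gamma", "c", "g_e", "g", "M"):
            if not getattr(self, key) > 0:
                raise ValueError(f"ForceParams.{key} must be strictly positive")
        if self.grad_eps < 0:
            raise ValueError("grad_eps must be non-negative")


def double_well(phi):
    """W(phi) = phi^2 (phi - 1)^2, minima at 0 and 1."""
    return phi**2 * (phi - 1.0) ** 2


def double_well_deriv(phi):
    """W'(phi) = 2 phi (phi - 1) (2 phi - 1)."""
    return 2.0 * phi * (phi - 1.0) * (2.0 * phi - 1.0)


def _values(f) -> np.ndarray:
    return f.values if isinstance(f, PhaseField) else np.asarray(f)


def _interface_coefficient(grad2: np.ndarray, p: ForceParams) -> np.ndarray:
    """Mask selecting the interface band (1 there, 0 elsewhere)."""
    return grad2 > p.interface_grad2_min


def surface_tension_force(
    cell: CellState, p: ForceParams, *, grad: np.ndarray | None = None,
    lap: np.ndarray | None = None,
) -> np.ndarray:
    """F_ten, shape (3, nx, ny, nz)."""
    phi = cell.field.values
    g = gradient(phi) if grad is None else grad
    lp = laplacian(phi) if lap is None else lap
    g2 = gradient_squared_norm(g)
    coef = -p.gamma * (lp - p.c * double_well_deriv(phi)) / (g2 + p.grad_eps)
    coef *= _interface_coefficient(g2, p)
    return coef * g


def repulsion_force(
    cell: CellState,
    others: Sequence[PhaseField | np.ndarray],
    eggshell: PhaseField | np.ndarray,
    p: ForceParams,
    *,
    grad: np.ndarray | None = None,
) -> np.ndarray:
    """F_rep from the eggshell and all other cells, shape (3, ...)."""
    phi = cell.field.values
    g = gradient(phi) if grad is None else grad
    g2 = gradient_squared_norm(g)
    phie = _values(eggshell)
    others_sq = sum((_values(o) ** 2 for o in others), start=np.zeros_like(phi))
    coef = (p.g_e * phi * phie**2 + p.g * phi * others_sq) / (g2 + p.grad_eps)
    coef *= _interface_coefficient(g2, p)
    return coef * g


def attraction_force(
    cell_name: str,
    cells: Sequence[CellState],
    sigma,
    *,
    grads: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """F_atr = sum over neighbours j of sigma(i, j) * grad(phi_j).

    ``sigma`` is an :class:`~embryophase.attraction.AttractionMatrix` (or any
    object with a ``value(a, b)`` method). Advective pull along neighbour
    interface normals; no regularization is needed (no division).
    """
    shape = None
    out = None
    for other in cells:
        if other.name == cell_name:
            shape = (3,) + other.field.values.shape
            continue
        s = sigma.value(cell_name, other.name)
        if s == 0.0:
            continue
        g = grads[other.name] if grads is not None else gradient(other.field.values)
        out = s * g if out is None else out + s * g
    if out is None:
        if shape is None:
            raise KeyError(f"cell {cell_name!r} not present in cell list")
        out = np.zeros(shape)
    return out


def volume_force(
    cell: CellState, p: ForceParams, *, grad: np.ndarray | None = None
) -> np.ndarray:
    """F_vol = M (int phi - V) grad(phi) / |grad(phi)|  (gradient identity form).

    With a volume deficit the prefactor is negative and -grad(phi) points
    outward, so the interface expands to restore the prescribed volume.
    """
    phi = cell.field.values
    g = gradient(phi) if grad is None else grad
    g2 = gradient_squared_norm(g)
    deficit = float(phi.sum()) - cell.target_volume_lattice()
    coef = p.M * deficit / (np.sqrt(g2) + p.grad_eps)
    coef *= _interface_coefficient(g2, p)
    return coef * g


def net_velocity_field(
    cell: CellState,
    embryo: EmbryoState,
    p: ForceParams,
    sigma,
    tau: float,
) -> np.ndarray:
    """u = (F_ten + F_rep + F_atr + F_vol) / tau, shape (3, ...)."""
    grad = gradient(cell.field.values)
    others = [c.field for c in embryo.cells if c.name != cell.name]
    total = surface_tension_force(cell, p, grad=grad)
    total += repulsion_force(cell, others, embryo.eggshell, p, grad=grad)
    total += attraction_force(cell.name, embryo.cells, sigma)
    total += volume_force(cell, p, grad=grad)
    return total / tau
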