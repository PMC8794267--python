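"""Overdamped time integration and the quasi-steady-state stage scheduler.

The fields advect with the net interface velocity:

    d(phi_i)/dt = -(1/tau) (F_ten + F_rep + F_atr + F_vol) . grad(phi_i)

integrated with explicit forward Euler at a fixed step ``h``. Between
samples the mass centres of all cells are tracked; the root-mean-square
cell speed ``vbar(t)`` defines the embryo's motion state. A quasi-steady
state is a smoothed local minimum of ``vbar`` — the trigger the scheduler
uses to fire the next round of divisions, mirroring the relaxation
observed in vivo before each division group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .attraction import AttractionMatrix, apply_motifs, default_matrix, four_cell_fitted_matrix, zero_matrix
from .division import DivisionSpec, Lineage, bisect_cell
from .errors import ConfigError, InstabilityError
from .forces import ForceParams, double_well_deriv
from .phase_fields import (
    EmbryoState,
    gradient,
    gradient_squared_norm,
    laplacian,
)


@dataclass(frozen=True)
class DynamicsParams:
    """Integration and sampling settings.

    tau is the viscosity of the embryo's internal environment and h the
    explicit time step (model units). ``sample_stride`` steps separate mass-
    centre samples; ``smooth_window`` samples are averaged before minimum
    detection; minima closer than ``qss_min_separation`` samples are merged.
    """

    tau: float = 2.62
    h: float = 0.1
    sample_stride: int = 100
    smooth_window: int = 21
    qss_min_separation: int = 20
    max_steps: int = 500_000

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.h <= 0:
            raise ConfigError("tau and h must be positive")
        if self.sample_stride < 1 or self.smooth_window < 1:
            raise ConfigError("sample_stride and smooth_window must be >= 1")


@dataclass
class VelocityTrace:
    """RMS cell-speed series sampled along a run.

    ``times`` are absolute step indices of the later sample of each speed
    interval; speeds are um per model time unit (|delta r_c| / (stride h)).
    """

    times: np.ndarray
    v_bar: np.ndarray
    per_cell_speeds: np.ndarray  # (n_samples, n_cells)
    cell_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.v_bar = np.asarray(self.v_bar, dtype=float)
        if (self.v_bar < 0).any():
            raise ValueError("v_bar must be non-negative")


def step(embryo: EmbryoState, p: ForceParams, d: DynamicsParams,
         sigma: AttractionMatrix) -> EmbryoState:
    """One explicit Euler step; returns a new state with the clock advanced."""
    out = embryo.copy()
    _advance(out, p, d, sigma, 1)
    return out


def _advance(embryo: EmbryoState, p: ForceParams, d: DynamicsParams,
             sigma: AttractionMatrix, n_steps: int,
             phie2: np.ndarray | None = None) -> None:
    """Advance ``embryo`` in place by ``n_steps`` Euler steps.

    The update uses the advective scalar (F_total . grad(phi_i)) assembled
    per cell; neighbour gradients are shared across cells within a step.
    The arithmetic is identical to dotting the modular force fields of
    :mod:`embryophase.forces` with the cell's gradient.
    """
    if phie2 is None:
        phie2 = embryo.eggshell.values**2
    cells = embryo.cells
    names = [c.name for c in cells]
    targets = [c.target_volume_lattice() for c in cells]
    coef_h = d.h / d.tau
    for step_i in range(n_steps):
        phis = [c.field.values for c in cells]
        grads = [gradient(phi) for phi in phis]
        sq_sum = None
        if len(cells) > 1:
            sq_sum = phis[0] ** 2
            for phi in phis[1:]:
                sq_sum = sq_sum + phi**2
        updates = []
        for i, cell in enumerate(cells):
            phi = phis[i]
            g = grads[i]
            g2 = gradient_squared_norm(g)
            band = g2 > p.interface_grad2_min
            lap = laplacian(phi)
            # (F_ten + F_rep) . grad = A * g2 / (g2 + eps)
            a = -p.gamma * (lap - p.c * double_well_deriv(phi))
            a += p.g_e * phi * phie2
            if sq_sum is not None:
                a += p.g * phi * (sq_sum - phi**2)
            dot = a * (g2 / (g2 + p.grad_eps))
            # F_vol . grad = M (vol - V) g2 / (|g| + eps)
            deficit = float(phi.sum()) - targets[i]
            dot += (p.M * deficit) * (g2 / (np.sqrt(g2) + p.grad_eps))
            dot *= band
            # F_atr . grad = sum_j sigma_ij (grad phi_j . grad phi_i)
            for j, other in enumerate(cells):
                if j == i:
                    continue
                s = sigma.value(cell.name, other.name)
                if s == 0.0:
                    continue
                gj = grads[j]
                dot += s * (gj[0] * g[0] + gj[1] * g[1] + gj[2] * g[2])
            updates.append(coef_h * dot)
        for cell, upd in zip(cells, updates):
            if step_i == 0 and float(np.abs(upd).max()) > 0.5:
                # CFL-style guard, sampled once per advance chunk
                warnings.warn(
                    f"large explicit update (|dphi| > 0.5) for cell {cell.name} "
                    f"at step {embryo.step + 1}: the scheme may be unstable",
                    stacklevel=2,
                )
            cell.field.values -= upd
            if not np.isfinite(cell.field.values).all():
                raise InstabilityError(
                    f"non-finite phase field for cell {cell.name} at step "
                    f"{embryo.step + 1}"
                )
        embryo.step += 1


def average_velocity(
    sample_steps: np.ndarray,
    positions: dict[str, np.ndarray],
    d: DynamicsParams,
) -> VelocityTrace:
    """RMS speed series from per-cell mass-centre samples.

    ``positions[name]`` has shape (n_samples, 3) in um; speeds are finite
    differences over the sampling interval ``sample_stride * h``.
    """
    names = sorted(positions)
    steps = np.asarray(sample_steps)
    if steps.size < 2:
        return VelocityTrace(steps[:0], np.empty(0), np.empty((0, len(names))), names)
    dt = np.diff(steps).astype(float) * d.h
    speeds = np.stack(
        [
            np.linalg.norm(np.diff(np.asarray(positions[n]), axis=0), axis=1) / dt
            for n in names
        ],
        axis=1,
    )
    v_bar = np.sqrt((speeds**2).mean(axis=1))
    return VelocityTrace(steps[1:], v_bar, speeds, names)


def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or series.size == 0:
        return np.asarray(series, dtype=float)
    window = min(window, series.size)
    kernel = np.ones(window) / window
    padded = np.pad(series, (window // 2, window - 1 - window // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def detect_quasi_steady(v: VelocityTrace, d: DynamicsParams) -> list[int]:
    """Step indices of quasi-steady states (local minima of smoothed vbar).

    A minimum is a sign change of the discrete first difference from
    negative to positive; detections closer than ``qss_min_separation``
    samples keep only the earlier one. A monotone series yields [].
    """
    if v.v_bar.size < 3:
        return []
    s = _smooth(v.v_bar, d.smooth_window)
    diff = np.diff(s)
    minima: list[int] = []
    last_idx = -(10**9)
    falling = False
    for i in range(diff.size):
        if diff[i] < 0:
            falling = True
        elif diff[i] > 0:
            if falling and i - last_idx >= d.qss_min_separation:
                minima.append(i)
                last_idx = i
            falling = False
    return [int(v.times[i]) for i in minima]


# ---------------------------------------------------------------------------
# stop rules


@dataclass(frozen=True)
class FixedSteps:
    """Stop after exactly ``n`` integration steps."""

    n: int


@dataclass(frozen=True)
class VelocityBelow:
    """Stop at the first sample with vbar below ``threshold`` (um / time unit)."""

    threshold: float


@dataclass(frozen=True)
class NthQuasiSteady:
    """Stop once the ``n``-th quasi-steady state has been detected."""

    n: int = 1


StopRule = FixedSteps | VelocityBelow | NthQuasiSteady


@dataclass
class Trajectory:
    """Sampled observables of one stage."""

    sample_steps: np.ndarray
    positions: dict[str, np.ndarray]
    velocity: VelocityTrace
    contact_maps: list | None = None


@dataclass
class StageResult:
    trajectory: Trajectory
    t_stop: int
    timed_out: bool
    embryo: EmbryoState
    start_step: int

    @property
    def duration_steps(self) -> int:
        return self.t_stop - self.start_step


def run_stage(
    embryo: EmbryoState,
    p: ForceParams,
    d: DynamicsParams,
    sigma: AttractionMatrix,
    stop: StopRule,
    *,
    contact_stride: int | None = None,
    contact_threshold_um2: float = 1.0,
) -> StageResult:
    """Integrate one stage in place until the stop rule fires or max_steps.

    Returns the sampled trajectory, the reported stop step (for
    ``NthQuasiSteady`` this is the detected minimum itself, which precedes
    the detection moment by the smoothing lag) and the evolved embryo. On
    ``max_steps`` without a stop the result is flagged ``timed_out``.
    """
    from .metrics import contact_map  # deferred: metrics imports dynamics types

    start_step = embryo.step
    phie2 = embryo.eggshell.values**2
    names = embryo.names
    sample_steps = [embryo.step]
    positions = {n: [embryo.cell(n).field.center_of_mass()] for n in names}
    contact_maps = [] if contact_stride is not None else None
    if contact_maps is not None:
        contact_maps.append(contact_map(embryo, contact_threshold_um2))

    t_stop: int | None = None
    timed_out = False
    if isinstance(stop, FixedSteps) and stop.n == 0:
        t_stop = embryo.step

    while t_stop is None:
        advanced = embryo.step - start_step
        if advanced >= d.max_steps:
            timed_out = True
            t_stop = embryo.step
            break
        chunk = min(d.sample_stride, d.max_steps - advanced)
        if isinstance(stop, FixedSteps):
            chunk = min(chunk, stop.n - advanced)
        _advance(embryo, p, d, sigma, chunk, phie2=phie2)
        sample_steps.append(embryo.step)
        for n in names:
            positions[n].append(embryo.cell(n).field.center_of_mass())
        if contact_maps is not None and (len(sample_steps) - 1) % contact_stride == 0:
            contact_maps.append(contact_map(embryo, contact_threshold_um2))

        if isinstance(stop, FixedSteps):
            if embryo.step - start_step >= stop.n:
                t_stop = start_step + stop.n
        else:
            trace = average_velocity(
                np.asarray(sample_steps), {n: np.asarray(v) for n, v in positions.items()}, d
            )
            if isinstance(stop, VelocityBelow):
                if trace.v_bar.size and trace.v_bar[-1] < stop.threshold:
                    t_stop = int(trace.times[-1])
            elif isinstance(stop, NthQuasiSteady):
                minima = detect_quasi_steady(trace, d)
                if len(minima) >= stop.n:
                    t_stop = minima[stop.n - 1]
            else:
                raise ConfigError(f"unknown stop rule {stop!r}")

    arr_positions = {n: np.asarray(v) for n, v in positions.items()}
    trace = average_velocity(np.asarray(sample_steps), arr_positions, d)
    trajectory = Trajectory(np.asarray(sample_steps), arr_positions, trace, contact_maps)
    return StageResult(trajectory, int(t_stop), timed_out, embryo, start_step)


# ---------------------------------------------------------------------------
# stage scheduler


@dataclass(frozen=True)
class StageSpec:
    """One stage of the division program.

    The stage evolves under the attraction policy until ``stop`` fires,
    then applies ``divisions`` (simultaneous events) and hands over.
    ``attraction_mode`` is one of ``zero``, ``fitted4``, ``sister_rule``;
    ``motifs`` are single-pair overrides applied after the mode matrix;
    ``extra_delay_steps`` postpones the divisions past the stop point (the
    division-timing perturbation).
    """

    name: str
    stop: StopRule
    divisions: tuple[DivisionSpec, ...] = ()
    attraction_mode: str = "sister_rule"
    motifs: tuple[tuple[tuple[str, str], float], ...] = ()
    extra_delay_steps: int = 0


@dataclass
class ScheduleResult:
    stages: list[StageResult]
    stage_names: list[str]
    embryo: EmbryoState

    @property
    def durations(self) -> dict[str, int]:
        return {n: r.duration_steps for n, r in zip(self.stage_names, self.stages)}


def build_sigma(mode: str, cells: list[str], lineage: Lineage,
                motifs=()) -> AttractionMatrix:
    if mode == "zero":
        m = zero_matrix(cells)
    elif mode == "fitted4":
        m = four_cell_fitted_matrix()
    elif mode == "sister_rule":
        m = default_matrix(cells, lineage)
    elif mode.startswith("uniform:"):
        value = float(mode.split(":", 1)[1])
        m = zero_matrix(cells)
        m = AttractionMatrix({pair: value for pair in m.entries})
    else:
        raise ConfigError(f"unknown attraction mode {mode!r}")
    return apply_motifs(m, motifs)


def stage_scheduler(
    program: list[StageSpec],
    embryo: EmbryoState,
    p: ForceParams,
    d: DynamicsParams,
    *,
    contact_stride: int | None = None,
    contact_threshold_um2: float = 1.0,
) -> ScheduleResult:
    """Run a multi-stage division program.

    Each stage re-derives its attraction matrix from the current cell list
    (sister rule refreshed after every division, then motifs), integrates to
    its stop rule, optionally holds for a timing perturbation, then applies
    the stage's divisions.
    """
    results: list[StageResult] = []
    names: list[str] = []
    for spec in program:
        for div in spec.divisions:
            if div.mother not in embryo.names:
                raise ConfigError(
                    f"stage {spec.name!r}: dividing cell {div.mother} absent "
                    f"(cells: {embryo.names})"
                )
        sigma = build_sigma(
            spec.attraction_mode, embryo.names, Lineage(dict(embryo.lineage)), spec.motifs
        )
        result = run_stage(
            embryo, p, d, sigma, spec.stop,
            contact_stride=contact_stride,
            contact_threshold_um2=contact_threshold_um2,
        )
        if spec.extra_delay_steps > 0:
            _advance(embryo, p, d, sigma, spec.extra_delay_steps)
        for div in spec.divisions:
            embryo = bisect_cell(embryo, div)
        results.append(result)
        names.append(spec.name)
    return ScheduleResult(results, names, embryo)
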