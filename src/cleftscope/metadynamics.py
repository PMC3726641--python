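"""Well-tempered metadynamics on toy potentials.

Bias is a sum of Gaussians deposited along the trajectory with heights
damped by exp(-V/kB*dT), dT = (gamma - 1)*T. Dynamics are overdamped
Euler-Maruyama Langevin steps: the engine validates the bias machinery,
not molecular dynamics. The free-energy estimator is the direct
F = -(gamma/(gamma-1)) V scaling, gauge-fixed so min F = 0 on the grid.

For 1D runs the bias (value and analytic Gaussian-sum force) is cached
incrementally on a fine grid and linearly interpolated between grid
points, which is numerically equivalent to the direct hill sum at the
grid resolution (sigma/5) but O(1) per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import KB, RunError, UsageError
from .model_io import Frame, HillRecord
from .synthetic_data import ToyPotential


@dataclass
class CollectiveVariable:
    """Euclidean distance between the mean positions of two atom groups."""

    name: str
    group_a: list[int]
    group_b: list[int]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("CV groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("CV groups must be disjoint")


@dataclass
class BiasParameters:
    w0: float = 0.1          # initial hill height, kcal/mol
    sigma: float = 0.2       # hill width, A
    pace: float = 1.0        # deposition interval, ps
    bias_factor: float = 10.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.w0 <= 0 or self.sigma <= 0:
            raise ValueError("w0 and sigma must be > 0")
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must be > 1")

    @property
    def delta_t(self) -> float:
        """Well-tempered dT = (gamma - 1) * T, in K."""
        return (self.bias_factor - 1.0) * self.temperature


@dataclass
class WallParameters:
    limit: float = 12.0      # A
    kappa: float = 100.0     # kcal/mol
    exponent: int = 2

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class BiasState:
    """Deposited hills plus the well-tempered parameters."""

    params: BiasParameters
    hills: list[HillRecord] = field(default_factory=list)

    def append(self, hill: HillRecord) -> None:
        if self.hills and hill.time < self.hills[-1].time:
            raise ValueError("hill times must be non-decreasing")
        self.hills.append(hill)

    @property
    def dim(self) -> int:
        return len(self.hills[0].center) if self.hills else 0


def cv_value(frame: Frame, cv: CollectiveVariable) -> float:
    """|mean(group_a positions) - mean(group_b positions)| in A."""
    pa = frame.positions[cv.group_a].mean(axis=0)
    pb = frame.positions[cv.group_b].mean(axis=0)
    return float(np.linalg.norm(pa - pb))


def bias_potential(state: BiasState, s) -> float | np.ndarray:
    """Sum over hills of height * exp(-sum_i (s_i - c_i)^2 / (2 sigma_i^2)).

    ``s`` may be a single CV vector or an (..., dim) array of points.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if not state.hills:
        return 0.0 if s.ndim == 1 else np.zeros(s.shape[:-1])
    dim = state.dim
    if s.shape[-1] != dim:
        raise UsageError(f"CV vector has dim {s.shape[-1]}, hills have dim {dim}")
    centers = np.array([h.center for h in state.hills])   # (n, dim)
    sigmas = np.array([h.sigma for h in state.hills])
    heights = np.array([h.height for h in state.hills])
    diff = s[..., None, :] - centers                       # (..., n, dim)
    expo = np.sum(diff ** 2 / (2.0 * sigmas ** 2), axis=-1)
    v = np.sum(heights * np.exp(-expo), axis=-1)
    return float(v) if v.ndim == 0 else v


def deposit(state: BiasState, s, time: float = 0.0) -> HillRecord:
    """Append a well-tempered hill: w = w0 * exp(-V(s) / (kB * dT)).

    The height never exceeds w0 and strictly decreases on repeated
    deposition at a fixed point.
    """
    p = state.params
    s = np.atleast_1d(np.asarray(s, dtype=float))
    v = bias_potential(state, s) if state.hills else 0.0
    w = p.w0 * math.exp(-float(v) / (KB * p.delta_t))
    hill = HillRecord(time=time, center=s.copy(),
                      sigma=np.full(s.shape, p.sigma),
                      height=w, bias_factor=p.bias_factor)
    state.append(hill)
    return hill


def wall_energy(s, wall: WallParameters) -> float:
    """One-sided wall: 0 below the limit, kappa*(s-limit)^exponent above,
    summed over CV components."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    over = np.clip(s - wall.limit, 0.0, None)
    return float(np.sum(wall.kappa * over ** wall.exponent))


def _wall_force(x: float, wall: WallParameters | None) -> float:
    if wall is None or x <= wall.limit:
        return 0.0
    return -wall.kappa * wall.exponent * (x - wall.limit) ** (wall.exponent - 1)


@dataclass
class MetadRun:
    """Output of a sampler run: recorded CV samples plus the bias state."""

    times: np.ndarray
    samples: np.ndarray     # (n_records, dim)
    state: BiasState
    n_steps: int
    dt: float


def run_wt_metad(potential: ToyPotential,
                 params: BiasParameters | None = None,
                 wall: WallParameters | None = None,
                 n_steps: int = 100_000,
                 dt: float = 0.002,
                 friction: float = 1.0,
                 seed: int = 0,
                 x0: np.ndarray | float | None = None,
                 stride: int = 10,
                 biased: bool = True) -> MetadRun:
    """Overdamped Langevin sampling of a toy potential, optionally biased.

    Hills are deposited every ``pace`` ps of simulated time; generation is
    seed-deterministic. Divergence (non-finite coordinates or escape far
    outside the domain) raises :class:`RunError` with diagnostics.
    """
    params = params or BiasParameters()
    state = BiasState(params=params)
    rng = np.random.default_rng(seed)
    dim = potential.dim
    kt = KB * params.temperature
    noise_scale = math.sqrt(2.0 * kt * dt / friction)
    pace_steps = max(1, int(round(params.pace / dt)))
    lo, hi = potential.domain[:, 0], potential.domain[:, 1]
    escape_lo, escape_hi = lo - 5.0, hi + 5.0

    if x0 is None:
        if dim == 1 and "minima" in potential.reference:
            x = np.array([potential.reference["minima"][0]], dtype=float)
        else:
            x = (lo + hi) / 2.0
    else:
        x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()

    n_rec = n_steps // stride
    samples = np.empty((n_rec, dim))
    times = np.empty(n_rec)

    if dim == 1:
        _run_1d(potential, params, wall, state, n_steps, dt, friction, rng,
                x, stride, biased, samples, times, noise_scale, pace_steps,
                float(escape_lo[0]), float(escape_hi[0]))
    else:
        _run_nd(potential, params, wall, state, n_steps, dt, friction, rng,
                x, stride, biased, samples, times, noise_scale, pace_steps,
                escape_lo, escape_hi)
    return MetadRun(times=times, samples=samples, state=state,
                    n_steps=n_steps, dt=dt)


def _run_1d(potential, params, wall, state, n_steps, dt, friction, rng, x,
            stride, biased, samples, times, noise_scale, pace_steps,
            escape_lo, escape_hi) -> None:
    # incremental grid cache of the Gaussian-sum bias (value + force)
    h_grid = params.sigma / 5.0
    g_lo, g_hi = escape_lo - 1.0, escape_hi + 1.0
    grid = np.arange(g_lo, g_hi + h_grid, h_grid)
    vg = np.zeros_like(grid)
    fg = np.zeros_like(grid)  # bias force = -dV/ds
    inv_h = 1.0 / h_grid
    kb_dt_inv = 1.0 / (KB * params.delta_t)
    sigma2 = params.sigma ** 2

    noise = rng.normal(0.0, noise_scale, size=n_steps)
    xv = float(x[0])
    grad = potential.gradient
    mob = dt / friction

    for step in range(n_steps):
        fi = (xv - g_lo) * inv_h
        i0 = int(fi)
        frac = fi - i0
        f_bias = fg[i0] * (1.0 - frac) + fg[i0 + 1] * frac if biased else 0.0
        f_pot = -float(grad(xv))
        f_wall = _wall_force(xv, wall)
        xv = xv + (f_pot + f_bias + f_wall) * mob + noise[step]
        if not math.isfinite(xv) or xv < escape_lo or xv > escape_hi:
            raise RunError(
                f"run diverged at step {step}: x={xv!r} "
                f"(dt={dt}, friction={friction}; reduce the step size)")
        if biased and (step + 1) % pace_steps == 0:
            fi = (xv - g_lo) * inv_h
            i0 = int(fi)
            frac = fi - i0
            v_here = vg[i0] * (1.0 - frac) + vg[i0 + 1] * frac
            w = params.w0 * math.exp(-v_here * kb_dt_inv)
            state.append(HillRecord(time=(step + 1) * dt, center=[xv],
                                    sigma=[params.sigma], height=w,
                                    bias_factor=params.bias_factor))
            dg = grid - xv
            gauss = w * np.exp(-dg ** 2 / (2.0 * sigma2))
            vg += gauss
            fg += gauss * dg / sigma2
        if (step + 1) % stride == 0:
            r = (step + 1) // stride - 1
            samples[r, 0] = xv
            times[r] = (step + 1) * dt


def _run_nd(potential, params, wall, state, n_steps, dt, friction, rng, x,
            stride, biased, samples, times, noise_scale, pace_steps,
            escape_lo, escape_hi) -> None:
    dim = len(x)
    sigma2 = params.sigma ** 2
    centers: list[np.ndarray] = []
    heights: list[float] = []
    mob = dt / friction
    kb_dt_inv = 1.0 / (KB * params.delta_t)

    def bias_v_f(pt: np.ndarray) -> tuple[float, np.ndarray]:
        if not centers:
            return 0.0, np.zeros(dim)
        c = np.array(centers)
        h = np.array(heights)
        diff = pt - c
        g = h * np.exp(-np.sum(diff ** 2, axis=1) / (2.0 * sigma2))
        v = float(g.sum())
        f = (g[:, None] * diff / sigma2).sum(axis=0)  # -dV/ds
        return v, f

    for step in range(n_steps):
        _, f_bias = bias_v_f(x) if biased else (0.0, np.zeros(dim))
        f_pot = -potential.gradient(x)
        f_wall = np.array([_wall_force(float(x[d]), wall) for d in range(dim)])
        x = x + (f_pot + f_bias + f_wall) * mob \
            + rng.normal(0.0, noise_scale, size=dim)
        if (not np.all(np.isfinite(x))) or np.any(x < escape_lo) or np.any(x > escape_hi):
            raise RunError(f"run diverged at step {step}: x={x!r}")
        if biased and (step + 1) % pace_steps == 0:
            v_here, _ = bias_v_f(x)
            w = params.w0 * math.exp(-v_here * kb_dt_inv)
            centers.append(x.copy())
            heights.append(w)
            state.append(HillRecord(time=(step + 1) * dt, center=x.copy(),
                                    sigma=np.full(dim, params.sigma), height=w,
                                    bias_factor=params.bias_factor))
        if (step + 1) % stride == 0:
            r = (step + 1) // stride - 1
            samples[r] = x
            times[r] = (step + 1) * dt


def reconstruct_fes(state: BiasState, grid: np.ndarray) -> np.ndarray:
    """F(s) = -(gamma/(gamma-1)) V(s) on the grid, shifted so min F = 0.

    ``grid`` is an (n,) array for 1 CV or an (..., dim) mesh for several.
    """
    if not state.hills:
        raise UsageError("cannot reconstruct a free energy from an empty bias")
    gamma = state.params.bias_factor
    grid = np.asarray(grid, dtype=float)
    pts = grid[..., None] if state.dim == 1 and grid.ndim == 1 else grid
    v = bias_potential(state, pts)
    f = -(gamma / (gamma - 1.0)) * np.asarray(v)
    return f - f.min()


def average_profiles(profiles: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Bin-wise mean (re-zeroed at its minimum) and per-bin sd."""
    if not profiles:
        raise UsageError("no profiles to average")
    shapes = {p.shape for p in map(np.asarray, profiles)}
    if len(shapes) > 1:
        raise UsageError(f"profiles on mismatched grids: {shapes}")
    stack = np.stack([np.asarray(p, dtype=float) for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(mean)
    return mean - mean.min(), sd


def project_fes(fes3: np.ndarray, drop_axis: int, temperature: float,
                spacing: float) -> np.ndarray:
    """Boltzmann projection of a 3-CV surface onto the remaining two.

    F2(a,b) = -kT ln sum_c exp(-F3(a,b,c)/kT) * dc, computed with
    log-sum-exp so the result is finite wherever any F3 value is finite;
    re-zeroed at its minimum. Projecting out a separable axis recovers the
    remaining surface exactly.
    """
    from scipy.special import logsumexp

    fes3 = np.asarray(fes3, dtype=float)
    kt = KB * temperature
    lse = logsumexp(-fes3 / kt, axis=drop_axis)
    f2 = -kt * (lse + math.log(spacing))
    return f2 - f2.min()
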