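"""Synthetic phantoms, Q-matrix ensembles, drive ensembles and oracles.

No FDTD solver output ships with this package; everything downstream is
exercised on synthetic data built here.  The phantom field generator is an
analytic surrogate — decaying dipole/loop-like patterns around a lossy
homogeneous cylinder — that is deliberately non-physical but reproduces the
structural features that matter for worst-case SAR analysis: per-channel
fields with smooth phase variation, a tunable dominant-z (single field
component) fraction, rank-<=3 Q-matrices, and a dominant eigenvalue near
the array elements.

``brute_force_max`` is the independent oracle for the trigonometric
maximization: exhaustive evaluation of the cosine-form SAR on a dense phase
grid (global phase fixed at phi_1 = 0) followed by local gradient
refinement.  All pairwise phase differences of a uniform grid lie on the
same grid, so the surface decomposes into 1-D tables indexed by index
differences, which keeps the Nc = 4 case tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .qmodel import (
    ChannelFieldSet,
    DriveVector,
    QMatrix,
    QMatrixSet,
    TissueGrid,
    ValidationError,
    _hermitize,
)
from . import bounds as _bounds
from .trigmax import TrigMaxConfig, sar_gradient, sar_phase_form

__all__ = [
    "PhantomSpec",
    "QEnsembleSpec",
    "DriveEnsemble",
    "generate_phantom_fields",
    "random_q_ensemble",
    "random_drives",
    "brute_force_max",
    "multistart_ascent",
    "benchmark_scenario",
]


# ---------------------------------------------------------------------------
# phantom fields


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic surrogate of a cylindrical transmit array on a lossy phantom.

    Defaults emulate an 8-element dipole-like array around a homogeneous
    tissue cylinder (sigma = 0.5 S/m, rho = 1000 kg/m^3 — muscle-like) with
    1 cm voxels.  ``dominant_z`` in [0, 1] is the power fraction of the
    z-component of each element's E-field (1.0 -> pure Ez -> rank-1
    Q-matrices everywhere); ``decay_length`` the exponential decay of the
    field magnitude away from the element, meters.
    """

    shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size: float = 0.01
    sigma: float = 0.5
    rho: float = 1000.0
    n_channels: int = 8
    geometry: Literal["cylinder", "flat"] = "cylinder"
    element_model: Literal["dipole_like", "loop_like"] = "dipole_like"
    decay_length: float = 0.04
    dominant_z: float = 0.9
    wavelength: float = 0.12
    surface_field: float = 60.0  # V/m per sqrt(W) at the element
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 3:
            raise ValidationError("at least 3 channels are required")
        if self.decay_length <= 0:
            raise ValidationError("decay length must be positive")
        if not (0.0 <= self.dominant_z <= 1.0):
            raise ValidationError("dominant_z must lie in [0, 1]")


def _element_positions(spec: PhantomSpec, extent: np.ndarray) -> np.ndarray:
    """Element centers just outside the phantom."""
    nc = spec.n_channels
    if spec.geometry == "cylinder":
        radius = 0.62 * float(np.hypot(extent[0], extent[1]))
        ang = 2.0 * np.pi * np.arange(nc) / nc
        return np.column_stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.zeros(nc)]
        )
    # flat former above the grid
    xs = np.linspace(-0.4 * extent[0], 0.4 * extent[0], nc)
    return np.column_stack(
        [xs, np.full(nc, 0.7 * extent[1]), np.zeros(nc)]
    )


def generate_phantom_fields(spec: PhantomSpec) -> ChannelFieldSet:
    """Per-channel complex fields on a homogeneous cylindrical phantom.

    Each element produces a field of magnitude ``E0 exp(-d/L)`` with a
    smoothly varying propagation phase ``-2 pi d / wavelength`` (d = distance
    to the element).  The Cartesian split puts ``dominant_z`` of the power
    in Ez and the rest in the transverse plane — radially from the element
    for dipole-like, azimuthally for loop-like elements.  Deterministic for
    a given spec.
    """
    nx, ny, nz = spec.shape
    vs = spec.voxel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * vs
    y = (np.arange(ny) - (ny - 1) / 2.0) * vs
    z = (np.arange(nz) - (nz - 1) / 2.0) * vs
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    extent = np.array([x.max() - x.min(), y.max() - y.min(), z.max() - z.min()]) / 2.0
    extent = np.maximum(extent, vs)

    mask_radius = 0.95 * min(extent[0], extent[1])
    mask = np.hypot(xx, yy) <= mask_radius
    grid = TissueGrid(
        voxel_size=(vs, vs, vs),
        sigma=np.where(mask, spec.sigma, 0.0),
        rho=np.where(mask, spec.rho, 1.2),  # air density outside
        body_mask=mask,
    )

    pos = _element_positions(spec, extent)
    beta = 2.0 * np.pi / spec.wavelength
    fz = np.sqrt(spec.dominant_z)
    ft = np.sqrt(1.0 - spec.dominant_z)

    ex = np.zeros((spec.n_channels, nx, ny, nz), dtype=complex)
    ey = np.zeros_like(ex)
    ez = np.zeros_like(ex)
    for c, p in enumerate(pos):
        dx, dy, dz = xx - p[0], yy - p[1], zz - p[2]
        d = np.sqrt(dx**2 + dy**2 + dz**2)
        mag = spec.surface_field * np.exp(-d / spec.decay_length)
        field = mag * np.exp(-1j * beta * d)
        # transverse unit vector in the xy plane
        dt = np.maximum(np.hypot(dx, dy), 1e-12)
        if spec.element_model == "dipole_like":
            ux, uy = dx / dt, dy / dt  # radial from the element
        else:
            ux, uy = -dy / dt, dx / dt  # azimuthal (loop-like)
        ez[c] = fz * field
        ex[c] = ft * ux * field
        ey[c] = ft * uy * field
    return ChannelFieldSet(grid=grid, ex=ex, ey=ey, ez=ez)


# ---------------------------------------------------------------------------
# random ensembles


@dataclass(frozen=True)
class QEnsembleSpec:
    """Random Hermitian-PSD Q-matrix ensemble of bounded rank.

    Each matrix is a sum of ``rank`` rank-1 outer products of complex
    Gaussian vectors with geometrically decaying weights (ratio
    ``eigenvalue_decay``), scaled so the mean trace is ``scale`` W/kg per W.
    ``diag_dominance`` in [0, 1) concentrates each factor on one random
    channel — this drives the matrix toward diagonal dominance while
    preserving rank <= ``rank`` (an added diagonal would not).
    """

    nc: int = 8
    rank: int = 3
    count: int = 100
    diag_dominance: float = 0.0
    eigenvalue_decay: float = 0.3
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.rank <= 3):
            raise ValidationError("rank must be 1, 2 or 3")
        if not (0.0 <= self.diag_dominance < 1.0):
            raise ValidationError("diag_dominance must lie in [0, 1)")
        if self.count < 1:
            raise ValidationError("count must be >= 1")


def random_q_ensemble(spec: QEnsembleSpec) -> QMatrixSet:
    """Seeded ensemble satisfying every Q-matrix invariant."""
    rng = np.random.default_rng(spec.seed)
    nc, r = spec.nc, spec.rank
    weights = spec.eigenvalue_decay ** np.arange(r)
    entries = np.zeros((spec.count, nc, nc), dtype=complex)
    for i in range(spec.count):
        q = np.zeros((nc, nc), dtype=complex)
        for w in weights:
            v = (rng.standard_normal(nc) + 1j * rng.standard_normal(nc)) / np.sqrt(2)
            if spec.diag_dominance > 0:
                conc = np.full(nc, 1.0 - spec.diag_dominance)
                conc[rng.integers(nc)] += spec.diag_dominance * nc
                v = v * conc
            q += w * np.outer(v.conj(), v)
        entries[i] = q
    entries *= spec.scale / np.mean(np.trace(entries, axis1=1, axis2=2).real)
    return QMatrixSet(entries=entries, averaged=True)


@dataclass
class DriveEnsemble:
    """Stack of random drives: amplitudes (count, Nc) and optional phases."""

    amplitudes: np.ndarray
    phases: np.ndarray | None
    total_power: float

    def __len__(self) -> int:
        return self.amplitudes.shape[0]

    def __iter__(self) -> Iterator[DriveVector]:
        for i in range(len(self)):
            yield DriveVector(
                amplitudes=self.amplitudes[i],
                phases=None if self.phases is None else self.phases[i],
            )

    def __getitem__(self, i: int) -> DriveVector:
        return DriveVector(
            amplitudes=self.amplitudes[i],
            phases=None if self.phases is None else self.phases[i],
        )


def random_drives(
    nc: int,
    count: int,
    total_power: float = 1.0,
    with_phases: bool = True,
    seed: int = 0,
) -> DriveEnsemble:
    """Random drives normalized to ``total_power`` watts.

    Per-channel powers are uniform on the simplex (flat Dirichlet), so
    every power split is equally likely; amplitudes are their square roots
    and phases, when requested, uniform on (-pi, pi].
    """
    if count < 1:
        raise ValidationError("count must be >= 1")
    rng = np.random.default_rng(seed)
    powers = rng.dirichlet(np.ones(nc), size=count) * total_power
    amps = np.sqrt(powers)
    phases = None
    if with_phases:
        phases = rng.uniform(-np.pi, np.pi, size=(count, nc))
    return DriveEnsemble(amplitudes=amps, phases=phases, total_power=total_power)


# ---------------------------------------------------------------------------
# brute-force oracle


def _refine(entries: np.ndarray, a: np.ndarray, phi0: np.ndarray) -> float:
    """Local gradient ascent over the free phases (phi_1 fixed at 0)."""
    nc = a.size

    def neg(p_free):
        phi = np.concatenate([[0.0], p_free])
        return -sar_phase_form(entries, a, phi)

    def neg_grad(p_free):
        phi = np.concatenate([[0.0], p_free])
        return -sar_gradient(entries, a, phi)[1:]

    res = minimize(neg, phi0[1:], jac=neg_grad, method="L-BFGS-B")
    return float(-res.fun)


def brute_force_max(
    q: QMatrix | np.ndarray,
    amplitudes: Sequence[float],
    grid_points: int = 720,
    refine: bool = True,
) -> float:
    """Exhaustive phase-grid maximum of the SAR, the TM method's oracle.

    Fixes the global phase (phi_1 = 0, justified by the global-shift
    invariance) and scans the remaining Nc-1 phases on a uniform grid of
    ``grid_points`` each, optionally polishing the best node with gradient
    ascent.  Cost grows as grid_points^(Nc-1); refuses Nc > 5 and grids
    whose node count exceeds ~5e8 — use :func:`multistart_ascent` there.
    """
    entries = q.entries if isinstance(q, QMatrix) else _hermitize(np.asarray(q))
    a = np.asarray(amplitudes, dtype=float)
    nc = a.size
    if entries.shape != (nc, nc):
        raise ValidationError("amplitudes do not match Q dimension")
    if nc > 5:
        raise ValidationError(
            "brute-force grid is limited to Nc <= 5; use multistart_ascent"
        )
    g = int(grid_points)
    if g < 2:
        raise ValidationError("grid must have at least 2 points per phase")
    if nc >= 3 and float(g) ** (nc - 1) > 5e8:
        raise ValidationError(
            "grid too dense for this channel count; reduce grid_points"
        )

    base = float(np.sum(a**2 * np.real(np.diagonal(entries))))
    if nc == 1:
        return base
    mag = np.abs(entries)
    theta = np.angle(entries)
    b = 2.0 * np.einsum("l,lm,m->lm", a, mag, a)
    step = 2.0 * np.pi / g
    grid = np.arange(g) * step - np.pi

    def pair_table(l: int, m: int) -> np.ndarray:
        # value of the (l, m) cosine term as a function of i_m - i_l (mod g)
        return b[l, m] * np.cos(theta[l, m] + np.arange(g) * step)

    # terms against the fixed channel 0 as functions of the free index
    anchored = [b[0, m] * np.cos(theta[0, m] + grid) for m in range(1, nc)]

    best_val = -np.inf
    best_idx: tuple[int, ...] = ()
    if nc == 2:
        vals = base + anchored[0]
        i = int(np.argmax(vals))
        best_val, best_idx = float(vals[i]), (i,)
    elif nc == 3:
        dif = (np.arange(g)[None, :] - np.arange(g)[:, None]) % g
        m12 = pair_table(1, 2)[dif]
        vals = base + anchored[0][:, None] + anchored[1][None, :] + m12
        i, j = np.unravel_index(int(np.argmax(vals)), vals.shape)
        best_val, best_idx = float(vals[i, j]), (int(i), int(j))
    elif nc == 4:
        dif = (np.arange(g)[None, :] - np.arange(g)[:, None]) % g
        t12 = pair_table(1, 2)[dif]  # [i1, i2]
        t13 = pair_table(1, 3)[dif]  # [i1, i3]
        t23 = pair_table(2, 3)[dif]  # [i2, i3]
        a2, a3, a4 = anchored
        for i1 in range(g):
            rows = a3 + t12[i1]
            cols = a4 + t13[i1]
            vals = rows[:, None] + cols[None, :] + t23
            flat = int(np.argmax(vals))
            v = float(vals.flat[flat]) + base + a2[i1]
            if v > best_val:
                i2, i3 = np.unravel_index(flat, vals.shape)
                best_val, best_idx = v, (i1, int(i2), int(i3))
    else:  # nc == 5
        dif = (np.arange(g)[None, :] - np.arange(g)[:, None]) % g
        tabs = {
            (l, m): pair_table(l, m)[dif] for l in range(1, 5) for m in range(l + 1, 5)
        }
        a2, a3, a4, a5 = anchored
        for i1 in range(g):
            for i2 in range(g):
                rows = a4 + tabs[(1, 3)][i1] + tabs[(2, 3)][i2]
                cols = a5 + tabs[(1, 4)][i1] + tabs[(2, 4)][i2]
                vals = rows[:, None] + cols[None, :] + tabs[(3, 4)]
                flat = int(np.argmax(vals))
                v = float(vals.flat[flat]) + base + a2[i1] + a3[i2]
                if v > best_val:
                    i3, i4 = np.unravel_index(flat, vals.shape)
                    best_val, best_idx = v, (i1, i2, int(i3), int(i4))

    if not refine:
        return best_val
    phi0 = np.concatenate([[0.0], grid[list(best_idx)]])
    return max(best_val, _refine(entries, a, phi0))


def multistart_ascent(
    q: QMatrix | np.ndarray,
    amplitudes: Sequence[float],
    n_starts: int = 32,
    seed: int = 0,
) -> float:
    """Gradient-ascent oracle from seeded random phase starts."""
    entries = q.entries if isinstance(q, QMatrix) else _hermitize(np.asarray(q))
    a = np.asarray(amplitudes, dtype=float)
    rng = np.random.default_rng(seed)
    best = -np.inf
    for _ in range(n_starts):
        phi0 = np.concatenate([[0.0], rng.uniform(-np.pi, np.pi, a.size - 1)])
        best = max(best, _refine(entries, a, phi0))
    return best


# ---------------------------------------------------------------------------
# end-to-end benchmark


def benchmark_scenario(
    qset: QMatrixSet | "VOPSet",  # noqa: F821 - VOPSet accepted duck-typed
    n_drives: int,
    methods: Sequence[str] = ("tm", "rp", "tp", "lb", "ub"),
    seed: int = 0,
    config: TrigMaxConfig | None = None,
    model: "_bounds.RPModel | None" = None,
    total_power: float = 1.0,
    calibration_samples: int = 100,
):
    """Monte-Carlo comparison of all estimators on random drives.

    Generates ``n_drives`` seeded random drives (amplitudes and phases),
    evaluates the requested estimators and returns the
    :class:`~trigsar.bounds.BoundsReport`.  A VOP set is evaluated through
    its augmented matrices (overestimation term included).  When the RP
    method is requested without a calibrated model, one is calibrated here
    from ``calibration_samples`` amplitude draws (seed derived from
    ``seed``).
    """
    if not methods:
        raise ValidationError("at least one method must be requested")
    if hasattr(qset, "augmented_qmatrixset"):
        qset = qset.augmented_qmatrixset()
    ensemble = random_drives(
        qset.n_channels, n_drives, total_power=total_power, with_phases=True, seed=seed
    )
    if "rp" in methods and model is None:
        model = _bounds.calibrate_rp(
            qset, n_samples=calibration_samples, seed=seed + 1, config=config
        )
    report = _bounds.compare_methods(
        qset, list(ensemble), model=model, config=config, methods=methods
    )
    report.seed = seed
    report.meta.update(n_drives=n_drives, total_power=total_power)
    return report
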