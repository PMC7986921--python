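"""Voxelwise Q-matrix model of local SAR for multi-channel transmit arrays.

For a transmit array with ``Nc`` channels driven by the complex vector
``s`` (entries in sqrt(W), so ``||s||^2`` is the total transmit power), the
local SAR in a voxel is the Hermitian quadratic form ``s† Q s``.  ``Q`` is
assembled from the per-channel electric-field maps and the tissue
conductivity/density, one rank-1 term per Cartesian field component, so
``rank(Q) <= 3`` regardless of the channel count.  Regulatory limits apply
to SAR averaged over a region containing 10 g of tissue, so the raw
matrices are mass-averaged over a cube per voxel before any peak search.

Units throughout: fields in V/m per sqrt(W) of channel excitation,
conductivity in S/m, density in kg/m^3, Q entries in W/kg per W, SAR in
W/kg, positions in meters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: relative tolerance on the Hermitian-asymmetry norm of an incoming matrix
HERMITIAN_RTOL = 1e-8
#: eigenvalues below RANK_RTOL * lambda_max count as numerically zero
RANK_RTOL = 1e-10


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class TissueGrid:
    """Voxel grid of tissue electrical/mass properties.

    Parameters
    ----------
    voxel_size : 3-tuple of float
        Edge lengths of a voxel along (x, y, z), meters.
    sigma : ndarray, shape (nx, ny, nz)
        Electrical conductivity, S/m.  Non-negative.
    rho : ndarray, shape (nx, ny, nz)
        Mass density, kg/m^3.  Strictly positive on ``body_mask``.
    body_mask : bool ndarray, shape (nx, ny, nz)
        True for tissue voxels; air voxels are excluded from SAR.
    """

    voxel_size: tuple[float, float, float]
    sigma: np.ndarray
    rho: np.ndarray
    body_mask: np.ndarray

    def __post_init__(self):
        sigma = np.asarray(self.sigma, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        mask = np.asarray(self.body_mask, dtype=bool)
        if sigma.shape != rho.shape or sigma.shape != mask.shape:
            raise ValidationError("sigma, rho and body_mask must share one shape")
        if sigma.ndim != 3:
            raise ValidationError("tissue maps must be 3-D (nx, ny, nz)")
        if np.any(sigma < 0):
            raise ValidationError("conductivity must be non-negative")
        if np.any(rho[mask] <= 0):
            raise ValidationError("density must be positive on the body mask")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError("voxel_size must be three positive lengths")
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "body_mask", mask)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sigma.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, m^3."""
        return self.voxel_size[0] * self.voxel_size[1] * self.voxel_size[2]

    def voxel_mass(self) -> np.ndarray:
        """Tissue mass per voxel, kg; zero outside the body mask."""
        return np.where(self.body_mask, self.rho, 0.0) * self.voxel_volume


@dataclass(frozen=True)
class ChannelFieldSet:
    """Per-channel complex E-field maps on a tissue grid.

    ``ex``, ``ey``, ``ez`` have shape (Nc, nx, ny, nz) and hold the field a
    unit (1 W) excitation of each channel produces, V/m.
    """

    grid: TissueGrid
    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray

    def __post_init__(self):
        arrays = []
        for name in ("ex", "ey", "ez"):
            arr = np.asarray(getattr(self, name), dtype=complex)
            arrays.append(arr)
            object.__setattr__(self, name, arr)
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValidationError("ex, ey, ez must share one shape")
        shape = arrays[0].shape
        if len(shape) != 4 or shape[1:] != self.grid.shape:
            raise ValidationError(
                "field arrays must be (Nc, nx, ny, nz) matching the grid"
            )
        if shape[0] < 3:
            raise ValidationError("at least 3 channels are required")

    @property
    def n_channels(self) -> int:
        return self.ex.shape[0]


def _hermitize(entries: np.ndarray, rtol: float = HERMITIAN_RTOL) -> np.ndarray:
    """Symmetrize as (Q + Q†)/2 after checking the asymmetry is numerical noise."""
    entries = np.asarray(entries, dtype=complex)
    if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
        raise ValidationError("Q must be a square matrix")
    norm = np.linalg.norm(entries)
    asym = np.linalg.norm(entries - entries.conj().T)
    if norm > 0 and asym > rtol * norm:
        raise ValidationError(
            f"matrix is not Hermitian: asymmetry {asym:.3e} exceeds "
            f"{rtol:.1e} * ||Q|| = {rtol * norm:.3e}"
        )
    return 0.5 * (entries + entries.conj().T)


@dataclass(frozen=True)
class EigenInfo:
    """Spectrum diagnostics of a Q-matrix.

    ``eigenvalues`` sorted descending; ``dominant_fraction`` is
    lambda_1 / sum(lambda), the share of worst-case power the leading
    eigenmode carries; ``eigenvector_phases`` are the phases psi_n of the
    dominant eigenvector, normalized so the first non-negligible component
    has phase zero.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    dominant_fraction: float
    eigenvector_phases: np.ndarray

    @property
    def rank(self) -> int:
        """Count of eigenvalues above RANK_RTOL * lambda_max."""
        lmax = self.eigenvalues[0]
        if lmax <= 0:
            return 0
        return int(np.sum(self.eigenvalues > RANK_RTOL * lmax))


class QMatrix:
    """Hermitian PSD matrix mapping a drive vector to local SAR (W/kg per W).

    Incoming entries are symmetrized as ``(Q + Q†)/2`` provided their
    asymmetry norm is at most ``1e-8 * ||Q||``; larger asymmetry is rejected.
    """

    __slots__ = ("entries", "_eigen")

    def __init__(self, entries: np.ndarray):
        self.entries = _hermitize(entries)
        self._eigen: EigenInfo | None = None

    @property
    def n_channels(self) -> int:
        return self.entries.shape[0]

    @property
    def magnitude(self) -> np.ndarray:
        """|Q_nm| entrywise."""
        return np.abs(self.entries)

    @property
    def phase(self) -> np.ndarray:
        """Entry phases theta_nm = arg(Q_nm); antisymmetric for Hermitian Q."""
        return np.angle(self.entries)

    def eigen_info(self) -> EigenInfo:
        """Cached eigendecomposition; see :func:`eigen_info`."""
        if self._eigen is None:
            self._eigen = eigen_info(self)
        return self._eigen

    def validate_psd(self, rtol: float = RANK_RTOL) -> None:
        """Raise if the minimum eigenvalue is below ``-rtol * lambda_max``."""
        w = np.linalg.eigvalsh(self.entries)
        lmax = max(w[-1], 0.0)
        if w[0] < -rtol * max(lmax, np.finfo(float).tiny):
            raise ValidationError(
                f"matrix is not PSD: min eigenvalue {w[0]:.3e} "
                f"vs lambda_max {lmax:.3e}"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"QMatrix(Nc={self.n_channels})"


@dataclass
class QMatrixSet:
    """Collection of Q-matrices indexed by voxel.

    ``entries`` has shape (Nv, Nc, Nc); ``voxel_index`` (Nv, 3) holds the
    integer grid index of each matrix (0-based, axes x, y, z).  ``averaged``
    distinguishes raw from 10g-averaged sets.  ``cube_side`` optionally
    records the averaging-cube side (voxels) used at each voxel.
    """

    entries: np.ndarray
    voxel_index: np.ndarray | None = None
    averaged: bool = False
    labels: Sequence[str] | None = None
    cube_side: np.ndarray | None = None

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=complex)
        if self.entries.ndim != 3 or self.entries.shape[1] != self.entries.shape[2]:
            raise ValidationError("entries must have shape (Nv, Nc, Nc)")
        if len(self) == 0:
            raise ValidationError("a Q-matrix set must be non-empty")
        if self.voxel_index is None:
            self.voxel_index = np.column_stack(
                [np.arange(len(self)), np.zeros((len(self), 2), dtype=int)]
            )
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.voxel_index.shape != (len(self), 3):
            raise ValidationError("voxel_index must have shape (Nv, 3)")
        if len(np.unique(self.voxel_index, axis=0)) != len(self):
            raise ValidationError("voxel indices must be unique")

    def __len__(self) -> int:
        return self.entries.shape[0]

    @property
    def n_channels(self) -> int:
        return self.entries.shape[1]

    def __iter__(self) -> Iterator[QMatrix]:
        for i in range(len(self)):
            yield QMatrix(self.entries[i])

    def __getitem__(self, i: int) -> QMatrix:
        return QMatrix(self.entries[i])

    def validate(self, rtol: float = RANK_RTOL) -> None:
        """Check Hermiticity and PSD of every matrix; raise listing offenders."""
        bad: list[int] = []
        for i in range(len(self)):
            q = self.entries[i]
            norm = np.linalg.norm(q)
            if norm > 0 and np.linalg.norm(q - q.conj().T) > HERMITIAN_RTOL * norm:
                bad.append(i)
                continue
            w = np.linalg.eigvalsh(0.5 * (q + q.conj().T))
            if w[0] < -rtol * max(w[-1], np.finfo(float).tiny):
                bad.append(i)
        if bad:
            raise ValidationError(
                f"{len(bad)} matrices fail Hermitian/PSD validation "
                f"(first offenders: {bad[:10]})"
            )

    def max_eigenvalues(self) -> np.ndarray:
        """lambda_max of every matrix (vectorized eigh)."""
        return np.linalg.eigvalsh(self.entries)[:, -1]


@dataclass(frozen=True)
class DriveVector:
    """Per-channel drive: amplitudes in sqrt(W) and optional phases in rad."""

    amplitudes: np.ndarray
    phases: np.ndarray | None = None

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.ndim != 1:
            raise ValidationError("amplitudes must be a 1-D vector")
        if not np.all(np.isfinite(amps)) or np.any(amps < 0):
            raise ValidationError("amplitudes must be finite and non-negative")
        object.__setattr__(self, "amplitudes", amps)
        if self.phases is not None:
            ph = np.asarray(self.phases, dtype=float)
            if ph.shape != amps.shape:
                raise ValidationError("phases must match amplitudes in length")
            object.__setattr__(self, "phases", ph)

    @property
    def n_channels(self) -> int:
        return self.amplitudes.size

    @property
    def total_power(self) -> float:
        """P_tot = sum s_n^2, W."""
        return float(np.sum(self.amplitudes**2))

    def as_complex(self) -> np.ndarray:
        """s_n e^{i phi_n}; requires phases."""
        if self.phases is None:
            raise ValidationError("drive has no phases (amplitude-only setting)")
        return self.amplitudes * np.exp(1j * self.phases)


# ---------------------------------------------------------------------------
# operations


def build_q(fields: ChannelFieldSet, voxel: tuple[int, int, int]) -> QMatrix:
    """Assemble the Q-matrix of one voxel from per-channel fields.

    Q = (sigma / 2 rho) * (Ex† Ex + Ey† Ey + Ez† Ez), one rank-1 outer
    product per Cartesian component, hence Hermitian PSD with rank <= 3.
    """
    i, j, k = voxel
    grid = fields.grid
    if not grid.body_mask[i, j, k]:
        raise ValidationError(f"voxel {voxel} is outside the body mask")
    rho = grid.rho[i, j, k]
    if rho <= 0:
        raise ValidationError(f"voxel {voxel} has non-positive density")
    coeff = grid.sigma[i, j, k] / (2.0 * rho)
    q = np.zeros((fields.n_channels, fields.n_channels), dtype=complex)
    for comp in (fields.ex, fields.ey, fields.ez):
        e = comp[:, i, j, k]
        q += np.outer(e.conj(), e)
    return QMatrix(coeff * q)


def build_q_field(fields: ChannelFieldSet) -> QMatrixSet:
    """Raw (unaveraged) Q-matrix at every body voxel.

    Vectorized over the grid; returns a set ordered by C-order scan of the
    body mask, with voxel indices attached.
    """
    grid = fields.grid
    mask = grid.body_mask
    idx = np.argwhere(mask)
    coeff = grid.sigma[mask] / (2.0 * grid.rho[mask])  # (Nv,)
    nv, nc = idx.shape[0], fields.n_channels
    q = np.zeros((nv, nc, nc), dtype=complex)
    for comp in (fields.ex, fields.ey, fields.ez):
        e = comp[:, mask].T  # (Nv, Nc)
        q += e[:, :, None].conj() * e[:, None, :]
    q *= coeff[:, None, None]
    return QMatrixSet(entries=q, voxel_index=idx, averaged=False)


def eigen_info(q: QMatrix | np.ndarray) -> EigenInfo:
    """Sorted spectrum, dominant-eigenvector phases and dominant fraction."""
    entries = q.entries if isinstance(q, QMatrix) else _hermitize(q)
    w, v = np.linalg.eigh(entries)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    total = float(np.sum(np.clip(w, 0.0, None)))
    dom = float(w[0] / total) if total > 0 else 0.0
    vec = v[:, 0]
    # fix the global phase: first non-negligible component made real positive
    mags = np.abs(vec)
    ref = int(np.argmax(mags > 1e-12 * (mags.max() or 1.0)))
    if mags[ref] > 0:
        vec = vec * np.exp(-1j * np.angle(vec[ref]))
    psi = np.angle(vec)
    return EigenInfo(
        eigenvalues=w, eigenvectors=v, dominant_fraction=dom, eigenvector_phases=psi
    )


def sar(q: QMatrix, drive: DriveVector) -> float:
    """SAR = Re(s† Q s) for a drive with phases, W/kg.

    A tiny negative value from rounding is clamped to zero; anything below
    ``-1e-10 * lambda_max * P_tot`` raises.
    """
    s = drive.as_complex()
    if s.size != q.n_channels:
        raise ValidationError(
            f"drive has {s.size} channels, Q has {q.n_channels}"
        )
    val = float(np.real(s.conj() @ q.entries @ s))
    if val < 0:
        scale = float(np.linalg.norm(q.entries)) * drive.total_power
        if val < -RANK_RTOL * max(scale, np.finfo(float).tiny):
            raise ValidationError(f"negative SAR {val:.3e} beyond tolerance")
        val = 0.0
    return val


def required_cube_side(
    grid: TissueGrid, voxel: tuple[int, int, int], target_mass_kg: float
) -> int | None:
    """Smallest odd cube side (voxels) centered on ``voxel`` enclosing
    ``target_mass_kg`` of tissue; cube clipped at grid edges.  None when the
    target is unreachable even with the largest clipped cube."""
    mass = grid.voxel_mass()
    nx, ny, nz = grid.shape
    i, j, k = voxel
    max_half = max(nx, ny, nz)  # generous upper bound on the half-width
    for half in range(0, max_half + 1):
        sl = tuple(
            slice(max(c - half, 0), min(c + half + 1, n))
            for c, n in zip((i, j, k), (nx, ny, nz))
        )
        if mass[sl].sum() >= target_mass_kg:
            return 2 * half + 1
        if (
            sl[0] == slice(0, nx)
            and sl[1] == slice(0, ny)
            and sl[2] == slice(0, nz)
        ):
            break
    return None


def average_10g(
    qfield: QMatrixSet, grid: TissueGrid, target_mass: float = 10.0
) -> QMatrixSet:
    """Mass-weighted cube averaging of a raw Q field (10 g by default).

    For each body voxel the smallest odd-sided cube centered there whose
    enclosed tissue mass reaches ``target_mass`` grams is found (clipped at
    grid edges); entries are averaged with voxel-mass weights over the body
    voxels in the cube.  Voxels whose largest clipped cube never reaches the
    target are excluded with a warning.
    """
    if qfield.averaged:
        raise ValidationError("input set is already averaged")
    target_kg = target_mass * 1e-3
    mass = grid.voxel_mass()
    nx, ny, nz = grid.shape
    nc = qfield.n_channels

    # raw Q arranged on the grid for slicing, weighted by mass
    qgrid = np.zeros((nx, ny, nz, nc, nc), dtype=complex)
    on_grid = np.zeros((nx, ny, nz), dtype=bool)
    for n, (i, j, k) in enumerate(qfield.voxel_index):
        qgrid[i, j, k] = qfield.entries[n]
        on_grid[i, j, k] = True
    if not np.all(on_grid[grid.body_mask]):
        raise ValidationError("raw Q must be defined on every body voxel")
    mq = qgrid * mass[..., None, None]

    out: list[np.ndarray] = []
    kept: list[np.ndarray] = []
    sides: list[int] = []
    excluded = 0
    for i, j, k in qfield.voxel_index:
        side = required_cube_side(grid, (i, j, k), target_kg)
        if side is None:
            excluded += 1
            continue
        half = side // 2
        sl = tuple(
            slice(max(c - half, 0), min(c + half + 1, n))
            for c, n in zip((i, j, k), (nx, ny, nz))
        )
        m = mass[sl].sum()
        avg = mq[sl].sum(axis=(0, 1, 2)) / m
        out.append(0.5 * (avg + avg.conj().T))
        kept.append(np.array([i, j, k]))
        sides.append(side)
    if excluded:
        logger.warning(
            "10g averaging excluded %d voxels whose clipped cube never "
            "reaches %.1f g of tissue",
            excluded,
            target_mass,
        )
    if not out:
        raise ValidationError("no voxel reaches the target averaging mass")
    return QMatrixSet(
        entries=np.array(out),
        voxel_index=np.array(kept),
        averaged=True,
        cube_side=np.array(sides),
    )
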