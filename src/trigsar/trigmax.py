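"""Phase-only worst-case SAR maximization by trigonometric fixed-point iteration.

For fixed channel amplitudes ``s_n`` the local SAR of a Hermitian Q-matrix
is a linear combination of cosines of phase differences,

    SAR(phi) = sum_n s_n^2 Q_nn
             + sum_{n<m} 2 s_n |Q_nm| s_m cos(-phi_n + theta_nm + phi_m),

so every local maximum over the phases is a periodic copy of the global
maximum.  Setting each gradient component to zero yields, per channel, a
closed-form update ``phi_l = atan2(Y_l, X_l)`` whose fixed point is a
stationary phase set; iterating it converges to the maximizing phases in a
handful of sweeps.  The peak of the per-voxel maxima over a Q-matrix set is
the worst-case pSAR for that amplitude setting — the safety-relevant
quantity when phase monitoring is absent or untrusted.

The coordinate update in complex form: with ``w_m = s_m e^{i phi_m}`` and
``c_l = sum_{m != l} Q_lm w_m``, one has ``X_l + i Y_l = 2 s_l c_l``, so the
update is ``phi_l <- arg(c_l)`` — the exact 1-D maximizer of the sinusoid
along coordinate ``l``.  Both forms are implemented; they are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .qmodel import DriveVector, QMatrix, QMatrixSet, ValidationError, _hermitize

__all__ = [
    "TrigMaxConfig",
    "TrigMaxState",
    "PhaseMaxResult",
    "WorstCaseResult",
    "sar_phase_form",
    "sar_gradient",
    "sar_hessian",
    "coordinate_update",
    "maximize_phases",
    "worst_case_psar",
    "time_integrated_worst_case",
]


@dataclass(frozen=True)
class TrigMaxConfig:
    """Solver settings.

    epsilon : float
        Absolute SAR-change stopping tolerance, W/kg (default 1e-6).
    epsilon_rel : float
        Additional relative SAR-change criterion |dSAR|/SAR.
    grad_tol : float or None
        When set, also require the gradient infinity norm to fall below
        this value before stopping — guarantees stationarity certificates
        tighter than the SAR-change criterion alone can (the SAR error is
        quadratic in the phase error near a maximum).
    sweep_scheme : {"jacobi", "gauss_seidel"}
        "jacobi" updates all channels from the previous sweep's phases (the
        reference pseudocode); "gauss_seidel" uses already-updated phases
        within the sweep, which makes each sweep a monotone block-coordinate
        ascent.  Both share fixed points.
    initial_phases : array or None
        Start phases (default all zeros).
    perturb_scale, max_escapes, seed
        Escape from non-maximum stationary points (possible only from
        measure-zero starts): phases are perturbed by ``perturb_scale``
        radians drawn from a seeded generator when the iteration is
        stationary but the phase Hessian has positive curvature.
    """

    epsilon: float = 1e-6
    epsilon_rel: float = 1e-12
    max_iterations: int = 500
    sweep_scheme: Literal["jacobi", "gauss_seidel"] = "jacobi"
    initial_phases: np.ndarray | None = None
    grad_tol: float | None = None
    perturb_scale: float = 1e-3
    max_escapes: int = 5
    seed: int = 0
    #: sweeps after which a still-unconverged jacobi iteration falls back to
    #: gauss_seidel (simultaneous updates can orbit without settling; the
    #: in-place sweep is a monotone coordinate ascent and cannot)
    jacobi_fallback_after: int = 100

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if self.sweep_scheme not in ("jacobi", "gauss_seidel"):
            raise ValidationError(f"unknown sweep scheme {self.sweep_scheme!r}")


# ---------------------------------------------------------------------------
# scalar/cosine-form evaluation paths (independent of the quadratic form)


def _as_entries(q: QMatrix | np.ndarray) -> np.ndarray:
    return q.entries if isinstance(q, QMatrix) else _hermitize(np.asarray(q))


def _check_sizes(entries: np.ndarray, amplitudes: np.ndarray, phases=None):
    nc = entries.shape[-1]
    if amplitudes.shape[-1] != nc:
        raise ValidationError("amplitude vector does not match Q dimension")
    if phases is not None and phases.shape[-1] != nc:
        raise ValidationError("phase vector does not match Q dimension")
    if np.any(amplitudes < 0):
        raise ValidationError("amplitudes must be non-negative")


def sar_phase_form(
    q: QMatrix | np.ndarray, amplitudes: Sequence[float], phases: Sequence[float]
) -> float:
    """SAR evaluated from the cosine double sum (not the quadratic form).

    Returns sum_n s_n^2 Q_nn + sum_{n<m} 2 s_n |Q_nm| s_m
    cos(-phi_n + theta_nm + phi_m).
    """
    entries = _as_entries(q)
    a = np.asarray(amplitudes, dtype=float)
    phi = np.asarray(phases, dtype=float)
    _check_sizes(entries, a, phi)
    mag = np.abs(entries)
    theta = np.angle(entries)
    val = float(np.sum(a**2 * np.real(np.diagonal(entries))))
    nc = entries.shape[0]
    iu, ju = np.triu_indices(nc, k=1)
    val += float(
        np.sum(
            2.0
            * a[iu]
            * mag[iu, ju]
            * a[ju]
            * np.cos(-phi[iu] + theta[iu, ju] + phi[ju])
        )
    )
    return val


def _pair_tables(entries: np.ndarray, a: np.ndarray):
    """B_lm = 2 s_l |Q_lm| s_m (zero diagonal) and theta_lm."""
    mag = np.abs(entries)
    b = 2.0 * np.einsum("l,lm,m->lm", a, mag, a)
    np.fill_diagonal(b, 0.0)
    return b, np.angle(entries)


def sar_gradient(
    q: QMatrix | np.ndarray, amplitudes: Sequence[float], phases: Sequence[float]
) -> np.ndarray:
    """Analytic gradient of the cosine form w.r.t. each phase, W/kg per rad.

    grad_l = sum_{m != l} B_lm sin(-phi_l + theta_lm + phi_m).
    """
    entries = _as_entries(q)
    a = np.asarray(amplitudes, dtype=float)
    phi = np.asarray(phases, dtype=float)
    _check_sizes(entries, a, phi)
    b, theta = _pair_tables(entries, a)
    g = theta + phi[None, :] - phi[:, None]
    return np.sum(b * np.sin(g), axis=1)


def sar_hessian(
    q: QMatrix | np.ndarray, amplitudes: Sequence[float], phases: Sequence[float]
) -> np.ndarray:
    """Phase Hessian; always singular along the all-ones direction (global
    phase invariance), negative semidefinite at a maximum."""
    entries = _as_entries(q)
    a = np.asarray(amplitudes, dtype=float)
    phi = np.asarray(phases, dtype=float)
    _check_sizes(entries, a, phi)
    b, theta = _pair_tables(entries, a)
    c = b * np.cos(theta + phi[None, :] - phi[:, None])
    return c - np.diag(np.sum(c, axis=1))


# ---------------------------------------------------------------------------
# coefficient-form state (the literal A_x / A_y / Y_l / X_l construction)


@dataclass
class TrigMaxState:
    """Precomputed update coefficients and iteration history for one matrix.

    ``a_x[n, l] = 2 s_n |Q_nl| s_l cos(theta_nl)`` (symmetric) and
    ``a_y[n, l] = 2 s_n |Q_nl| s_l sin(theta_nl)`` (antisymmetric).
    """

    a_x: np.ndarray
    a_y: np.ndarray
    amplitudes: np.ndarray
    entries: np.ndarray
    degenerate_channels: list[int] = field(default_factory=list)
    phase_history: list[np.ndarray] = field(default_factory=list)
    sar_history: list[float] = field(default_factory=list)

    @classmethod
    def from_matrix(
        cls, q: QMatrix | np.ndarray, amplitudes: Sequence[float]
    ) -> "TrigMaxState":
        entries = _as_entries(q)
        a = np.asarray(amplitudes, dtype=float)
        _check_sizes(entries, a)
        b, theta = _pair_tables(entries, a)
        return cls(
            a_x=b * np.cos(theta), a_y=b * np.sin(theta), amplitudes=a, entries=entries
        )

    def update_terms(self, phases: np.ndarray, l: int) -> tuple[float, float]:
        """(Y_l, X_l) of the stationary-equation rearrangement."""
        phi = np.asarray(phases, dtype=float)
        nc = self.amplitudes.size
        y = 0.0
        x = 0.0
        for m in range(l + 1, nc):
            y += self.a_y[l, m] * np.cos(phi[m]) + self.a_x[l, m] * np.sin(phi[m])
            x += -self.a_y[l, m] * np.sin(phi[m]) + self.a_x[l, m] * np.cos(phi[m])
        for n in range(l):
            y -= self.a_y[n, l] * np.cos(phi[n]) - self.a_x[n, l] * np.sin(phi[n])
            x += self.a_y[n, l] * np.sin(phi[n]) + self.a_x[n, l] * np.cos(phi[n])
        return float(y), float(x)


def coordinate_update(state: TrigMaxState, phases: Sequence[float], l: int) -> float:
    """Exact 1-D maximizer of SAR along phase coordinate ``l``.

    Returns ``atan2(Y_l, X_l)``.  When both terms vanish (zero-amplitude or
    fully decoupled channel) the coordinate does not affect SAR; the
    previous phase is kept and the channel recorded as degenerate.
    """
    phi = np.asarray(phases, dtype=float)
    y, x = state.update_terms(phi, l)
    scale = np.abs(state.a_x).max() + np.abs(state.a_y).max()
    if scale == 0.0 or np.hypot(y, x) <= 1e-14 * scale:
        if l not in state.degenerate_channels:
            state.degenerate_channels.append(l)
        return float(phi[l])
    return float(np.arctan2(y, x))


# ---------------------------------------------------------------------------
# batched fixed-point driver


def _batch_sar(entries: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Re(w† Q w) for stacked matrices (..., Nc, Nc) and drives (..., Nc)."""
    return np.real(np.einsum("...l,...lm,...m->...", w.conj(), entries, w))


def _batch_grad(entries: np.ndarray, a: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gradient 2 Im(conj(w_l) c_l) for stacked matrices."""
    w = a * np.exp(1j * phi)
    c = np.einsum("...lm,...m->...l", entries, w)
    c -= np.einsum("...ll->...l", entries) * w
    return 2.0 * np.imag(w.conj() * c)


def _sweep(
    entries: np.ndarray, a: np.ndarray, phi: np.ndarray, scheme: str
) -> np.ndarray:
    """One full sweep of phase updates over stacked matrices (Nv, Nc, Nc)."""
    active = a > 0
    if scheme == "jacobi":
        w = a * np.exp(1j * phi)
        c = np.einsum("...lm,...m->...l", entries, w)
        c -= np.einsum("...ll->...l", entries) * w
        new = np.where((np.abs(c) > 0) & active, np.angle(c), phi)
        return new
    # gauss_seidel: use already-updated phases within the sweep
    phi = phi.copy()
    w = a * np.exp(1j * phi)
    nc = entries.shape[-1]
    for l in range(nc):
        if not active[l]:
            continue
        c = np.einsum("...m,...m->...", entries[..., l, :], w)
        c = c - entries[..., l, l] * w[..., l]
        upd = np.abs(c) > 0
        phi[..., l] = np.where(upd, np.angle(c), phi[..., l])
        w[..., l] = a[l] * np.exp(1j * phi[..., l])
    return phi


def _normalize_phases(phi: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Remove the global-phase degeneracy: first driven channel gets phase 0,
    undriven channels report 0, everything wrapped to (-pi, pi]."""
    active = a > 0
    if not np.any(active):
        return np.zeros_like(phi)
    ref = int(np.argmax(active))
    out = phi - phi[..., ref : ref + 1]
    out = np.angle(np.exp(1j * out))
    out[..., ~active] = 0.0
    return out


@dataclass
class PhaseMaxResult:
    """Maximizing phases and diagnostics for a single Q-matrix."""

    phases: np.ndarray
    max_sar: float
    iterations: int
    converged: bool
    sar_history: np.ndarray
    grad_inf_norm: float
    n_escapes: int = 0

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PhaseMaxResult(max_sar={self.max_sar:.6g}, "
            f"iterations={self.iterations}, converged={self.converged})"
        )


@dataclass
class WorstCaseResult:
    """Per-matrix worst-case SAR over a set and its peak (pSAR_TM)."""

    max_sar: np.ndarray  # (Nv,) W/kg
    phases: np.ndarray  # (Nv, Nc) rad
    iterations: np.ndarray
    converged: np.ndarray
    amplitudes: np.ndarray
    peak_sar: float
    argmax: int
    peak_voxel: np.ndarray | None = None

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"WorstCaseResult(peak_sar={self.peak_sar:.6g} W/kg, "
            f"argmax={self.argmax}, n={len(self.max_sar)})"
        )


def _run_fixed_point(
    entries: np.ndarray,
    a: np.ndarray,
    config: TrigMaxConfig,
    record_history: bool = False,
):
    """Fixed-point iteration over stacked matrices (Nv, Nc, Nc).

    Returns (phases, sar, iterations, converged, histories) with best-seen
    SAR/phases retained per matrix so the result never falls below the
    initial-phase SAR.
    """
    nv, nc = entries.shape[0], entries.shape[-1]
    if nc < 2:
        raise ValidationError("at least two channels are required")
    if not np.any(a > 0):
        raise ValidationError("amplitudes must not all be zero")
    if config.initial_phases is not None:
        phi0 = np.asarray(config.initial_phases, dtype=float)
        if phi0.shape[-1] != nc:
            raise ValidationError("initial phases do not match Nc")
        phi = np.broadcast_to(phi0, (nv, nc)).astype(float).copy()
    else:
        phi = np.zeros((nv, nc))

    rng = np.random.default_rng(config.seed)
    sar = _batch_sar(entries, a * np.exp(1j * phi))
    best_sar = sar.copy()
    best_phi = phi.copy()
    histories = [[float(s)] for s in sar] if record_history else None

    iterations = np.zeros(nv, dtype=int)
    converged = np.zeros(nv, dtype=bool)
    escapes = np.zeros(nv, dtype=int)
    active = np.ones(nv, dtype=bool)
    # per-matrix sweep scheme; a simultaneous (jacobi) iteration can fall
    # into a 2-cycle between symmetric phase sets (the SAR change vanishes
    # while the gradient does not) — such matrices are switched to
    # gauss_seidel sweeps, which ascend monotonically and cannot cycle
    use_gs = np.full(nv, config.sweep_scheme == "gauss_seidel")
    # gradient scale per matrix: every gradient entry is bounded by the
    # magnitude-sum of the off-diagonal cosine coefficients
    babs = 2.0 * np.einsum("l,...lm,m->...lm", a, np.abs(entries), a)
    for l in range(nc):
        babs[..., l, l] = 0.0
    gscale = np.maximum(babs.sum(axis=(-2, -1)), np.finfo(float).tiny)

    for k in range(1, config.max_iterations + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        if k == config.jacobi_fallback_after:
            use_gs[idx] = True
        new_phi = np.empty((idx.size, nc))
        for scheme, sel in (("jacobi", ~use_gs[idx]), ("gauss_seidel", use_gs[idx])):
            if np.any(sel):
                sub_idx = idx[sel]
                new_phi[sel] = _sweep(entries[sub_idx], a, phi[sub_idx], scheme)
        sub = entries[idx]
        new_sar = _batch_sar(sub, a * np.exp(1j * new_phi))
        delta = np.abs(new_sar - sar[idx])
        phi[idx] = new_phi
        sar[idx] = new_sar
        iterations[idx] = k
        if record_history:
            for j, s in zip(idx, new_sar):
                histories[j].append(float(s))
        improve = new_sar > best_sar[idx]
        upd = idx[improve]
        best_sar[upd] = new_sar[improve]
        best_phi[upd] = new_phi[improve]

        tol = np.maximum(config.epsilon, config.epsilon_rel * np.abs(new_sar))
        done = (delta <= tol) & (k >= 2)
        if np.any(done):
            gnorm = np.max(np.abs(_batch_grad(sub, a, new_phi)), axis=-1)
            cycling = done & (gnorm > 1e-8 * gscale[idx]) & ~use_gs[idx]
            use_gs[idx[cycling]] = True
            done &= ~cycling
            if config.grad_tol is not None:
                done &= gnorm <= config.grad_tol

        if np.any(done):
            didx = idx[done]
            # stationary: certify a maximum, else perturb and continue
            stuck = _positive_curvature(entries[didx], a, phi[didx])
            for j, bad in zip(didx, stuck):
                if bad and escapes[j] < config.max_escapes:
                    escapes[j] += 1
                    kick = config.perturb_scale * rng.standard_normal(nc)
                    phi[j] = phi[j] + np.where(a > 0, kick, 0.0)
                    sar[j] = _batch_sar(entries[j], a * np.exp(1j * phi[j]))
                else:
                    converged[j] = True
                    active[j] = False
                    # prefer the stationary iterate over a fractionally
                    # higher transient so the certificate holds at the
                    # returned phases
                    if sar[j] >= best_sar[j] - 1e-12 * max(abs(sar[j]), 1.0):
                        best_sar[j] = sar[j]
                        best_phi[j] = phi[j]
    # return best-seen state
    final_grad = np.max(np.abs(_batch_grad(entries, a, phi)), axis=-1)
    out_phi = np.where((sar >= best_sar)[:, None], phi, best_phi)
    out_sar = np.maximum(sar, best_sar)
    return out_phi, out_sar, iterations, converged, histories, final_grad, escapes


def _positive_curvature(entries: np.ndarray, a: np.ndarray, phi: np.ndarray):
    """True per matrix when the phase Hessian has meaningful positive
    curvature (stationary point that is not a maximum)."""
    b = 2.0 * np.einsum("l,...lm,m->...lm", a, np.abs(entries), a)
    for l in range(entries.shape[-1]):
        b[..., l, l] = 0.0
    theta = np.angle(entries)
    c = b * np.cos(theta + phi[..., None, :] - phi[..., :, None])
    h = c.copy()
    rows = np.sum(c, axis=-1)
    for l in range(entries.shape[-1]):
        h[..., l, l] -= rows[..., l]
    w = np.linalg.eigvalsh(h)
    tol = 1e-7 * np.maximum(np.max(np.abs(b), axis=(-2, -1)), np.finfo(float).tiny)
    return w[..., -1] > tol


def maximize_phases(
    q: QMatrix | np.ndarray,
    amplitudes: Sequence[float],
    config: TrigMaxConfig | None = None,
) -> PhaseMaxResult:
    """Worst-case phases and SAR for one Q-matrix at fixed amplitudes.

    Iterates ``phi_l <- atan2(Y_l, X_l)`` sweeps until the SAR change falls
    below the configured tolerance; the returned SAR never falls below the
    initial-phase SAR, and the reported phases are normalized so the first
    driven channel has phase zero.
    """
    config = config or TrigMaxConfig()
    entries = _as_entries(q)
    a = np.asarray(amplitudes, dtype=float)
    _check_sizes(entries, a)
    phi, sar, iters, conv, hist, grad, escapes = _run_fixed_point(
        entries[None], a, config, record_history=True
    )
    return PhaseMaxResult(
        phases=_normalize_phases(phi[0], a),
        max_sar=float(sar[0]),
        iterations=int(iters[0]),
        converged=bool(conv[0]),
        sar_history=np.asarray(hist[0]),
        grad_inf_norm=float(grad[0]),
        n_escapes=int(escapes[0]),
    )


def worst_case_psar(
    qset: QMatrixSet,
    amplitudes: Sequence[float],
    config: TrigMaxConfig | None = None,
) -> WorstCaseResult:
    """Worst-case SAR per matrix and its peak over the set (pSAR_TM).

    The per-matrix maximizations are independent, so the peak does not
    depend on evaluation order; the sweep runs vectorized across matrices.
    """
    config = config or TrigMaxConfig()
    a = np.asarray(amplitudes, dtype=float)
    _check_sizes(qset.entries, a)
    sym = 0.5 * (qset.entries + np.conj(np.swapaxes(qset.entries, -1, -2)))
    phi, sar, iters, conv, _, grad, escapes = _run_fixed_point(sym, a, config)
    phi = _normalize_phases(phi, a)
    arg = int(np.argmax(sar))
    return WorstCaseResult(
        max_sar=sar,
        phases=phi,
        iterations=iters,
        converged=conv,
        amplitudes=a,
        peak_sar=float(sar[arg]),
        argmax=arg,
        peak_voxel=None if qset.voxel_index is None else qset.voxel_index[arg],
    )


@dataclass
class TimeIntegratedResult:
    """Duration-weighted worst-case SAR for a time-dependent amplitude drive."""

    per_matrix: np.ndarray  # (Nv,) time-averaged worst-case SAR, W/kg
    peak_sar: float
    argmax: int
    durations: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover
        return f"TimeIntegratedResult(peak_sar={self.peak_sar:.6g} W/kg)"


def time_integrated_worst_case(
    qset: QMatrixSet,
    amplitude_trajectory: Sequence[Sequence[float]],
    durations: Sequence[float],
    config: TrigMaxConfig | None = None,
) -> TimeIntegratedResult:
    """Worst-case pSAR for a time-resolved amplitude trajectory.

    Per matrix the worst-case SAR of each time step is averaged with
    duration weights (the phase adversary may differ per step); the peak is
    taken over matrices.  A single step reduces to :func:`worst_case_psar`.
    """
    amps = np.atleast_2d(np.asarray(amplitude_trajectory, dtype=float))
    durs = np.atleast_1d(np.asarray(durations, dtype=float))
    if amps.shape[0] == 0 or durs.size == 0:
        raise ValidationError("trajectory must contain at least one time step")
    if amps.shape[0] != durs.size:
        raise ValidationError("one duration per time step is required")
    if np.any(durs <= 0):
        raise ValidationError("durations must be positive")
    total = durs.sum()
    acc = np.zeros(len(qset))
    for a_t, d_t in zip(amps, durs):
        res = worst_case_psar(qset, a_t, config)
        acc += d_t * res.max_sar
    per_matrix = acc / total
    arg = int(np.argmax(per_matrix))
    return TimeIntegratedResult(
        per_matrix=per_matrix,
        peak_sar=float(per_matrix[arg]),
        argmax=arg,
        durations=durs,
    )


def sar_from_drive(q: QMatrix | np.ndarray, drive: DriveVector) -> float:
    """Convenience: cosine-form SAR of a drive carrying phases."""
    if drive.phases is None:
        raise ValidationError("drive has no phases")
    return sar_phase_form(q, drive.amplitudes, drive.phases)
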