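"""Virtual-observation-point (VOP) compression of Q-matrix sets.

A full-body Q10g set holds one matrix per voxel — far too many for
real-time supervision.  A VOP set is a small subset such that every
original matrix ``Q_j`` is dominated, in the positive-semidefinite sense,
by some VOP ``V`` inflated with a global overestimation term:

    V + delta * lambda_bar * I - Q_j  >=  0   (PSD),

where ``lambda_bar`` is the largest eigenvalue over all matrices in the
set and ``delta`` the allowed overestimation fraction (5% by default).
PSD dominance implies ``s† Q_j s <= s† (V + delta*lambda_bar*I) s`` for
every drive, so the VOP-based peak never underestimates the full-set peak
and exceeds it by at most ``delta * lambda_bar * P_tot``.

The compression here is a greedy first-fit pass in descending-lambda_max
order: a matrix becomes a new VOP unless an existing VOP already dominates
it.  This is deterministic and carries the dominance guarantee; it does
not attempt the minimal VOP count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qmodel import QMatrixSet, ValidationError

__all__ = ["VOPSet", "compress_vops"]

#: PSD-test tolerance relative to lambda_bar
PSD_RTOL = 1e-10


@dataclass
class VOPSet:
    """Compressed surrogate set with a global overestimation term.

    ``vops`` has shape (Nvop, Nc, Nc); ``delta_term = delta * lambda_bar``
    is the scalar added (times identity) when evaluating; ``provenance``
    maps each original matrix index to the VOP that dominates it.
    """

    vops: np.ndarray
    delta: float
    lambda_bar: float
    provenance: np.ndarray
    source_index: np.ndarray  # original-set index of each VOP

    @property
    def delta_term(self) -> float:
        return self.delta * self.lambda_bar

    @property
    def n_vops(self) -> int:
        return self.vops.shape[0]

    @property
    def n_channels(self) -> int:
        return self.vops.shape[1]

    def estimate_psar(self, drive_complex: np.ndarray) -> float:
        """Conservative pSAR for a complex drive: max_v s†Vs + delta_term*P."""
        s = np.asarray(drive_complex, dtype=complex)
        vals = np.real(np.einsum("l,vlm,m->v", s.conj(), self.vops, s))
        return float(vals.max() + self.delta_term * np.sum(np.abs(s) ** 2))

    def as_qmatrixset(self) -> QMatrixSet:
        """The VOP matrices (without the delta term) as a plain set."""
        return QMatrixSet(
            entries=self.vops,
            voxel_index=np.column_stack(
                [self.source_index, np.zeros((self.n_vops, 2), dtype=int)]
            ),
            averaged=True,
        )

    def augmented_qmatrixset(self) -> QMatrixSet:
        """VOP matrices with the overestimation term folded in
        (V + delta*lambda_bar*I), ready for downstream peak searches."""
        aug = self.vops + self.delta_term * np.eye(self.n_channels)[None]
        return QMatrixSet(
            entries=aug,
            voxel_index=np.column_stack(
                [self.source_index, np.zeros((self.n_vops, 2), dtype=int)]
            ),
            averaged=True,
        )


def _dominates(v: np.ndarray, q: np.ndarray, shift: float, tol: float) -> bool:
    """True when v + shift*I - q is PSD within tolerance."""
    d = v - q
    d[np.diag_indices_from(d)] += shift
    w = np.linalg.eigvalsh(0.5 * (d + d.conj().T))
    return bool(w[0] >= -tol)


def compress_vops(qset: QMatrixSet, delta: float = 0.05) -> VOPSet:
    """Greedy VOP compression with overestimation fraction ``delta``.

    Matrices are visited in descending lambda_max order (ties broken by
    original index); each either joins the VOP list or is certified as
    dominated by an existing VOP plus ``delta * lambda_bar * I``.
    """
    if not (0.0 < delta < 1.0):
        raise ValidationError("delta must lie in (0, 1)")
    lam = qset.max_eigenvalues()
    lambda_bar = float(lam.max())
    if lambda_bar <= 0:
        raise ValidationError("set has no positive eigenvalue to compress against")
    shift = delta * lambda_bar
    tol = PSD_RTOL * lambda_bar

    order = np.lexsort((np.arange(len(qset)), -lam))
    vop_entries: list[np.ndarray] = []
    vop_source: list[int] = []
    provenance = np.full(len(qset), -1, dtype=int)
    for j in order:
        q = 0.5 * (qset.entries[j] + qset.entries[j].conj().T)
        placed = False
        for v_idx, v in enumerate(vop_entries):
            if _dominates(v, q, shift, tol):
                provenance[j] = v_idx
                placed = True
                break
        if not placed:
            vop_entries.append(q)
            vop_source.append(int(j))
            provenance[j] = len(vop_entries) - 1
    return VOPSet(
        vops=np.array(vop_entries),
        delta=delta,
        lambda_bar=lambda_bar,
        provenance=provenance,
        source_index=np.array(vop_source, dtype=int),
    )
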