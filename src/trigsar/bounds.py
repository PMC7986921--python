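"""Comparator estimators of worst-case peak local SAR.

Alongside the exact trigonometric maximization (TM), SAR supervision
practice uses faster conservative estimators:

* total-power (TP) bound: ``lambda_max * P_tot`` per matrix — the maximum of
  the quadratic form over every drive of the given total power, ignoring
  the known per-channel power split;
* reference-phases (RP) estimate: the quadratic form at a handful of fixed
  reference phase vectors, inflated by calibrated correction factors
  ``zeta_k >= 1`` and capped at the TP bound;
* eigenvector-phase lower bound (LB) and magnitude-sum upper bound (UB):
  closed forms that bracket the worst case without any iteration and agree
  with it exactly for rank-1 (single dominant field direction) matrices.

``compare_methods`` evaluates all of them against the actual pSAR of
phase-carrying drives and summarizes overestimation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .qmodel import DriveVector, QMatrix, QMatrixSet, ValidationError, eigen_info
from .trigmax import TrigMaxConfig, sar_phase_form, worst_case_psar

__all__ = [
    "RPModel",
    "BoundsReport",
    "tp_bound",
    "lower_bound",
    "upper_bound",
    "psar_lower_bound",
    "psar_upper_bound",
    "default_reference_phases",
    "calibrate_rp",
    "rp_estimate",
    "compare_methods",
]


def tp_bound(qset: QMatrixSet, total_power: float) -> float:
    """Total-power eigenvalue bound: max_j lambda_max(Q_j) * P_tot, W/kg."""
    if total_power <= 0:
        raise ValidationError("total power must be positive")
    return float(qset.max_eigenvalues().max() * total_power)


def lower_bound(q: QMatrix | np.ndarray, amplitudes: Sequence[float]) -> float:
    """Worst-case SAR lower bound from dominant-eigenvector phases.

    Evaluates the quadratic form with the known amplitudes and the phases
    ``psi_n`` of the dominant eigenvector.  For a rank-1 matrix these phases
    cancel every entry phase and the bound is tight (perfect constructive
    interference of the channel fields).
    """
    q = q if isinstance(q, QMatrix) else QMatrix(np.asarray(q))
    info = q.eigen_info()
    a = np.asarray(amplitudes, dtype=float)
    return sar_phase_form(q, a, info.eigenvector_phases)


def upper_bound(q: QMatrix | np.ndarray, amplitudes: Sequence[float]) -> float:
    """Magnitude-sum upper bound: sum_nm s_n |Q_nm| s_m (all cosines at 1)."""
    q = q if isinstance(q, QMatrix) else QMatrix(np.asarray(q))
    a = np.asarray(amplitudes, dtype=float)
    return float(a @ q.magnitude @ a)


def psar_lower_bound(qset: QMatrixSet, amplitudes: Sequence[float]) -> float:
    """Peak of the per-matrix lower bounds over the set."""
    return max(lower_bound(QMatrix(e), amplitudes) for e in qset.entries)


def psar_upper_bound(qset: QMatrixSet, amplitudes: Sequence[float]) -> float:
    """Peak of the per-matrix upper bounds over the set."""
    a = np.asarray(amplitudes, dtype=float)
    vals = np.einsum("l,jlm,m->j", a, np.abs(qset.entries), a)
    return float(vals.max())


# ---------------------------------------------------------------------------
# reference-phases method


def default_reference_phases(nc: int) -> list[np.ndarray]:
    """Default K=2 reference sets: all-zero phases and the circularly
    polarized increment 2*pi*n/Nc.  Suitable reference phases depend on the
    array, so callers may supply their own."""
    return [np.zeros(nc), 2.0 * np.pi * np.arange(nc) / nc]


@dataclass(frozen=True)
class RPModel:
    """Calibrated reference-phases estimator.

    ``reference_phases`` are K phase vectors; ``correction_factors`` the
    calibrated ``zeta_k >= 1`` guaranteeing conservativeness on the sampled
    amplitude family.  Calibration metadata records the sampling budget and
    seed for reproducibility.
    """

    reference_phases: tuple[np.ndarray, ...]
    correction_factors: np.ndarray
    n_samples: int = 0
    seed: int | None = None

    def __post_init__(self):
        if len(self.reference_phases) < 1:
            raise ValidationError("at least one reference phase set is required")
        zeta = np.asarray(self.correction_factors, dtype=float)
        if zeta.shape != (len(self.reference_phases),):
            raise ValidationError("one correction factor per reference set")
        if not np.all(np.isfinite(zeta)) or np.any(zeta < 1.0 - 1e-12):
            raise ValidationError("correction factors must be finite and >= 1")
        object.__setattr__(self, "correction_factors", zeta)


def _reference_psar(
    qset: QMatrixSet, amplitudes: np.ndarray, phases: np.ndarray
) -> float:
    """max_j w_k† Q_j w_k for the drive with the k-th reference phases."""
    w = amplitudes * np.exp(1j * phases)
    vals = np.real(np.einsum("l,jlm,m->j", w.conj(), qset.entries, w))
    return float(vals.max())


def _sample_amplitudes(nc: int, count: int, rng: np.random.Generator) -> np.ndarray:
    """Amplitude vectors with per-channel power uniform on the unit simplex."""
    powers = rng.dirichlet(np.ones(nc), size=count)
    return np.sqrt(powers)


def calibrate_rp(
    qset: QMatrixSet,
    reference_phases: Sequence[np.ndarray] | None = None,
    n_samples: int = 200,
    seed: int = 0,
    config: TrigMaxConfig | None = None,
) -> RPModel:
    """Calibrate correction factors with TM as the exact inner maximizer.

    For each reference set k, ``zeta_k`` is the largest ratio of the exact
    worst-case pSAR (TM) to the reference-phase pSAR over ``n_samples``
    amplitude vectors drawn uniformly (in power) on the simplex — the
    smallest inflation that is conservative on the sampled family.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    nc = qset.n_channels
    refs = [np.asarray(p, dtype=float) for p in (
        reference_phases if reference_phases is not None else default_reference_phases(nc)
    )]
    for p in refs:
        if p.shape != (nc,):
            raise ValidationError("reference phase sets must have length Nc")
    rng = np.random.default_rng(seed)
    amps = _sample_amplitudes(nc, n_samples, rng)
    zeta = np.ones(len(refs))
    for a in amps:
        tm = worst_case_psar(qset, a, config).peak_sar
        for k, p in enumerate(refs):
            denom = _reference_psar(qset, a, p)
            if denom <= 0:
                raise ValidationError(
                    f"reference set {k} gives zero SAR for a sampled drive"
                )
            zeta[k] = max(zeta[k], tm / denom)
    return RPModel(
        reference_phases=tuple(refs),
        correction_factors=zeta,
        n_samples=n_samples,
        seed=seed,
    )


def rp_estimate(
    qset: QMatrixSet, amplitudes: Sequence[float], model: RPModel
) -> float:
    """Reference-phases estimate: min_k zeta_k * max_j w_k† Q_j w_k,
    capped at the TP bound for the drive's total power."""
    a = np.asarray(amplitudes, dtype=float)
    est = min(
        zeta * _reference_psar(qset, a, p)
        for zeta, p in zip(model.correction_factors, model.reference_phases)
    )
    return min(est, tp_bound(qset, float(np.sum(a**2))))


# ---------------------------------------------------------------------------
# method comparison


@dataclass
class BoundsReport:
    """Per-drive estimates and overestimation statistics.

    All arrays are aligned with the drive list; absent methods are None.
    Overestimation is (estimate - actual)/actual in percent.
    """

    actual: np.ndarray | None
    tm: np.ndarray | None
    rp: np.ndarray | None
    tp: np.ndarray | None
    lb: np.ndarray | None
    ub: np.ndarray | None
    n_drives: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    _METHODS = ("tm", "rp", "tp", "lb", "ub")

    def available_methods(self) -> list[str]:
        return [m for m in self._METHODS if getattr(self, m) is not None]

    def overestimation(self, method: str) -> np.ndarray:
        """Percent overestimation of the actual pSAR by ``method``."""
        if self.actual is None:
            raise ValidationError("actual pSAR not available in this report")
        est = getattr(self, method)
        if est is None:
            raise ValidationError(f"method {method!r} not present in report")
        return (est / self.actual - 1.0) * 100.0

    def summary(self) -> pd.DataFrame:
        """Mean/max/min overestimation per method, percent."""
        rows = []
        for m in self.available_methods():
            o = self.overestimation(m)
            rows.append(
                {
                    "method": m,
                    "mean_overestimation_pct": float(np.mean(o)),
                    "max_overestimation_pct": float(np.max(o)),
                    "min_overestimation_pct": float(np.min(o)),
                }
            )
        return pd.DataFrame(rows)

    def histogram(self, method: str, bins: int | np.ndarray = 50):
        """Histogram (counts, bin edges) of percent overestimation."""
        return np.histogram(self.overestimation(method), bins=bins)

    def to_frame(self) -> pd.DataFrame:
        data = {"drive": np.arange(self.n_drives)}
        if self.actual is not None:
            data["actual"] = self.actual
        for m in self.available_methods():
            data[m] = getattr(self, m)
        return pd.DataFrame(data)

    def plot_overestimation(self, bins: int = 50, ax=None):
        """Overlaid overestimation histograms, one color per method."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"tm": "green", "rp": "blue", "tp": "red", "lb": "purple", "ub": "orange"}
        for m in self.available_methods():
            ax.hist(
                self.overestimation(m),
                bins=bins,
                alpha=0.5,
                label=m.upper(),
                color=colors.get(m),
            )
        ax.set_xlabel("overestimation of actual pSAR [%]")
        ax.set_ylabel("drives")
        ax.legend()
        return ax


def compare_methods(
    qset: QMatrixSet,
    drives: Sequence[DriveVector],
    model: RPModel | None = None,
    config: TrigMaxConfig | None = None,
    methods: Sequence[str] = ("tm", "rp", "tp", "lb", "ub"),
) -> BoundsReport:
    """Evaluate the requested estimators against the actual pSAR per drive.

    Drives must carry phases so the actual pSAR is computable.  The RP
    method requires a calibrated ``model``; without one it is skipped.
    """
    methods = tuple(methods)
    drives = list(drives)
    if not drives:
        raise ValidationError("at least one drive is required")
    entries = qset.entries
    lam_max = float(qset.max_eigenvalues().max())

    # eigenvector phases per matrix, for the LB closed form
    psi = None
    if "lb" in methods:
        psi = np.array([eigen_info(e).eigenvector_phases for e in entries])

    actual = np.empty(len(drives))
    out = {m: np.empty(len(drives)) for m in methods if m != "rp" or model}
    for i, d in enumerate(drives):
        if d.phases is None:
            raise ValidationError("drives must include phases for comparison")
        s = d.as_complex()
        actual[i] = float(
            np.real(np.einsum("l,jlm,m->j", s.conj(), entries, s)).max()
        )
        a = d.amplitudes
        if "tm" in out:
            out["tm"][i] = worst_case_psar(qset, a, config).peak_sar
        if "rp" in out:
            out["rp"][i] = rp_estimate(qset, a, model)
        if "tp" in out:
            out["tp"][i] = lam_max * d.total_power
        if "lb" in out:
            w = a * np.exp(1j * psi)
            vals = np.real(np.einsum("jl,jlm,jm->j", w.conj(), entries, w))
            out["lb"][i] = float(vals.max())
        if "ub" in out:
            out["ub"][i] = psar_upper_bound(qset, a)
    return BoundsReport(
        actual=actual,
        tm=out.get("tm"),
        rp=out.get("rp"),
        tp=out.get("tp"),
        lb=out.get("lb"),
        ub=out.get("ub"),
        n_drives=len(drives),
    )
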