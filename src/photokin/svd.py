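"""SVD rank analysis and model-matrix rotation of spectro-temporal data.

A truncated SVD ``A ≈ U W V^T`` is rotated into physical concentration
profiles ``C`` and species spectra ``S`` through an invertible model matrix
``X`` built from spectroscopic constraints (known spectra, isosbestic points,
assumed zero-extinction regions)::

    C = U W X^-1,   S = X V^T,   so that C·S = A^(K) for any invertible X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import SpectroTemporalMatrix, ValidationError

logger = logging.getLogger(__name__)

MAX_CONDITION = 1e12


def _lag1_autocorr(x: np.ndarray) -> float:
    """Lag-1 autocorrelation; ~1 for smooth vectors, ~0 for white noise."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return 1.0
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


@dataclass
class SVDResult:
    """Economy SVD of a spectro-temporal matrix plus rank diagnostics."""

    U: np.ndarray                  # N_T x K_full
    W: np.ndarray                  # singular values, descending
    V: np.ndarray                  # N_L x K_full
    time_axis: np.ndarray
    wavelength_axis: np.ndarray
    window: str
    kind: str
    rank_K: int = -1               # unset until estimate_rank
    diagnostics: list = field(default_factory=list)


@dataclass
class ModelMatrix:
    """K x K rotation relating abstract SVD components to physical species."""

    X: np.ndarray
    constraint_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.X.shape[1]:
            raise ValidationError("model matrix must be square")
        self.condition = float(np.linalg.cond(self.X))
        if self.condition > MAX_CONDITION:
            raise ValidationError(
                f"model matrix is numerically singular "
                f"(condition number {self.condition:.3g})"
            )


def compute_svd(m: SpectroTemporalMatrix) -> SVDResult:
    """Full economy SVD with per-component diagnostics.

    Missing values are not imputed here; mask or interpolate first.
    """
    if m.n_missing:
        raise ValidationError(
            f"matrix has {m.n_missing} missing values; mask or impute before SVD"
        )
    U, W, Vt = np.linalg.svd(m.values, full_matrices=False)
    V = Vt.T
    diags = [
        {
            "component": k,
            "singular_value": float(W[k]),
            "u_autocorr": _lag1_autocorr(U[:, k]),
            "v_autocorr": _lag1_autocorr(V[:, k]),
        }
        for k in range(W.size)
    ]
    return SVDResult(U, W, V, m.time_axis, m.wavelength_axis, m.window,
                     m.kind, rank_K=-1, diagnostics=diags)


def noise_floor(W: np.ndarray) -> float:
    """Noise-floor proxy: median of the trailing half of the singular values."""
    W = np.asarray(W, dtype=float)
    tail = W[W.size // 2:]
    return float(np.median(tail)) if tail.size else 0.0


def estimate_rank(
    svd: SVDResult,
    sv_ratio_threshold: float = 5.0,
    autocorr_threshold: float = 0.8,
) -> int:
    """Number of leading components that are both large and smooth.

    A component is significant when its singular value is at least
    ``sv_ratio_threshold`` times the noise floor AND the lag-1 autocorrelation
    of both its singular vectors reaches ``autocorr_threshold``.  Counting
    stops at the first failing component (ties excluded conservatively).
    Sets ``svd.rank_K`` and records the rationale in the diagnostics.
    """
    if not 0 < autocorr_threshold <= 1:
        raise ValidationError("autocorr_threshold must lie in (0, 1]")
    if sv_ratio_threshold <= 0:
        raise ValidationError("sv_ratio_threshold must be positive")
    floor = noise_floor(svd.W)
    # lag-1 autocorrelation is meaningless for a handful of points
    check_u = svd.U.shape[0] >= 8
    check_v = svd.V.shape[0] >= 8
    K = 0
    for d in svd.diagnostics:
        # the absolute guard rejects numerically-zero components of exact
        # low-rank matrices, where the floor itself vanishes
        sv_ok = (d["singular_value"] >= sv_ratio_threshold * floor
                 and d["singular_value"] > 1e-10 * svd.W[0])
        ac_ok = ((d["u_autocorr"] >= autocorr_threshold or not check_u)
                 and (d["v_autocorr"] >= autocorr_threshold or not check_v))
        d["noise_floor"] = floor
        d["significant"] = bool(sv_ok and ac_ok)
        d["rationale"] = (
            f"sv {'≥' if sv_ok else '<'} {sv_ratio_threshold}×floor({floor:.3g}); "
            f"autocorr {'≥' if ac_ok else '<'} {autocorr_threshold}"
        )
        if sv_ok and ac_ok:
            K += 1
        else:
            break
    svd.rank_K = K
    logger.info("estimate_rank: K=%d (floor %.3g)", K, floor)
    return K


def truncate(svd: SVDResult, K: int) -> SpectroTemporalMatrix:
    """Best rank-K reconstruction ``A^(K) = U^(K) W^(K) V^(K)T``."""
    if not 1 <= K <= svd.W.size:
        raise ValidationError(f"K={K} outside [1, {svd.W.size}]")
    vals = (svd.U[:, :K] * svd.W[:K]) @ svd.V[:, :K].T
    return SpectroTemporalMatrix(vals, svd.time_axis, svd.wavelength_axis,
                                 window=svd.window, kind=svd.kind)


def rotate_to_species(svd: SVDResult, X: ModelMatrix):
    """Rotate the truncated SVD into profiles ``C`` and spectra ``S``.

    Requires ``svd.rank_K`` set to the model-matrix dimension.  Returns
    ``(C, S)`` with ``C·S = A^(K)`` to solver precision.
    """
    K = X.X.shape[0]
    if svd.rank_K != K:
        raise ValidationError(
            f"rank_K={svd.rank_K} does not match model matrix dimension {K}; "
            "run estimate_rank first"
        )
    UW = svd.U[:, :K] * svd.W[:K]
    C = np.linalg.solve(X.X.T, UW.T).T          # U W X^-1
    S = X.X @ svd.V[:, :K].T                    # X V^T
    return C, S
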