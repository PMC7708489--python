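"""Recover field-TM rows from intensity-only measurements (phase retrieval).

Each selected NMF component supplies an excitation intensity time-series
``h_p = |<t, E_in(p)>|**2`` with known input phasors ``E_in(p)``; the unknown
complex row ``t`` (length ``n_slm``) is recovered up to a global phase — all
quality metrics here are phase invariant.  The solver is a standard two-stage
scheme:

1. *Spectral initialization*: the leading eigenvector of the weighted
   covariance ``(1/P) sum_p f(h_p) conj(E_p) E_p^T``, which concentrates along
   ``t`` for random inputs.  The "refined" weighting
   ``f(y) = max(1 - 1/y, -1)`` (with ``y`` the mean-normalized intensity)
   suppresses the unit-eigenvalue bulk and reaches a given alignment with
   fewer measurements than the plain ``f(y) = y`` (truncated) weighting.
2. *Amplitude-flow gradient descent* on the amplitude loss
   ``(1/P) sum_p (sqrt(h_p) - |<t, E_p>|)**2`` with a fixed step sized from
   the spectral norm of the pattern matrix, or backtracking line search.

The problem is well posed when P is a few times larger than ``n_slm``; with
P below ``n_slm`` the system is underdetermined and a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import eigsh

from .optics_sim import PhasePatternSet, substream

__all__ = [
    "PhaseRetrievalConfig",
    "RetrievedRow",
    "FieldTMEstimate",
    "spectral_init",
    "retrieve_row",
    "retrieve_field_tm",
    "phase_cosine",
]

_EPS = 1e-12


def phase_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Global-phase-invariant cosine similarity |<a, b>| / (|a||b|)."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.abs(np.vdot(a, b)) / (na * nb))


@dataclass(frozen=True)
class PhaseRetrievalConfig:
    n_iter_max: int = 400
    step_rule: str = "fixed"  # "fixed" | "backtracking"
    step_scale: float = 0.2
    tol: float = 1e-10
    init: str = "refined-spectral"  # "spectral" | "refined-spectral" | "random"
    trunc: float = 5.0  # clip normalized intensities above this for the plain weighting
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.step_rule not in ("fixed", "backtracking"):
            raise ValueError("step_rule must be 'fixed' or 'backtracking'")
        if self.init not in ("spectral", "refined-spectral", "random"):
            raise ValueError("init must be 'spectral', 'refined-spectral' or 'random'")


@dataclass
class RetrievedRow:
    t_est: np.ndarray
    loss_trace: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class FieldTMEstimate:
    matrix: np.ndarray
    loss_traces: list[np.ndarray]
    status: list[str]
    row_indices: np.ndarray | None = None


def _check_measurements(h_row: np.ndarray, patterns: PhasePatternSet) -> np.ndarray:
    h_row = np.asarray(h_row, dtype=float).ravel()
    if h_row.shape[0] != patterns.n_patterns:
        raise ValueError(
            f"h_row has {h_row.shape[0]} entries, pattern set has {patterns.n_patterns}"
        )
    if np.all(h_row == 0):
        raise ValueError("all-zero intensity row: nothing to retrieve")
    if patterns.n_patterns < patterns.n_slm:
        warnings.warn(
            "fewer measurements than unknowns (P < n_slm): retrieval is underdetermined",
            stacklevel=3,
        )
    return np.clip(h_row, 0.0, None)


def _leading_eigvec(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    if n <= 32:
        vals, vecs = np.linalg.eigh(M)
        return vecs[:, -1]
    _, vecs = eigsh(M, k=1, which="LA")
    return vecs[:, 0]


def spectral_init(
    h_row: np.ndarray, patterns: PhasePatternSet, config: PhaseRetrievalConfig
) -> np.ndarray:
    """Spectral estimate of the row: leading eigenvector of the weighted covariance.

    The returned vector is scaled so that the empirical mean of
    ``|<init, E_p>|**2`` matches ``mean(h_row)``.
    """
    h_row = _check_measurements(h_row, patterns)
    y = h_row / h_row.mean()
    if config.init == "refined-spectral":
        f = np.maximum(1.0 - 1.0 / np.maximum(y, _EPS), -1.0)
    else:  # plain (truncated) spectral weighting
        f = np.where(y <= config.trunc, y, 0.0)
    E = patterns.fields  # (n_slm, P)
    M = (np.conj(E) * f) @ E.T / patterns.n_patterns
    v = _leading_eigvec(M)
    a = v @ E
    scale = np.sqrt(h_row.mean() / max(np.mean(np.abs(a) ** 2), _EPS))
    return scale * v


def retrieve_row(
    h_row: np.ndarray, patterns: PhasePatternSet, config: PhaseRetrievalConfig | None = None
) -> RetrievedRow:
    """Amplitude-flow phase retrieval of one field-TM row.

    Minimizes ``(1/P) sum_p (sqrt(h_p) - |E_p^T t|)**2`` by Wirtinger gradient
    descent from the spectral initialization.  The NMF hands over rows with
    arbitrary scale, so measurements are normalized to unit mean internally
    and the scale is re-attached to the returned estimate.  With the fixed
    step rule a loss increase raises an error advising backtracking; with
    backtracking the loss trace is non-increasing by construction.
    """
    if config is None:
        config = PhaseRetrievalConfig()
    h_raw = _check_measurements(h_row, patterns)
    scale = h_raw.mean()
    h = h_raw / scale
    sqrt_h = np.sqrt(h)
    E = patterns.fields
    P = patterns.n_patterns

    if config.init == "random":
        rng = substream(config.seed, "pr_init")
        t = rng.standard_normal(patterns.n_slm) + 1j * rng.standard_normal(patterns.n_slm)
        a = t @ E
        t *= np.sqrt(h.mean() / max(np.mean(np.abs(a) ** 2), _EPS))
    else:
        t = spectral_init(h, patterns, config)

    # Lipschitz scale from the pattern matrix spectral norm (power iteration)
    v = np.ones(patterns.n_slm, dtype=complex) / np.sqrt(patterns.n_slm)
    for _ in range(20):
        v = np.conj(E) @ (v @ E)
        v /= np.linalg.norm(v)
    lips = np.linalg.norm(np.conj(E) @ (v @ E)) / P
    step = config.step_scale / max(lips, _EPS)

    def loss_and_grad(t):
        a = t @ E
        absa = np.abs(a)
        diff = absa - sqrt_h
        loss = float(np.mean(diff**2))
        phase = a / np.maximum(absa, _EPS)
        grad = np.conj(E) @ (diff * phase) / P
        return loss, grad

    loss, grad = loss_and_grad(t)
    trace = [loss]
    converged = False
    for it in range(config.n_iter_max):
        if config.step_rule == "fixed":
            t_new = t - step * grad
            loss_new, grad_new = loss_and_grad(t_new)
            if loss_new > loss + 1e-12:
                raise RuntimeError(
                    "fixed-step amplitude flow diverged (loss increased); "
                    "use step_rule='backtracking' or a smaller step_scale"
                )
        else:
            s = step
            for _ in range(40):
                t_new = t - s * grad
                loss_new, grad_new = loss_and_grad(t_new)
                if loss_new <= loss:
                    break
                s *= 0.5
            else:  # pragma: no cover - pathological
                loss_new, grad_new, t_new = loss, grad, t
        t, grad = t_new, grad_new
        trace.append(loss_new)
        if loss - loss_new <= config.tol * max(loss, _EPS):
            loss = loss_new
            converged = True
            break
        loss = loss_new
    return RetrievedRow(
        t_est=t * np.sqrt(scale),
        loss_trace=np.asarray(trace),
        n_iter=len(trace) - 1,
        converged=converged,
    )


def retrieve_field_tm(
    H_rows: np.ndarray,
    patterns: PhasePatternSet,
    config: PhaseRetrievalConfig | None = None,
    row_indices: np.ndarray | None = None,
) -> FieldTMEstimate:
    """Retrieve every row of the field TM independently; failures do not stop the rest."""
    H_rows = np.atleast_2d(np.asarray(H_rows, dtype=float))
    matrix = np.zeros((H_rows.shape[0], patterns.n_slm), dtype=complex)
    traces: list[np.ndarray] = []
    status: list[str] = []
    for k in range(H_rows.shape[0]):
        try:
            out = retrieve_row(H_rows[k], patterns, config)
            matrix[k] = out.t_est
            traces.append(out.loss_trace)
            status.append("ok" if out.converged else "max-iter")
        except Exception as exc:  # propagate per-row, keep going
            traces.append(np.array([]))
            status.append(f"failed: {exc}")
    return FieldTMEstimate(
        matrix=matrix,
        loss_traces=traces,
        status=status,
        row_indices=None if row_indices is None else np.asarray(row_indices, dtype=int),
    )
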