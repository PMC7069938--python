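"""l1-regularized least-squares inversion with (monotone) FISTA.

The reconstruction solves

    T̂ = argmin_T  ‖S − A T‖₂² + α² ‖T‖₁ ,

exactly as written: no ½ on the data term and the regularization weight
enters squared, so the proximal threshold per step is α²·step for a gradient
step of size ``step`` on the data term (∇‖S − AT‖² = 2 Aᵀ(AT − S), Lipschitz
constant L = 2‖A‖₂²).

The iteration is the monotone FISTA variant: the accelerated proximal point
is kept only if it does not increase the objective, so the objective trace
is non-increasing by construction.  All linear algebra runs on the cached
Gram matrix AᵀA (n × n), which makes each iteration O(n²) regardless of the
number of RF samples m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SolverError
from .forward import ForwardModel

__all__ = [
    "SolverConfig",
    "ReconResult",
    "soft_threshold",
    "lipschitz_estimate",
    "alpha_max",
    "fista_solve",
    "choose_alpha",
]


@dataclass(frozen=True)
class SolverConfig:
    """FISTA settings.

    alpha : regularization weight α (enters the objective as α²‖T‖₁).
    max_iters / tolerance : stop on iteration budget or when the relative
        objective change drops below tolerance.
    step_rule : "fixed_1_over_L" (power-iteration Lipschitz estimate with a
        5% safety margin) or "backtracking".
    nonnegativity : use the one-sided threshold (T ≥ 0).
    """

    alpha: float = 0.0
    max_iters: int = 2000
    tolerance: float = 1e-8
    step_rule: str = "fixed_1_over_L"
    nonnegativity: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise SolverError("alpha must be nonnegative")
        if self.max_iters < 1:
            raise SolverError("max_iters must be at least 1")
        if self.tolerance <= 0:
            raise SolverError("tolerance must be positive")
        if self.step_rule not in ("fixed_1_over_L", "backtracking"):
            raise SolverError(f"unknown step rule {self.step_rule!r}")


@dataclass
class ReconResult:
    """Sparse estimate on the grid plus solver diagnostics."""

    T_hat: np.ndarray
    objective_trace: np.ndarray
    n_iters: int
    converged: bool
    residual_norm: float
    alpha: float

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.T_hat))


def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise sign(v) · max(|v| − lam, 0) — the proximal operator of
    lam‖·‖₁."""
    if lam < 0:
        raise SolverError("threshold must be nonnegative")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def _as_matrix(model) -> np.ndarray:
    return model.matrix if isinstance(model, ForwardModel) else np.asarray(model, float)


def _gram(model) -> np.ndarray:
    if isinstance(model, ForwardModel):
        return model.gram()
    A = np.asarray(model, dtype=float)
    return A.T @ A


def lipschitz_estimate(
    model, tol: float = 1e-6, max_sweeps: int = 20000, seed: int = 0
) -> float:
    """Largest squared singular value ‖A‖₂² by power iteration on AᵀA."""
    G = _gram(model)
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(G.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_sweeps):
        w = G @ v
        lam_new = float(v @ w)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
        if abs(lam_new - lam) <= tol * max(lam_new, 1e-300):
            return lam_new
        lam = lam_new
    raise SolverError(
        f"power iteration did not converge in {max_sweeps} sweeps "
        f"(last estimate {lam:.6g})"
    )


def alpha_max(model, S: np.ndarray) -> float:
    """Smallest α for which T̂ = 0: the zero vector is optimal iff
    ‖∇‖S − AT‖²|_{T=0}‖_∞ = 2‖AᵀS‖_∞ ≤ α², hence α_max = √(2‖AᵀS‖_∞)."""
    A = _as_matrix(model)
    return float(np.sqrt(2.0 * np.max(np.abs(A.T @ S))))


def fista_solve(
    model,
    S: np.ndarray,
    config: SolverConfig,
    T0: np.ndarray | None = None,
    _precomputed: tuple | None = None,
) -> ReconResult:
    """Minimize ‖S − A T‖₂² + α²‖T‖₁ by monotone FISTA.

    ``model`` is a :class:`ForwardModel` or a plain (m × n) array.  ``T0``
    optionally warm-starts the iteration (the problem is convex, so the
    solution does not depend on it).
    """
    A = _as_matrix(model)
    S = np.asarray(S, dtype=float).ravel()
    if S.size != A.shape[0]:
        raise SolverError(
            f"data vector length {S.size} does not match model rows {A.shape[0]}"
        )
    if _precomputed is not None:
        G, L = _precomputed
    else:
        G = _gram(model)
        L = 2.0 * lipschitz_estimate(model)
    b = A.T @ S
    S2 = float(S @ S)
    a2 = config.alpha ** 2

    if L == 0:
        raise SolverError("model matrix is identically zero")
    step = 1.0 / (1.05 * L)  # 5% safety on the power-iteration estimate
    thresh = a2 * step

    def prox(v: np.ndarray) -> np.ndarray:
        if config.nonnegativity:
            return np.maximum(v - thresh, 0.0)
        return soft_threshold(v, thresh)

    def objective(T: np.ndarray, GT: np.ndarray) -> float:
        return S2 - 2.0 * (b @ T) + float(T @ GT) + a2 * np.abs(T).sum()

    T = np.zeros(A.shape[1]) if T0 is None else np.asarray(T0, dtype=float).copy()
    y = T.copy()
    t_mom = 1.0
    f = objective(T, G @ T)
    trace = [f]
    converged = False
    backtrack_step = step

    for _ in range(config.max_iters):
        grad = 2.0 * (G @ y - b)
        if config.step_rule == "fixed_1_over_L":
            z = prox(y - step * grad)
        else:  # backtracking on the data term
            g_y = S2 - 2.0 * (b @ y) + float(y @ (G @ y))
            while True:
                z = (
                    np.maximum(y - backtrack_step * grad - a2 * backtrack_step, 0.0)
                    if config.nonnegativity
                    else soft_threshold(y - backtrack_step * grad,
                                        a2 * backtrack_step)
                )
                d = z - y
                g_z = S2 - 2.0 * (b @ z) + float(z @ (G @ z))
                if g_z <= g_y + grad @ d + (d @ d) / (2 * backtrack_step) + 1e-12:
                    break
                backtrack_step *= 0.5
                if backtrack_step < 1e-30:
                    raise SolverError("backtracking step underflow")
        if not np.all(np.isfinite(z)):
            raise SolverError(
                f"divergence: non-finite iterate with step {step:.3g}"
            )
        f_z = objective(z, G @ z)
        if f_z > f:
            # adaptive (function-value) restart: discard the overshooting
            # accelerated point and retake a plain proximal-gradient step
            # from the last accepted iterate — guaranteed non-increasing
            # with step <= 1/L, so the trace stays monotone
            y = T.copy()
            t_mom = 1.0
            trace.append(f)
            continue
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2)) / 2.0
        y = z + ((t_mom - 1.0) / t_next) * (z - T)
        rel_change = (f - f_z) / max(abs(f), 1e-300)
        T, f = z, f_z
        t_mom = t_next
        trace.append(f)
        if rel_change < config.tolerance:
            converged = True
            break

    residual = float(np.linalg.norm(S - A @ T))
    return ReconResult(
        T_hat=T,
        objective_trace=np.asarray(trace),
        n_iters=len(trace) - 1,
        converged=converged,
        residual_norm=residual,
        alpha=config.alpha,
    )


@dataclass
class AlphaReport:
    """Per-candidate L-curve record from :func:`choose_alpha`."""

    table: pd.DataFrame
    alpha: float | None
    alpha_max: float
    flag: str  # "ok" | "manual"


def support_clusters(model, T: np.ndarray) -> int:
    """Number of 8-connected clusters of nonzero cells on the model's grid
    (falls back to the raw nonzero count for plain matrices)."""
    if not isinstance(model, ForwardModel):
        return int(np.count_nonzero(T))
    from scipy.ndimage import label

    img = model.grid.vector_to_image(np.abs(np.asarray(T)))
    return int(label(img > 0, structure=np.ones((3, 3)))[1])


def choose_alpha(
    model,
    S: np.ndarray,
    fractions: np.ndarray | None = None,
    support_budget: int = 8,
    support_metric: str = "clusters",
    base_config: SolverConfig | None = None,
) -> AlphaReport:
    """Heuristic regularization scan.

    Candidates are logarithmic fractions of α_max (the smallest α giving an
    all-zero solution).  The default rule picks the *smallest* candidate α
    whose solution support stays within ``support_budget`` — i.e. the least
    regularization that still yields an object as sparse as the scene is
    expected to be ("qualitatively close" to a known-sparse sample).

    ``support_metric`` is ``"clusters"`` (8-connected spots on the grid —
    robust to the mass-splitting between adjacent cells that coherent
    neighbouring columns produce) or ``"cells"`` (raw nonzero count).
    If no candidate qualifies the report is flagged ``"manual"`` and
    ``alpha`` falls back to the candidate with the sparsest support.
    """
    if support_metric not in ("clusters", "cells"):
        raise SolverError(f"unknown support metric {support_metric!r}")
    if fractions is None:
        fractions = np.geomspace(0.5, 0.02, 8)
    fractions = np.sort(np.asarray(fractions, dtype=float))[::-1]
    if np.any(fractions <= 0):
        raise SolverError("alpha fractions must be positive")
    base = base_config or SolverConfig()
    amax = alpha_max(model, S)
    G = _gram(model)
    L = 2.0 * lipschitz_estimate(model)

    rows = []
    T_warm = None
    for frac in fractions:  # descending: warm starts densify gradually
        a = frac * amax
        cfg = SolverConfig(
            alpha=a, max_iters=base.max_iters, tolerance=base.tolerance,
            step_rule=base.step_rule, nonnegativity=base.nonnegativity,
        )
        res = fista_solve(model, S, cfg, T0=T_warm, _precomputed=(G, L))
        T_warm = res.T_hat
        support = (
            support_clusters(model, res.T_hat)
            if support_metric == "clusters" else res.support_size
        )
        rows.append({
            "fraction": frac,
            "alpha": a,
            "support": support,
            "support_cells": res.support_size,
            "residual_norm": res.residual_norm,
            "l1_norm": float(np.abs(res.T_hat).sum()),
            "n_iters": res.n_iters,
        })
    table = pd.DataFrame(rows)
    ok = table[(table["support"] > 0) & (table["support"] <= support_budget)]
    if len(ok):
        alpha = float(ok["alpha"].min())
        flag = "ok"
    else:
        nonzero = table[table["support"] > 0]
        if len(nonzero):
            alpha = float(
                nonzero.sort_values(["support", "alpha"]).iloc[0]["alpha"]
            )
        else:
            alpha = None
        flag = "manual"
    return AlphaReport(table=table, alpha=alpha, alpha_max=amax, flag=flag)
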