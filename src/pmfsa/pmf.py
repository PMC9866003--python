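"""Uncertainty-weighted positive matrix factorization (PMF).

Solves X ~ G F with G (n x p, per-sample source contributions) and
F (p x m, source chemical profiles) both constrained nonnegative, by
minimizing the weighted least-squares objective

    Q = sum_ij ((x_ij - sum_k g_ik f_kj) / sigma_ij)^2

where sigma_ij is the per-cell measurement uncertainty.  The solver uses
alternating multiplicative updates generalized to per-cell weights
w_ij = 1/sigma_ij^2 (Lee-Seung style), which keep both factors nonnegative
and decrease Q monotonically.  Multi-start with deterministic per-start
seeds guards against local minima; an optional robust mode down-weights
cells whose scaled residual exceeds a cutoff (Huber-style), the usual
guard against outlier samples in receptor modeling.

Rotational ambiguity is explored through an Fpeak-style parameter: for
phi < 0 the rotation pushes contribution columns of G toward sparsity, for
phi > 0 the profile rows of F, via elementary pairwise transforms
T = I + phi * E_kl followed by projection to nonnegativity and a refit of
the free matrix.  The physically meaningful rotation is a human choice;
`fpeak_scan` only tabulates the candidates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class PMFConfig:
    """Solver settings.

    n_factors : number of sources p (must satisfy p <= min(n, m)).
    n_starts : random restarts; the best final Q is retained.
    max_iter : iteration cap per start.
    rel_tol : relative |dQ|/Q below which an iteration counts as stalled.
    tol_iters : consecutive stalled iterations required to declare
        convergence.
    seed : master seed; per-start generators are spawned from it.
    fpeak : rotation parameter in [-1, 1] applied after fitting (0 = none).
    robust / robust_cutoff : Huber-style down-weighting of cells with
        |scaled residual| > cutoff (EPA convention alpha = 4).
    """

    n_factors: int
    n_starts: int = 20
    max_iter: int = 5000
    rel_tol: float = 1e-8
    tol_iters: int = 10
    seed: int = 0
    fpeak: float = 0.0
    robust: bool = False
    robust_cutoff: float = 4.0

    def validate(self, n: int | None = None, m: int | None = None) -> None:
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if n is not None and m is not None and self.n_factors > min(n, m):
            raise ValueError(
                f"n_factors={self.n_factors} exceeds min(n, m)={min(n, m)}"
            )
        if self.n_starts < 1 or self.max_iter < 1:
            raise ValueError("n_starts and max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if not -1.0 <= self.fpeak <= 1.0:
            raise ValueError("fpeak must lie in [-1, 1]")
        if self.robust_cutoff <= 0:
            raise ValueError("robust_cutoff must be > 0")


@dataclass
class PMFSolution:
    """A converged factorization plus bookkeeping.

    G is n x p, F is p x m, both nonnegative.  ``q_trajectory`` is the
    per-iteration objective of the winning start; ``q_per_start`` the final
    objective of every start.  After `normalize_factors`, ``scaled`` is
    True and G columns are in ug/m3 of PM2.5 mass.
    """

    G: np.ndarray
    F: np.ndarray
    Q_true: float
    Q_robust: float
    q_trajectory: np.ndarray
    converged: bool
    start_index: int
    fpeak_applied: float = 0.0
    dq_from_base: float = 0.0
    species_names: list | None = None
    q_per_start: np.ndarray | None = None
    scaled: bool = False
    flagged_factors: tuple = ()
    warnings: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.G.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.G @ self.F


def _check_xu(X, U):
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if X.shape != U.shape:
        raise ValueError("X and U must have identical shapes")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(U))):
        raise ValueError("X and U must be finite")
    if np.any(U <= 0):
        raise ValueError("all uncertainties must be strictly positive")
    return X, U


def q_value(X, U, G, F, robust: bool = False, alpha: float = 4.0) -> float:
    """The PMF objective: sum of squared scaled residuals.

    In robust mode, cells with |r| > alpha contribute the Huber tail
    alpha * (2|r| - alpha) instead of r^2, capping outlier leverage.
    """
    X, U = _check_xu(X, U)
    r = (X - np.asarray(G) @ np.asarray(F)) / U
    r2 = r * r
    if robust:
        a = np.abs(r)
        tail = a > alpha
        r2[tail] = alpha * (2.0 * a[tail] - alpha)
    return float(r2.sum())


def _huber_weight_matrix(X, U, G, F, alpha):
    """Per-cell multiplier on 1/sigma^2 implementing Huber reweighting."""
    r = np.abs((X - G @ F) / U)
    w = np.ones_like(r)
    tail = r > alpha
    w[tail] = alpha / r[tail]
    return w


def _multiplicative_step(X, U, G, F, W):
    """One alternating multiplicative update of (G, F) under weights W."""
    WX = W * X
    GF = G @ F
    G = G * ((WX @ F.T) / ((W * GF) @ F.T + _EPS))
    G = np.maximum(G, _EPS)
    GF = G @ F
    F = F * ((G.T @ WX) / (G.T @ (W * GF) + _EPS))
    F = np.maximum(F, _EPS)
    return G, F


def _single_fit(X, U, config: PMFConfig, rng: np.random.Generator):
    n, m = X.shape
    p = config.n_factors
    col_scale = X.mean(axis=0) / p
    G = rng.uniform(0.5, 1.5, size=(n, p))
    F = rng.uniform(0.5, 1.5, size=(p, m)) * np.maximum(col_scale, _EPS)
    Winv = 1.0 / (U * U)
    traj = []
    stalled = 0
    converged = False
    q_prev = None
    for _ in range(config.max_iter):
        if config.robust:
            W = Winv * _huber_weight_matrix(X, U, G, F, config.robust_cutoff)
        else:
            W = Winv
        G, F = _multiplicative_step(X, U, G, F, W)
        q = q_value(X, U, G, F, robust=config.robust,
                    alpha=config.robust_cutoff)
        traj.append(q)
        if q_prev is not None:
            if abs(q_prev - q) <= config.rel_tol * max(q_prev, _EPS):
                stalled += 1
            else:
                stalled = 0
        q_prev = q
        if stalled >= config.tol_iters:
            converged = True
            break
    return G, F, np.asarray(traj), converged


def fit(X, U, config: PMFConfig, species_names=None) -> PMFSolution:
    """Best-of-``n_starts`` uncertainty-weighted PMF fit.

    Each start draws its initial G, F from an independent generator spawned
    deterministically from ``config.seed``, so identical inputs and config
    reproduce the result bit-for-bit.
    """
    X, U = _check_xu(X, U)
    n, m = X.shape
    config.validate(n, m)
    if species_names is not None and len(species_names) != m:
        raise ValueError("species_names length must match X columns")
    children = np.random.SeedSequence(config.seed).spawn(config.n_starts)
    best = None
    q_per_start = np.empty(config.n_starts)
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        G, F, traj, converged = _single_fit(X, U, config, rng)
        key = traj[-1]
        q_per_start[s] = key
        if best is None or key < best[0]:
            best = (key, s, G, F, traj, converged)
    _, s, G, F, traj, converged = best
    return PMFSolution(
        G=G,
        F=F,
        Q_true=q_value(X, U, G, F),
        Q_robust=q_value(X, U, G, F, robust=True,
                         alpha=config.robust_cutoff),
        q_trajectory=traj,
        converged=converged,
        start_index=int(s),
        species_names=list(species_names) if species_names is not None else None,
        q_per_start=q_per_start,
    )


def _refit_free_matrix(X, U, G, F, hold: str, max_iter: int = 500,
                       rel_tol: float = 1e-9):
    """Refit one matrix by multiplicative updates with the other held fixed."""
    W = 1.0 / (U * U)
    WX = W * X
    q_prev = None
    for _ in range(max_iter):
        GF = G @ F
        if hold == "G":
            F = F * ((G.T @ WX) / (G.T @ (W * GF) + _EPS))
            F = np.maximum(F, _EPS)
        else:
            G = G * ((WX @ F.T) / ((W * GF) @ F.T + _EPS))
            G = np.maximum(G, _EPS)
        q = q_value(X, U, G, F)
        if q_prev is not None and abs(q_prev - q) <= rel_tol * max(q_prev, _EPS):
            break
        q_prev = q
    return G, F


def apply_fpeak(
    sol: PMFSolution,
    phi: float,
    X,
    U,
    dq_budget: float = 0.10,
) -> PMFSolution:
    """Rotate a converged solution by the Fpeak-style parameter ``phi``.

    phi < 0 sharpens (sparsifies) contribution columns of G, phi > 0
    profile rows of F.  The elementary transform T = I + phi * E_kl is
    applied for the greedily chosen factor pair (k, l): among pairs whose
    post-rotation Q stays within ``dq_budget`` (relative) of the base Q,
    the pair pushing the most mass against the nonnegativity boundary is
    taken; if none qualifies the mildest pair is returned with a warning
    recorded.  phi = 0 returns the solution unchanged.  The reported
    ``dq_from_base`` is the (nonnegative) Q increase paid for the rotation.
    """
    if not -1.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [-1, 1]")
    if phi == 0.0:
        return dataclasses.replace(sol, fpeak_applied=0.0, dq_from_base=0.0)
    X, U = _check_xu(X, U)
    p = sol.n_factors
    if p < 2:
        out = dataclasses.replace(sol, fpeak_applied=phi, dq_from_base=0.0)
        out.warnings = sol.warnings + ["fpeak requires >= 2 factors; no-op"]
        return out
    q_base = sol.Q_true
    # work on unit-mean G columns so phi has a comparable effect per pair
    d = sol.G.mean(axis=0)
    d = np.where(d > 0, d, 1.0)
    Gn = sol.G / d
    Fn = d[:, None] * sol.F
    candidates = []
    for k in range(p):
        for l in range(p):
            if k == l:
                continue
            Gc = Gn.copy()
            Fc = Fn.copy()
            Gc[:, l] = Gc[:, l] + phi * Gc[:, k]
            Fc[k, :] = Fc[k, :] - phi * Fc[l, :]
            clip_mass = float(np.abs(Gc[Gc < 0]).sum() + np.abs(Fc[Fc < 0]).sum())
            Gc = np.maximum(Gc, _EPS)
            Fc = np.maximum(Fc, _EPS)
            hold = "G" if phi < 0 else "F"
            Gc, Fc = _refit_free_matrix(X, U, Gc, Fc, hold=hold)
            q = q_value(X, U, Gc, Fc)
            candidates.append((k, l, clip_mass, q, Gc, Fc))
    feasible = [c for c in candidates if c[3] - q_base <= dq_budget * q_base]
    warnings_out = list(sol.warnings)
    if feasible:
        # most boundary contact, then lowest Q, then lexicographic pair
        k, l, _, q, Gc, Fc = max(
            feasible, key=lambda c: (c[2], -c[3], -c[0], -c[1])
        )
    else:
        k, l, _, q, Gc, Fc = min(candidates, key=lambda c: (c[3], c[0], c[1]))
        warnings_out.append(
            f"fpeak {phi:+.2f}: dQ {q - q_base:.4g} exceeds budget "
            f"{dq_budget:.0%} of Q={q_base:.4g}"
        )
    return dataclasses.replace(
        sol,
        G=Gc,
        F=Fc,
        Q_true=q,
        Q_robust=q_value(X, U, Gc, Fc, robust=True),
        fpeak_applied=phi,
        dq_from_base=max(q - q_base, 0.0),
        warnings=warnings_out,
    )


def default_fpeak_grid() -> np.ndarray:
    """The conventional scan grid: -1.0 to +1.0 in 0.1 steps (21 values)."""
    return np.round(np.linspace(-1.0, 1.0, 21), 1)


def fpeak_scan(sol: PMFSolution, X, U, grid=None, dq_budget: float = 0.10):
    """Tabulate rotation outcomes over a grid of Fpeak values.

    Returns a list of dicts with keys ``phi``, ``dq``, ``q`` and
    ``solution``.  No automatic winner is chosen: selecting the physically
    meaningful rotation is the analyst's call.
    """
    if grid is None:
        grid = default_fpeak_grid()
    rows = []
    for phi in np.asarray(grid, dtype=float):
        rot = apply_fpeak(sol, float(phi), X, U, dq_budget=dq_budget)
        rows.append({
            "phi": float(phi),
            "dq": rot.dq_from_base,
            "q": rot.Q_true,
            "solution": rot,
        })
    return rows


def normalize_factors(sol: PMFSolution, mass_species: str) -> PMFSolution:
    """Rescale factors so G columns are in ug/m3 of PM2.5 mass.

    Each factor k is scaled by its mass loading f_k,mass: contributions
    g_ik <- g_ik * f_k,mass and the profile row is divided by the same,
    leaving G F unchanged.  Factors with (numerically) zero mass loading
    are flagged and left unscaled.  Factors are reordered by descending
    mean scaled contribution for reporting reproducibility.
    """
    if sol.species_names is None:
        raise ValueError("solution carries no species names")
    if mass_species not in sol.species_names:
        raise ValueError(f"mass species {mass_species!r} absent from profiles")
    j = sol.species_names.index(mass_species)
    load = sol.F[:, j].copy()
    zero = load <= 1e-10 * max(load.max(), _EPS)
    G = sol.G.copy()
    F = sol.F.copy()
    scale = np.where(zero, 1.0, load)
    G = G * scale[None, :]
    F = F / scale[:, None]
    order = np.argsort(-G.mean(axis=0), kind="stable")
    flagged = tuple(int(np.where(order == k)[0][0]) for k in np.where(zero)[0])
    warnings_out = list(sol.warnings)
    if flagged:
        warnings_out.append(
            f"factors {flagged} contribute no mass; left unscaled"
        )
    return dataclasses.replace(
        sol,
        G=G[:, order],
        F=F[order, :],
        scaled=True,
        flagged_factors=flagged,
        warnings=warnings_out,
    )
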