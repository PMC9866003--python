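"""Model-adequacy diagnostics for PMF solutions.

Three families of checks, all driven by the scaled residual matrix
R = (X - G F) / U:

* coverage of scaled residuals in [-3, +3] (at least 80% is the usual
  acceptance rule for a correctly weighted fit);
* IM / IS factor-number diagnostics: the maximum over species of the mean
  (IM) and of the standard deviation (IS) of that species' scaled
  residuals.  Both drop sharply once enough factors are fitted, so their
  curves against p locate the appropriate factor count;
* R^2 of the regression of reconstructed total mass on measured mass,
  the headline reliability number for an apportionment.

IM is taken literally as the maximum of the *signed* column means; the
maximum absolute column mean is reported alongside, since a strongly
negative species bias is equally diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pmf import PMFConfig, PMFSolution, fit


def scaled_residuals(X, U, sol: PMFSolution):
    """Scaled residual grid and the fraction of cells within +-3.

    Returns ``(R, coverage3)``; the 0.80 acceptance rule is evaluated by
    :func:`coverage_passes`.
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if X.shape != U.shape or X.shape != (sol.G.shape[0], sol.F.shape[1]):
        raise ValueError("inconsistent shapes between X, U and the solution")
    R = (X - sol.reconstruct()) / U
    coverage3 = float(np.mean(np.abs(R) <= 3.0))
    return R, coverage3


def coverage_passes(coverage3: float, threshold: float = 0.80) -> bool:
    return coverage3 >= threshold


def im_is(R) -> tuple[float, float]:
    """IM and IS from a scaled-residual grid.

    IM = max over species of the column mean; IS = max over species of the
    sample standard deviation (n-1 divisor).  Requires >= 2 samples.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("IS needs at least 2 samples")
    col_means = R.mean(axis=0)
    col_sds = R.std(axis=0, ddof=1)
    return float(col_means.max()), float(col_sds.max())


def im_abs(R) -> float:
    """Maximum absolute column mean (bias in either direction)."""
    R = np.asarray(R, dtype=float)
    return float(np.abs(R.mean(axis=0)).max())


def suggest_knee(curves: pd.DataFrame) -> int | None:
    """Advisory factor count: largest relative successive drop in IS.

    Only defined over consecutive entries of the recorded p column;
    returns None when fewer than two usable rows exist.
    """
    df = curves.dropna(subset=["IS"]).sort_values("p")
    best_p, best_drop = None, -np.inf
    prev_p, prev_is = None, None
    for p, is_val in zip(df["p"], df["IS"]):
        if prev_p is not None and p == prev_p + 1 and prev_is > 0:
            drop = (prev_is - is_val) / prev_is
            if drop > best_drop:
                best_drop, best_p = drop, int(p)
        prev_p, prev_is = p, is_val
    return best_p


def factor_number_curves(
    X, U, p_range, config: PMFConfig, species_names=None
) -> tuple[pd.DataFrame, int | None]:
    """Fit PMF over a range of factor counts and record (p, Q, IM, IS).

    Per-p failures are recorded as NaN rows rather than aborting the scan.
    Returns the curve table and the advisory knee p (never auto-final:
    physical meaningfulness of a factor count is a human judgement).
    """
    rows = []
    for p in p_range:
        cfg = PMFConfig(**{**config.__dict__, "n_factors": int(p)})
        try:
            sol = fit(X, U, cfg, species_names=species_names)
            R, cov = scaled_residuals(X, U, sol)
            im, is_ = im_is(R)
            rows.append({"p": int(p), "Q": sol.Q_true, "IM": im, "IS": is_,
                         "IM_abs": im_abs(R), "coverage3": cov,
                         "converged": sol.converged, "error": ""})
        except Exception as exc:  # noqa: BLE001 - scan must not abort
            rows.append({"p": int(p), "Q": np.nan, "IM": np.nan,
                         "IS": np.nan, "IM_abs": np.nan, "coverage3": np.nan,
                         "converged": False, "error": str(exc)})
    curves = pd.DataFrame(rows)
    return curves, suggest_knee(curves)


def mass_reconstruction_r2(measured_mass, sol: PMFSolution) -> float:
    """OLS R^2 between measured PM2.5 mass and summed scaled contributions.

    Requires a mass-scaled solution; factors flagged as contributing no
    mass are excluded from the sum (their columns are in arbitrary units).
    """
    if not sol.scaled:
        raise ValueError("normalize_factors must be applied first")
    measured = np.asarray(measured_mass, dtype=float)
    if measured.size < 3:
        raise ValueError("need at least 3 samples for R^2")
    cols = [k for k in range(sol.n_factors) if k not in sol.flagged_factors]
    recon = sol.G[:, cols].sum(axis=1)
    if measured.shape != recon.shape:
        raise ValueError("measured mass length must match samples")
    if np.std(recon) == 0 or np.std(measured) == 0:
        return 0.0
    res = stats.linregress(measured, recon)
    return float(res.rvalue**2)


@dataclass
class DiagnosticsReport:
    """Bundle of adequacy diagnostics for one solution."""

    R: np.ndarray
    coverage3: float
    coverage_pass: bool
    IM: float
    IS: float
    IM_abs: float
    r2_mass: float | None = None
    per_p_curves: pd.DataFrame | None = None
    suggested_p: int | None = None
    notes: list = field(default_factory=list)

    def summary(self) -> dict:
        out = {
            "coverage3": self.coverage3,
            "coverage_pass": bool(self.coverage_pass),
            "IM": self.IM,
            "IS": self.IS,
            "IM_abs": self.IM_abs,
        }
        if self.r2_mass is not None:
            out["r2_mass"] = self.r2_mass
        if self.suggested_p is not None:
            out["suggested_p"] = self.suggested_p
        return out


def diagnose(
    X, U, sol: PMFSolution, measured_mass=None,
    coverage_threshold: float = 0.80,
) -> DiagnosticsReport:
    """Compute the full diagnostics bundle for a fitted solution."""
    R, cov = scaled_residuals(X, U, sol)
    im, is_ = im_is(R)
    r2 = None
    notes = []
    if measured_mass is not None:
        if sol.scaled:
            r2 = mass_reconstruction_r2(measured_mass, sol)
        else:
            notes.append("r2_mass skipped: solution not mass-scaled")
    return DiagnosticsReport(
        R=R,
        coverage3=cov,
        coverage_pass=coverage_passes(cov, coverage_threshold),
        IM=im,
        IS=is_,
        IM_abs=im_abs(R),
        r2_mass=r2,
        notes=notes,
    )
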