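"""Pretreatment of speciated PM2.5 filter data for receptor modeling.

Converts a raw samples x species table -- with per-species method detection
limits (MDLs), below-detection-limit (BDL) censoring and sporadic missing
values -- into the conditioned concentration matrix ``X`` and per-cell
uncertainty matrix ``U`` that the uncertainty-weighted PMF solver consumes.

The conditioning rules are the conventional ones for EPA-PMF-style receptor
modeling of 24-h filter data:

* samples failing mass closure, i.e. where the gravimetric PM2.5 mass and
  the summed chemical species disagree by more than ``tol`` (default 50%),
  are excluded;
* species that are BDL or missing in at least ``bdl_missing_frac`` (default
  90%) of samples are excluded, as are species the analyst lists as
  unreliable;
* missing cells are imputed with the species geometric mean and assigned an
  uncertainty of 4x that mean;
* BDL cells (and measured zeros) are replaced by MDL/2 with uncertainty
  (5/6) x MDL;
* measured cells keep their value with uncertainty
  sqrt((error_fraction * x)^2 + (0.5 * MDL)^2);
* the total-mass column is down-weighted with uncertainty 4x the mass value,
  so the factorization apportions mass without letting the (redundant)
  total dominate the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: cell status codes
MEASURED = "measured"
MISSING = "missing"
BDL = "bdl"

_FLAG_VALUES = frozenset({MEASURED, MISSING, BDL})


@dataclass
class SpeciatedDataset:
    """A raw samples x species concentration table with censoring metadata.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per sample (row).
    dates : pandas.DatetimeIndex
        Calendar date of each 24-h sample; same length as ``sample_ids``.
    species_names : list of str
        Column labels, including the total-mass column.
    conc : ndarray of shape (n, m)
        Concentrations in ug/m3.  Cells flagged ``missing`` or ``bdl`` may
        be NaN; ``measured`` cells must be finite and >= 0.
    mdl : ndarray of shape (m,)
        Per-species method detection limit in ug/m3, all > 0.
    flags : ndarray of shape (n, m)
        Per-cell status, one of ``"measured"``, ``"missing"``, ``"bdl"``.
    mass_column : str
        Name of the total PM2.5 mass column (must be in ``species_names``).
    exclusion_log : list of tuple
        ``(entity, rule, detail)`` records accumulated by the exclusion
        operations; carried along so downstream containers can report every
        removal exactly once.
    """

    sample_ids: list
    dates: pd.DatetimeIndex
    species_names: list
    conc: np.ndarray
    mdl: np.ndarray
    flags: np.ndarray
    mass_column: str = "PM2.5"
    exclusion_log: list = field(default_factory=list)

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.mdl = np.asarray(self.mdl, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        self.sample_ids = list(self.sample_ids)
        self.species_names = list(self.species_names)
        self.dates = pd.DatetimeIndex(self.dates)
        n, m = self.conc.shape
        if len(self.sample_ids) != n or len(self.dates) != n:
            raise ValueError("sample_ids/dates length must match conc rows")
        if len(self.species_names) != m:
            raise ValueError("species_names length must match conc columns")
        if self.flags.shape != self.conc.shape:
            raise ValueError("flags grid must have the same shape as conc")
        if self.mdl.shape != (m,):
            raise ValueError("mdl must be one value per species")
        if not np.all(self.mdl > 0):
            raise ValueError("every MDL must be > 0")
        if self.mass_column not in self.species_names:
            raise ValueError(
                f"mass column {self.mass_column!r} not among species_names"
            )
        bad = set(np.unique(self.flags)) - _FLAG_VALUES
        if bad:
            raise ValueError(f"unknown flag values: {sorted(bad)}")
        meas = self.flags == MEASURED
        vals = self.conc[meas]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("measured concentrations must be finite and >= 0")

    # -- small conveniences -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.conc.shape[0]

    @property
    def n_species(self) -> int:
        return self.conc.shape[1]

    @property
    def mass_index(self) -> int:
        return self.species_names.index(self.mass_column)

    def bdl_missing_fraction(self) -> pd.Series:
        """Fraction of cells per species that are BDL or missing."""
        frac = np.mean(self.flags != MEASURED, axis=0)
        return pd.Series(frac, index=self.species_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.conc, index=self.sample_ids, columns=self.species_names
        )


@dataclass
class ConditionedMatrices:
    """Conditioned PMF inputs: concentration matrix X and uncertainty U.

    ``U`` holds the per-cell sigma of the weighted least-squares objective
    Q = sum((X - GF)^2 / U^2).  ``kept_samples`` / ``kept_species`` are
    integer positions into the raw dataset the preprocessing chain started
    from; ``exclusion_log`` lists every removed row/column exactly once.
    """

    X: np.ndarray
    U: np.ndarray
    sample_ids: list
    dates: pd.DatetimeIndex
    species_names: list
    mass_column: str
    kept_samples: np.ndarray
    kept_species: np.ndarray
    exclusion_log: list = field(default_factory=list)

    def __post_init__(self):
        if self.X.shape != self.U.shape:
            raise ValueError("X and U must have identical shapes")
        if np.any(self.U <= 0):
            raise ValueError("all uncertainties must be strictly positive")
        if np.any(self.X < 0):
            raise ValueError("conditioned concentrations must be >= 0")

    @property
    def mass_index(self) -> int:
        return self.species_names.index(self.mass_column)

    @property
    def measured_mass(self) -> np.ndarray:
        return self.X[:, self.mass_index]


def _subset_samples(ds: SpeciatedDataset, keep: np.ndarray, log_entries):
    return replace(
        ds,
        sample_ids=[ds.sample_ids[i] for i in keep],
        dates=ds.dates[keep],
        conc=ds.conc[keep],
        flags=ds.flags[keep],
        exclusion_log=ds.exclusion_log + list(log_entries),
    )


def _subset_species(ds: SpeciatedDataset, keep: np.ndarray, log_entries):
    return replace(
        ds,
        species_names=[ds.species_names[j] for j in keep],
        conc=ds.conc[:, keep],
        flags=ds.flags[:, keep],
        mdl=ds.mdl[keep],
        exclusion_log=ds.exclusion_log + list(log_entries),
    )


def closure_species_sum(ds: SpeciatedDataset) -> np.ndarray:
    """Per-sample sum of non-mass species used by the mass-closure check.

    Measured cells enter at face value, BDL cells at MDL/2 (negligible by
    construction), missing cells are skipped.
    """
    j_mass = ds.mass_index
    total = np.zeros(ds.n_samples)
    for j in range(ds.n_species):
        if j == j_mass:
            continue
        meas = ds.flags[:, j] == MEASURED
        bdl = ds.flags[:, j] == BDL
        total[meas] += ds.conc[meas, j]
        total[bdl] += ds.mdl[j] / 2.0
    return total


def exclude_unclosed_samples(
    ds: SpeciatedDataset, tol: float = 0.50
) -> SpeciatedDataset:
    """Drop samples whose chemical sum disagrees with gravimetric mass.

    A sample is removed when ``|mass - sum(species)| / mass > tol`` or when
    its mass value is missing or <= 0 (logged under a distinct rule rather
    than silently divided by).
    """
    if not 0 < tol:
        raise ValueError("tol must be positive")
    j_mass = ds.mass_index
    species_sum = closure_species_sum(ds)
    keep, log = [], []
    for i in range(ds.n_samples):
        sid = ds.sample_ids[i]
        if ds.flags[i, j_mass] != MEASURED or ds.conc[i, j_mass] <= 0:
            log.append((sid, "nonpositive-or-missing-mass",
                        f"mass flag={ds.flags[i, j_mass]}, "
                        f"value={ds.conc[i, j_mass]!r}"))
            continue
        mass = ds.conc[i, j_mass]
        rel = abs(mass - species_sum[i]) / mass
        if rel > tol:
            log.append((sid, "mass-closure",
                        f"mass={mass:.4f} species_sum={species_sum[i]:.4f} "
                        f"rel_diff={rel:.4f} > {tol}"))
        else:
            keep.append(i)
    return _subset_samples(ds, np.asarray(keep, dtype=int), log)


def exclude_species(
    ds: SpeciatedDataset,
    bdl_missing_frac: float = 0.90,
    drop_list=(),
) -> SpeciatedDataset:
    """Drop unreliable species columns.

    A species is removed when its BDL-or-missing fraction is >=
    ``bdl_missing_frac``, or when it appears in ``drop_list`` (analyst
    judgement, e.g. species measured with poor reproducibility).  Names in
    ``drop_list`` absent from the table are ignored.  Dropping the mass
    column is an error.
    """
    drop_list = set(drop_list)
    if ds.mass_column in drop_list:
        raise ValueError("refusing to drop the total-mass column")
    frac = ds.bdl_missing_fraction()
    keep, log = [], []
    for j, name in enumerate(ds.species_names):
        if name in drop_list:
            log.append((name, "drop-list", "explicitly excluded"))
            continue
        if name != ds.mass_column and frac[name] >= bdl_missing_frac:
            if name == ds.mass_column:  # pragma: no cover - guarded above
                raise ValueError("90% rule would drop the mass column")
            log.append((name, "bdl-missing-fraction",
                        f"{frac[name]:.3f} >= {bdl_missing_frac}"))
            continue
        keep.append(j)
    return _subset_species(ds, np.asarray(keep, dtype=int), log)


def signal_to_noise(ds: SpeciatedDataset) -> pd.Series:
    """Per-species signal-to-noise ratio (EPA PMF 5.0 convention).

    Each non-missing cell contributes ``max(0, (x - MDL) / MDL)`` (BDL cells
    contribute 0); the ratio is the mean over those cells.  Species with all
    cells missing get NaN.
    """
    out = np.full(ds.n_species, np.nan)
    for j in range(ds.n_species):
        meas = ds.flags[:, j] == MEASURED
        n_used = int(meas.sum() + (ds.flags[:, j] == BDL).sum())
        if n_used == 0:
            continue
        contrib = np.maximum(0.0, (ds.conc[meas, j] - ds.mdl[j]) / ds.mdl[j])
        out[j] = contrib.sum() / n_used
    return pd.Series(out, index=ds.species_names, name="s_n_ratio")


def geometric_mean_measured(ds: SpeciatedDataset, j: int) -> float:
    """Geometric mean of the measured, strictly positive values of species j."""
    meas = ds.flags[:, j] == MEASURED
    vals = ds.conc[meas, j]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError(
            f"species {ds.species_names[j]!r} has no measured positive "
            "values; exclude it before building matrices"
        )
    return float(math.exp(np.mean(np.log(vals))))


def build_matrices(
    ds: SpeciatedDataset, error_fraction: float = 0.1
) -> ConditionedMatrices:
    """Impute censored cells and derive the per-cell uncertainty matrix.

    Expects a dataset that has already passed through the sample- and
    species-exclusion steps.  See the module docstring for the cell rules.
    Measured zeros are handled like BDL cells (a reported 0 carries no more
    information than "below detection").
    """
    if error_fraction <= 0:
        raise ValueError("error_fraction must be positive")
    n, m = ds.conc.shape
    X = np.empty((n, m))
    U = np.empty((n, m))
    j_mass = ds.mass_index
    for j in range(m):
        flags = ds.flags[:, j]
        meas = (flags == MEASURED) & (ds.conc[:, j] > 0)
        zero_or_bdl = (flags == BDL) | ((flags == MEASURED) & (ds.conc[:, j] <= 0))
        miss = flags == MISSING
        X[meas, j] = ds.conc[meas, j]
        U[meas, j] = np.sqrt(
            (error_fraction * ds.conc[meas, j]) ** 2 + (0.5 * ds.mdl[j]) ** 2
        )
        X[zero_or_bdl, j] = ds.mdl[j] / 2.0
        U[zero_or_bdl, j] = (5.0 / 6.0) * ds.mdl[j]
        if miss.any():
            gm = geometric_mean_measured(ds, j)
            X[miss, j] = gm
            U[miss, j] = 4.0 * gm
        if j == j_mass:
            # total mass is down-weighted: sigma = 4 x concentration
            U[:, j] = 4.0 * X[:, j]
    if np.any(U <= 0):
        raise ValueError("conditioning produced a non-positive uncertainty")
    return ConditionedMatrices(
        X=X,
        U=U,
        sample_ids=list(ds.sample_ids),
        dates=ds.dates,
        species_names=list(ds.species_names),
        mass_column=ds.mass_column,
        kept_samples=np.arange(n),
        kept_species=np.arange(m),
        exclusion_log=list(ds.exclusion_log),
    )


def preprocess(
    ds: SpeciatedDataset,
    closure_tol: float = 0.50,
    bdl_missing_frac: float = 0.90,
    drop_list=(),
    error_fraction: float = 0.1,
) -> ConditionedMatrices:
    """Full conditioning chain: closure filter -> species filter -> X, U.

    ``kept_samples`` / ``kept_species`` in the result are integer positions
    into the dataset passed here.
    """
    step1 = exclude_unclosed_samples(ds, tol=closure_tol)
    step2 = exclude_species(step1, bdl_missing_frac=bdl_missing_frac,
                            drop_list=drop_list)
    cm = build_matrices(step2, error_fraction=error_fraction)
    sample_pos = {sid: i for i, sid in enumerate(ds.sample_ids)}
    species_pos = {name: j for j, name in enumerate(ds.species_names)}
    cm.kept_samples = np.asarray([sample_pos[s] for s in cm.sample_ids])
    cm.kept_species = np.asarray([species_pos[s] for s in cm.species_names])
    return cm
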