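"""Readers, writers and run configuration for every table in the pipeline.

CSV conventions
---------------
* concentration table: columns ``sample_id`` (optional), ``date``
  (ISO-8601), then one column per species.  Sentinels: ``NA`` = missing,
  ``<MDL`` = below detection limit.
* MDL table: columns ``species``, ``mdl``.
* wind table: columns ``timestamp``, ``wd_deg``, ``ws_ms``.

Floats round-trip at full precision (written with ``repr``-level digits),
so write(read(f)) preserves values exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import BDL, MEASURED, MISSING, ConditionedMatrices, SpeciatedDataset

NA_SENTINEL = "NA"
BDL_SENTINEL = "<MDL"
_FLOAT_FMT = "%.17g"


def read_dataset(conc_path, mdl_path, mass_column: str = "PM2.5") -> SpeciatedDataset:
    """Load a raw speciated dataset from a concentration CSV + MDL CSV."""
    raw = pd.read_csv(conc_path, dtype=str)
    cols = list(raw.columns)
    if cols and cols[0] == "sample_id":
        sample_ids = raw["sample_id"].tolist()
        raw = raw.drop(columns=["sample_id"])
        cols = list(raw.columns)
    else:
        sample_ids = [f"S{i + 1:03d}" for i in range(len(raw))]
    if not cols or cols[0] != "date":
        raise ValueError("first data column must be 'date' (ISO-8601)")
    dates = pd.DatetimeIndex(pd.to_datetime(raw["date"], format="ISO8601"))
    species = cols[1:]
    n, m = len(raw), len(species)
    conc = np.full((n, m), np.nan)
    flags = np.full((n, m), MEASURED, dtype=object)
    for j, name in enumerate(species):
        col = raw[name].astype(str).str.strip()
        miss = col.isin([NA_SENTINEL, "", "nan"])
        bdl = col == BDL_SENTINEL
        flags[miss, j] = MISSING
        flags[bdl, j] = BDL
        ok = ~(miss | bdl)
        conc[ok.to_numpy(), j] = col[ok].astype(float).to_numpy()
    mdl_tab = pd.read_csv(mdl_path, float_precision="round_trip")
    mdl_map = dict(zip(mdl_tab["species"].astype(str), mdl_tab["mdl"].astype(float)))
    missing_mdl = [s for s in species if s not in mdl_map]
    if missing_mdl:
        raise ValueError(f"MDL table lacks species: {missing_mdl}")
    return SpeciatedDataset(
        sample_ids=sample_ids,
        dates=dates,
        species_names=species,
        conc=conc,
        mdl=np.asarray([mdl_map[s] for s in species]),
        flags=flags,
        mass_column=mass_column,
    )


def write_dataset(ds: SpeciatedDataset, conc_path, mdl_path) -> None:
    """Write a dataset back to the concentration + MDL CSV pair."""
    n, m = ds.conc.shape
    cells = np.empty((n, m), dtype=object)
    for j in range(m):
        for i in range(n):
            flag = ds.flags[i, j]
            if flag == MISSING:
                cells[i, j] = NA_SENTINEL
            elif flag == BDL:
                cells[i, j] = BDL_SENTINEL
            else:
                cells[i, j] = _FLOAT_FMT % ds.conc[i, j]
    out = pd.DataFrame(cells, columns=ds.species_names)
    out.insert(0, "date", ds.dates.strftime("%Y-%m-%d"))
    out.insert(0, "sample_id", ds.sample_ids)
    out.to_csv(conc_path, index=False)
    pd.DataFrame({"species": ds.species_names, "mdl": ds.mdl}).to_csv(
        mdl_path, index=False, float_format=_FLOAT_FMT
    )


def write_matrices(cm: ConditionedMatrices, x_path, u_path) -> None:
    for mat, path in ((cm.X, x_path), (cm.U, u_path)):
        df = pd.DataFrame(mat, columns=cm.species_names)
        df.insert(0, "date", cm.dates.strftime("%Y-%m-%d"))
        df.insert(0, "sample_id", cm.sample_ids)
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_matrix(path):
    """Read an X/U CSV; returns (values, sample_ids, dates, species)."""
    df = pd.read_csv(path, float_precision="round_trip")
    ids = df["sample_id"].tolist()
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    species = [c for c in df.columns if c not in ("sample_id", "date")]
    return df[species].to_numpy(dtype=float), ids, dates, species


def write_exclusion_log(log, path) -> None:
    with open(path, "w") as fh:
        for entity, rule, detail in log:
            fh.write(json.dumps({"entity": entity, "rule": rule,
                                 "detail": detail}) + "\n")


def read_exclusion_log(path):
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out.append((rec["entity"], rec["rule"], rec["detail"]))
    return out


def read_wind(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("timestamp", "wd_deg", "ws_ms"):
        if col not in df.columns:
            raise ValueError(f"wind CSV lacks column {col!r}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_wind(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_solution(sol, outdir, dates=None, sample_ids=None) -> None:
    """Write G.csv and F.csv for a fitted (optionally scaled) solution.

    F.csv stacks two blocks per factor: the profile in concentration units
    and the percentage of each species apportioned to the factor.
    """
    outdir = Path(outdir)
    species = sol.species_names or [f"V{j + 1}" for j in range(sol.F.shape[1])]
    g = pd.DataFrame(sol.G, columns=[f"factor_{k + 1}" for k in range(sol.n_factors)])
    if dates is not None:
        g.insert(0, "date", pd.DatetimeIndex(dates).strftime("%Y-%m-%d"))
    if sample_ids is not None:
        g.insert(0, "sample_id", sample_ids)
    g.to_csv(outdir / "G.csv", index=False, float_format=_FLOAT_FMT)
    conc = pd.DataFrame(sol.F, columns=species)
    conc.insert(0, "factor", [f"factor_{k + 1}" for k in range(sol.n_factors)])
    conc.insert(1, "kind", "conc_ugm3")
    colsum = sol.F.sum(axis=0)
    pct = pd.DataFrame(
        100.0 * sol.F / np.where(colsum > 0, colsum, np.nan)[None, :],
        columns=species,
    )
    pct.insert(0, "factor", [f"factor_{k + 1}" for k in range(sol.n_factors)])
    pct.insert(1, "kind", "pct_of_species")
    pd.concat([conc, pct], ignore_index=True).to_csv(
        outdir / "F.csv", index=False, float_format=_FLOAT_FMT
    )


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run.

    Defaults mirror a conventional EPA-PMF-style study design: 50% mass
    closure tolerance, 90% BDL/missing species cut, 10% proportional
    error, 9 factors with Fpeak -0.1, CPF at the 80th percentile with a
    1 m/s calm cutoff over 16 sectors.
    """

    outdir: str = "run"
    conc: str | None = None
    mdl: str | None = None
    wind: str | None = None
    mass_column: str = "PM2.5"
    closure_tol: float = 0.50
    bdl_missing_frac: float = 0.90
    drop_list: tuple = ()
    error_fraction: float = 0.1
    n_factors: int = 9
    n_starts: int = 20
    max_iter: int = 5000
    rel_tol: float = 1e-8
    seed: int = 42
    fpeak: float = -0.1
    robust: bool = False
    robust_cutoff: float = 4.0
    scan_factors: tuple | None = None
    percentile: float = 0.80
    calm_cutoff: float = 1.0
    n_sectors: int = 16
    make_plots: bool = False

    def validate(self, check_paths: bool = True) -> None:
        checks = [
            (0 < self.closure_tol, "closure_tol must be > 0"),
            (0 < self.bdl_missing_frac <= 1, "bdl_missing_frac must be in (0, 1]"),
            (0 < self.error_fraction < 1, "error_fraction must be in (0, 1)"),
            (self.n_factors >= 1, "n_factors must be >= 1"),
            (self.n_starts >= 1, "n_starts must be >= 1"),
            (-1.0 <= self.fpeak <= 1.0, "fpeak must lie in [-1, 1]"),
            (0 < self.percentile < 1, "percentile must lie in (0, 1)"),
            (self.calm_cutoff >= 0, "calm_cutoff must be >= 0"),
            (self.n_sectors >= 1, "n_sectors must be >= 1"),
        ]
        errors = [msg for ok, msg in checks if not ok]
        if check_paths:
            for label in ("conc", "mdl", "wind"):
                p = getattr(self, label)
                if p is not None and not Path(p).exists():
                    errors.append(f"{label} path does not exist: {p}")
        if errors:
            raise ValueError("invalid run configuration: " + "; ".join(errors))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drop_list"] = list(self.drop_list)
        if self.scan_factors is not None:
            d["scan_factors"] = list(self.scan_factors)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "drop_list" in raw and raw["drop_list"] is not None:
            raw["drop_list"] = tuple(raw["drop_list"])
        if "scan_factors" in raw and raw["scan_factors"] is not None:
            raw["scan_factors"] = tuple(raw["scan_factors"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
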