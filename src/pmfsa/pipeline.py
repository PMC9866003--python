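"""End-to-end orchestration: preprocess -> fit -> rotate -> report.

`run_pipeline` executes the full source-apportionment chain on a
configured input set and writes every artifact plus a JSON manifest into
the output directory.  The manifest records the configuration, package
version, per-stage status and a SHA-256 checksum of every output file, so
identical config + seed can be verified to reproduce identical bytes.  A
stage failure is recorded in the manifest and the partial outputs are
retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contributions import contribution_frame
from .cpf import cpf_compute
from .diagnostics import diagnose, factor_number_curves
from .io import (
    RunConfig,
    read_dataset,
    read_wind,
    write_exclusion_log,
    write_matrices,
    write_solution,
)
from .pmf import PMFConfig, apply_fpeak, fit, normalize_factors
from .preprocessing import preprocess

log = logging.getLogger("pmfsa")

STAGES = ("preprocess", "scan_factors", "fit", "fpeak", "normalize",
          "diagnostics", "contributions", "cpf")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, dataset=None, wind=None) -> Path:
    """Run the whole chain; returns the output directory.

    ``dataset`` / ``wind`` may be passed in-memory (e.g. fresh from the
    synthetic generator); otherwise they are read from the configured
    paths.  The wind/CPF stage is skipped when no winds are available.
    """
    config.validate(check_paths=dataset is None)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "checksums": {},
    }
    outputs: list[Path] = []

    def record(stage, status, detail="", files=()):
        manifest["stages"][stage] = {"status": status, "detail": detail,
                                     "outputs": [Path(f).name for f in files]}
        outputs.extend(Path(f) for f in files)
        log.info("stage %-13s %s %s", stage, status, detail)

    def finish():
        for f in outputs:
            manifest["checksums"][f.name] = _sha256(f)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return outdir

    try:
        if dataset is None:
            dataset = read_dataset(config.conc, config.mdl,
                                   mass_column=config.mass_column)
        if wind is None and config.wind is not None:
            wind = read_wind(config.wind)
        cm = preprocess(
            dataset,
            closure_tol=config.closure_tol,
            bdl_missing_frac=config.bdl_missing_frac,
            drop_list=config.drop_list,
            error_fraction=config.error_fraction,
        )
        write_matrices(cm, outdir / "X.csv", outdir / "U.csv")
        write_exclusion_log(cm.exclusion_log, outdir / "exclusions.jsonl")
        record("preprocess", "ok",
               f"{cm.X.shape[0]} x {cm.X.shape[1]} after conditioning",
               [outdir / "X.csv", outdir / "U.csv",
                outdir / "exclusions.jsonl"])
    except Exception as exc:  # noqa: BLE001 - manifest must record failures
        record("preprocess", "failed", str(exc))
        return finish()

    pmf_cfg = PMFConfig(
        n_factors=config.n_factors, n_starts=config.n_starts,
        max_iter=config.max_iter, rel_tol=config.rel_tol,
        seed=config.seed, fpeak=config.fpeak, robust=config.robust,
        robust_cutoff=config.robust_cutoff,
    )

    try:
        if config.scan_factors:
            curves, knee = factor_number_curves(
                cm.X, cm.U, config.scan_factors, pmf_cfg,
                species_names=cm.species_names,
            )
            curves.to_csv(outdir / "factor_curves.csv", index=False)
            record("scan_factors", "ok", f"suggested p={knee}",
                   [outdir / "factor_curves.csv"])
        else:
            record("scan_factors", "skipped", "no scan range configured")
    except Exception as exc:  # noqa: BLE001
        record("scan_factors", "failed", str(exc))

    try:
        sol = fit(cm.X, cm.U, pmf_cfg, species_names=cm.species_names)
        with open(outdir / "fit_log.json", "w") as fh:
            json.dump({
                "q_true": sol.Q_true,
                "q_robust": sol.Q_robust,
                "q_per_start": list(map(float, sol.q_per_start)),
                "best_start": sol.start_index,
                "converged": bool(sol.converged),
                "iterations": int(len(sol.q_trajectory)),
            }, fh, indent=2)
        record("fit", "ok", f"Q={sol.Q_true:.4g}", [outdir / "fit_log.json"])
    except Exception as exc:  # noqa: BLE001
        record("fit", "failed", str(exc))
        return finish()

    try:
        rotated = apply_fpeak(sol, config.fpeak, cm.X, cm.U)
        record("fpeak", "ok",
               f"phi={config.fpeak:+.2f} dQ={rotated.dq_from_base:.4g}")
    except Exception as exc:  # noqa: BLE001
        record("fpeak", "failed", str(exc))
        rotated = sol

    try:
        scaled = normalize_factors(rotated, config.mass_column)
        write_solution(scaled, outdir, dates=cm.dates,
                       sample_ids=cm.sample_ids)
        record("normalize", "ok",
               f"{scaled.n_factors} factors mass-scaled",
               [outdir / "G.csv", outdir / "F.csv"])
    except Exception as exc:  # noqa: BLE001
        record("normalize", "failed", str(exc))
        return finish()

    try:
        report = diagnose(cm.X, cm.U, scaled,
                          measured_mass=cm.measured_mass)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report.summary(), fh, indent=2, sort_keys=True)
        record("diagnostics", "ok",
               f"coverage3={report.coverage3:.3f} r2={report.r2_mass:.3f}",
               [outdir / "report.json"])
    except Exception as exc:  # noqa: BLE001
        record("diagnostics", "failed", str(exc))

    try:
        mass_cols = [k for k in range(scaled.n_factors)
                     if k not in scaled.flagged_factors]
        table = contribution_frame(scaled.G[:, mass_cols], cm.dates,
                                   labels=[f"factor_{k + 1}" for k in mass_cols])
        table.to_csv(outdir / "contributions.csv", index=False)
        record("contributions", "ok", f"{len(table)} rows",
               [outdir / "contributions.csv"])
    except Exception as exc:  # noqa: BLE001
        record("contributions", "failed", str(exc))

    try:
        if wind is None:
            record("cpf", "skipped", "no wind data configured")
        else:
            files = []
            for k in range(scaled.n_factors):
                series = pd.Series(scaled.G[:, k], index=cm.dates)
                res = cpf_compute(series, wind,
                                  percentile=config.percentile,
                                  calm_cutoff=config.calm_cutoff,
                                  n_sectors=config.n_sectors)
                path = outdir / f"cpf_factor_{k + 1}.csv"
                res.to_frame().to_csv(path, index=False)
                files.append(path)
            record("cpf", "ok", f"{scaled.n_factors} sources", files)
    except Exception as exc:  # noqa: BLE001
        record("cpf", "failed", str(exc))

    if config.make_plots:
        try:
            from . import plots
            files = plots.plot_run(outdir, n_sectors=config.n_sectors)
            record("plots", "ok", f"{len(files)} figures", files)
        except Exception as exc:  # noqa: BLE001
            record("plots", "failed", str(exc))

    assert not np.any([s not in manifest["stages"] for s in STAGES])
    return finish()
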