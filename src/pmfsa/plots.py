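"""Figure helpers: source profiles, mass-reconstruction scatter, CPF roses.

All functions take already-computed tables and write PNG files with the
Agg backend; nothing here recomputes science.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_profile(F, species, path, factor_labels=None):
    """Bar panels: concentration of species (log) and % of species."""
    F = np.asarray(F, dtype=float)
    p, m = F.shape
    if factor_labels is None:
        factor_labels = [f"factor {k + 1}" for k in range(p)]
    colsum = F.sum(axis=0)
    pct = 100.0 * F / np.where(colsum > 0, colsum, np.nan)[None, :]
    fig, axes = plt.subplots(p, 1, figsize=(max(8, 0.35 * m), 1.8 * p),
                             sharex=True, squeeze=False)
    x = np.arange(m)
    for k in range(p):
        ax = axes[k, 0]
        ax.bar(x - 0.2, F[k], width=0.4, color="0.5", label="conc (ug/m3)")
        ax.set_yscale("log")
        ax2 = ax.twinx()
        ax2.bar(x + 0.2, pct[k], width=0.4, color="tab:green",
                label="% of species")
        ax2.set_ylim(0, 100)
        ax.set_ylabel(factor_labels[k], fontsize=8)
    axes[-1, 0].set_xticks(x)
    axes[-1, 0].set_xticklabels(species, rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_mass_scatter(measured, reconstructed, path):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(measured, reconstructed, s=18, alpha=0.7)
    lim = [0, max(np.max(measured), np.max(reconstructed)) * 1.05]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("measured PM2.5 (ug/m3)")
    ax.set_ylabel("reconstructed PM2.5 (ug/m3)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_cpf_rose(cpf_table: pd.DataFrame, path, title=""):
    """Polar CPF plot; north up, clockwise compass convention."""
    theta = np.radians(cpf_table["sector_center_deg"].to_numpy())
    vals = cpf_table["cpf"].to_numpy(dtype=float)
    vals = np.nan_to_num(vals, nan=0.0)
    width = 2 * np.pi / len(theta)
    fig = plt.figure(figsize=(4.5, 4.5))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.bar(theta, vals, width=width * 0.95, alpha=0.8)
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_run(rundir, n_sectors: int = 16):
    """Render the standard figures for a completed pipeline run."""
    rundir = Path(rundir)
    made = []
    f_path = rundir / "F.csv"
    if f_path.exists():
        table = pd.read_csv(f_path)
        conc = table[table["kind"] == "conc_ugm3"]
        species = [c for c in conc.columns if c not in ("factor", "kind")]
        made.append(plot_profile(conc[species].to_numpy(), species,
                                 rundir / "profiles.png",
                                 factor_labels=conc["factor"].tolist()))
    for path in sorted(rundir.glob("cpf_factor_*.csv")):
        made.append(plot_cpf_rose(pd.read_csv(path),
                                  path.with_suffix(".png"),
                                  title=path.stem))
    return made
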