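"""Deterministic report output: parity CSVs, figures, run metadata, manifest.

CSV dialect is comma-separated UTF-8 with '.' decimals and ASCII
hyphen-minus; row and column orders are fixed so repeated runs produce
byte-identical files.  PNG figures are written without software metadata
for the same reason.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .population import RHO2_YY_LEVELS, RHO_XX_LEVELS, round_half_up, table1
from .simulation import SimConfig
from .summarize import SummaryTables

__all__ = ["RunMetadata", "write_records", "write_report", "plot_bias_panels"]

logger = logging.getLogger(__name__)

_STAT_LABELS = {
    "r2s": "squared structure coefficient",
    "R2": "squared multiple correlation",
    "r2xy": "squared validity coefficient",
}


@dataclass(frozen=True)
class RunMetadata:
    """Everything needed to reproduce a run bit-exactly."""

    seed: int
    reps: int
    population_mode: str
    population_size: int
    n_cells: int
    undefined_per_cell: dict[int, int] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    @classmethod
    def from_run(cls, config: SimConfig, records: pd.DataFrame) -> "RunMetadata":
        undef = (
            records[records["predictor"] == 1]
            .groupby("cell_id")["r2s_undefined"]
            .sum()
            .astype(int)
        )
        nonzero = {int(c): int(v) for c, v in undef.items() if v}
        for cell_id, count in nonzero.items():
            logger.warning(
                "cell %d: %d replicate(s) with undefined structure "
                "coefficients", cell_id, count,
            )
        return cls(
            seed=config.seed,
            reps=config.reps,
            population_mode=config.population_mode,
            population_size=config.population_size,
            n_cells=len(config.resolved_cells()),
            undefined_per_cell=nonzero,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_records(
    records: pd.DataFrame, meta: RunMetadata, out_dir: str | Path
) -> dict[str, str]:
    """Write bias records (gzipped CSV) and run metadata (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_path = out / "records.csv.gz"
    # mtime=0 keeps gzip output byte-stable across runs
    records.to_csv(
        rec_path, index=False,
        compression={"method": "gzip", "mtime": 0},
    )
    meta_path = out / "run_metadata.json"
    meta_path.write_text(meta.to_json())
    return {p.name: _sha256(p) for p in (rec_path, meta_path)}


def _fmt(df: pd.DataFrame, decimals: int = 6) -> pd.DataFrame:
    return df.round(decimals)


def write_report(
    tables: SummaryTables,
    meta: RunMetadata,
    out_dir: str | Path,
    figures: bool = True,
) -> dict:
    """Write the parity CSVs, optional figure panels and a hash manifest.

    Returns the manifest mapping file names to SHA-256 hashes, plus a
    completeness flag listing design cells missing from the marginal
    table (a partial-grid run is reported, not hidden).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    files: list[Path] = []

    t1 = table1()
    p = out / "table1.csv"
    t1.to_csv(p, index=False)
    files.append(p)

    means = tables.mean_sd.copy()
    means["mean_2dp"] = [round_half_up(v, 2) for v in means["mean"]]
    means["mean_3dp"] = [round_half_up(v, 3) for v in means["mean"]]
    p = out / "table2_means.csv"
    _fmt(means).to_csv(p)
    files.append(p)

    eta_pct = (tables.eta2 * 100).rename(
        columns=lambda c: c + "_pct"
    )
    p = out / "table2_eta2.csv"
    _fmt(eta_pct, 4).to_csv(p)
    files.append(p)

    props = tables.proportions.copy()
    for col in props.columns:
        if col.startswith("bias_"):
            props[col + "_2dp"] = [round_half_up(v, 2) for v in props[col]]
    p = out / "table3_proportions.csv"
    _fmt(props).to_csv(p, index=False)
    files.append(p)

    p = out / "marginal_means.csv"
    _fmt(tables.marginal, 8).to_csv(p, index=False)
    files.append(p)

    if figures:
        for stat in ("r2s", "R2", "r2xy"):
            for corrected in (False, True):
                suffix = "corrected" if corrected else "uncorrected"
                p = out / f"bias_{stat}_{suffix}.png"
                plot_bias_panels(tables.marginal, stat, corrected, p)
                files.append(p)

    missing = 135 - len(tables.marginal)
    manifest = {
        "files": {f.name: _sha256(f) for f in files},
        "complete_grid": missing == 0,
        "n_cells_reported": int(len(tables.marginal)),
        "metadata": json.loads(meta.to_json()),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def plot_bias_panels(
    marginal: pd.DataFrame,
    stat: str,
    corrected: bool,
    path: str | Path,
) -> None:
    """One figure panel: mean bias faceted by (rho2_yy, rho_xx).

    Within each facet, predictor count k is on the x-axis with one line
    per sample size n.
    """
    col = f"bias_{stat}_{'cor' if corrected else 'unc'}"
    fig, axes = plt.subplots(
        len(RHO2_YY_LEVELS), len(RHO_XX_LEVELS),
        figsize=(10, 8), sharex=True, sharey=True,
    )
    for i, rho2_yy in enumerate(RHO2_YY_LEVELS):
        for j, rho_xx in enumerate(RHO_XX_LEVELS):
            ax = axes[i, j]
            sub = marginal[
                (marginal["rho2_yy"] == rho2_yy)
                & (marginal["rho_xx"] == rho_xx)
            ]
            for n, grp in sub.groupby("n"):
                ax.plot(grp["k"], grp[col], marker="o", label=f"n={n}")
            ax.axhline(0.0, color="grey", lw=0.8)
            ax.axhline(0.01, color="grey", lw=0.5, ls="--")
            ax.axhline(-0.01, color="grey", lw=0.5, ls="--")
            ax.set_title(
                rf"$\rho^2_{{y\hat y}}$={rho2_yy}, $\rho_{{xx}}$={rho_xx}",
                fontsize=9,
            )
            if i == len(RHO2_YY_LEVELS) - 1:
                ax.set_xlabel("k")
            if j == 0:
                ax.set_ylabel("mean bias")
    axes[0, 0].legend(fontsize=7)
    label = _STAT_LABELS[stat]
    fig.suptitle(
        f"Bias of the {'corrected ' if corrected else ''}{label}", fontsize=11
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
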