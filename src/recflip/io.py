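"""Table readers/writers, JSON results, and run manifests.

All tables go out as long-format CSV with an explicit header and a leading
``#`` units comment; floats are written with 12 significant digits so every
file round-trips numerically.  Each table gets a JSON sidecar with the
parameterization and tolerances that produced it.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import CircuitParameters, CircuitTopology
from .steady_state import DoseResponseTable, SweepGrid

__all__ = [
    "write_dose_response_csv",
    "read_dose_response_csv",
    "write_sweep_csv",
    "read_sweep_csv",
    "read_plate_csv",
    "write_json",
    "write_manifest",
]

_FLOAT_FMT = "%.12g"


def _write_csv(df: pd.DataFrame, path, units_comment: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# units: {units_comment}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_dose_response_csv(table: DoseResponseTable, path) -> None:
    df = pd.DataFrame(
        {
            "dose_pct": table.doses,
            "G_ss": table.G_ss,
            "R_ss": table.R_ss,
            "P_LR_ss": table.P_LR_ss,
        }
    )
    df["topology"] = table.topology.value
    df["params_digest"] = table.params_digest
    _write_csv(df, path, "dose_pct in % w/v L-ara; G_ss, R_ss in a.u.; P_LR_ss fraction")


def read_dose_response_csv(path) -> DoseResponseTable:
    df = pd.read_csv(path, comment="#")
    return DoseResponseTable(
        topology=CircuitTopology(df["topology"].iloc[0]),
        doses=df["dose_pct"].to_numpy(),
        G_ss=df["G_ss"].to_numpy(),
        R_ss=df["R_ss"].to_numpy(),
        P_LR_ss=df["P_LR_ss"].to_numpy(),
        params_digest=str(df["params_digest"].iloc[0]),
    )


def write_sweep_csv(grid: SweepGrid, path) -> None:
    """Long format: one row per (swept value, dose)."""
    rows = []
    for i, v in enumerate(grid.swept_values):
        table = grid.tables[i] if grid.tables else None
        for j, dose in enumerate(grid.doses):
            rows.append(
                {
                    "swept_name": grid.swept_name,
                    "swept_value": v,
                    "dose_pct": dose,
                    "G_ss": table.G_ss[j] if table else np.nan,
                    "R_ss": table.R_ss[j] if table else np.nan,
                    "P_LR_ss": table.P_LR_ss[j] if table else np.nan,
                    "G_norm": grid.G_norm_matrix[i, j],
                    "ci": grid.ci_per_value[i],
                }
            )
    _write_csv(
        pd.DataFrame(rows),
        path,
        "dose_pct in % w/v; G_ss, R_ss in a.u.; G_norm, ci dimensionless",
    )


def read_sweep_csv(path) -> SweepGrid:
    df = pd.read_csv(path, comment="#")
    values = df["swept_value"].unique()
    doses = np.sort(df["dose_pct"].unique())
    n_v, n_d = len(values), len(doses)
    piv = df.pivot_table(index="swept_value", columns="dose_pct", values="G_norm", sort=True)
    order = np.argsort(values)
    ci = (
        df.drop_duplicates("swept_value").set_index("swept_value")["ci"].sort_index().to_numpy()
    )
    return SweepGrid(
        swept_name=str(df["swept_name"].iloc[0]),
        swept_values=np.sort(values),
        doses=doses,
        G_norm_matrix=piv.to_numpy().reshape(n_v, n_d),
        ci_per_value=ci,
        tables=[],
    )


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate table (dose_pct, replicate, gfp_au, rfp_au)."""
    df = pd.read_csv(path, comment="#")
    required = {"dose_pct", "gfp_au", "rfp_au"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing column(s): {sorted(missing)}")
    return df


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, CircuitTopology):
            return o.value
        if isinstance(o, CircuitParameters):
            return o.to_dict()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_manifest(outdir, command: str, config: dict, seeds=None, digests=None) -> Path:
    """Echo every effective setting of a run; no silent defaults."""
    manifest = {
        "command": command,
        "recflip_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config,
        "seeds": seeds or {},
        "digests": digests or {},
    }
    path = Path(outdir) / "manifest.json"
    write_json(manifest, path)
    return path
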