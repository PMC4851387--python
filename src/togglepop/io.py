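"""Serialization of states, equilibria, branches, graphs and run manifests."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .continuation import Branch
from .equilibria import EquilibriumRecord
from .models import PopulationSpec
from .params import ModelParams

FLOAT_FMT = "%.12g"   # event localization to 1e-4 must survive serialization


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def save_state_csv(state: np.ndarray, spec: PopulationSpec,
                   path: str | Path) -> None:
    """Per-cell rows (cell_index, x, y, g, r) plus trailing rows for the
    extracellular variables."""
    m = spec.n_cell_vars
    cols = ["x", "y", "g", "r"] if spec.model_id == "S" else ["x", "y", "r"]
    rows = []
    for i in range(spec.N):
        block = state[m * i:m * (i + 1)]
        rows.append({"cell_index": str(i), **dict(zip(cols, block))})
    ext_names = ["g_e", "r_e"] if spec.model_id == "S" else ["r_e"]
    for name, val in zip(ext_names, state[m * spec.N:]):
        rows.append({"cell_index": name, cols[-1]: val})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def load_state_csv(path: str | Path, spec: PopulationSpec) -> np.ndarray:
    df = pd.read_csv(path, dtype={"cell_index": str})
    m = spec.n_cell_vars
    cols = ["x", "y", "g", "r"] if spec.model_id == "S" else ["x", "y", "r"]
    state = np.empty(spec.dim)
    cells = df[~df["cell_index"].isin(["g_e", "r_e"])]
    if len(cells) != spec.N:
        raise ValueError(f"expected {spec.N} cell rows, found {len(cells)}")
    for _, row in cells.iterrows():
        i = int(row["cell_index"])
        state[m * i:m * (i + 1)] = [row[c] for c in cols]
    ext_names = ["g_e", "r_e"] if spec.model_id == "S" else ["r_e"]
    for k, name in enumerate(ext_names):
        sub = df[df["cell_index"] == name]
        if len(sub) != 1:
            raise ValueError(f"missing extracellular row {name}")
        state[m * spec.N + k] = float(sub.iloc[0][cols[-1]])
    return state


def equilibria_to_frame(records: list[EquilibriumRecord]) -> pd.DataFrame:
    rows = []
    for k, rec in enumerate(records):
        rows.append({
            "index": k,
            "signature": rec.signature,
            "stable": rec.stable,
            "residual": rec.residual_norm,
            "leading_re": rec.leading_eigenvalue.real,
            **{v: s for v, s in zip(rec.spec.var_names(), rec.state)},
        })
    return pd.DataFrame(rows)


def branch_to_frame(branch: Branch, spec: PopulationSpec) -> pd.DataFrame:
    names = spec.var_names()
    rows = []
    for i in range(len(branch)):
        row = {branch.param_name: branch.params[i],
               "max_re_lambda": branch.leading_eig[i],
               "stable": branch.stable[i]}
        row.update(dict(zip(names, branch.states[i])))
        rows.append(row)
    return pd.DataFrame(rows)


def events_to_json(branch: Branch) -> list[dict]:
    return [{
        "kind": e.kind,
        "param": branch.param_name,
        "value": e.param_value,
        "localized": e.localized,
        "state": [float(v) for v in e.state],
    } for e in branch.events]


def plot_branch(branch: Branch, spec: PopulationSpec, component: str,
                path: str | Path) -> None:
    """Stability-coded bifurcation diagram (parameter vs one component)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = spec.var_names().index(component)
    ps = np.asarray(branch.params)
    vals = np.array([s[idx] for s in branch.states])
    stable = np.asarray(branch.stable)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ps[stable], vals[stable], "g.", label="stable")
    ax.plot(ps[~stable], vals[~stable], "b.", label="unstable", ms=3)
    for e in branch.events:
        ax.axvline(e.param_value, color="r", ls="--", lw=0.8)
        ax.annotate(e.kind, (e.param_value, vals.mean()))
    ax.set_xlabel(branch.param_name)
    ax.set_ylabel(component)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_manifest(outdir: str | Path, command: str, config: dict,
                   seed: int | None = None) -> Path:
    """Config echo + version + seed, sufficient to reproduce the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package": "togglepop",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": config,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
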