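"""CSV/JSON interchange for the pipeline.

CSV is the single interchange format; every artifact written here is
re-readable by the matching reader.  Schemas:

* traces:   ``well,gene,sample,cycle,fluorescence``  (long, 1-based cycles)
* ct table: ``gene,sample,[bio_rep,tech_rep,]ct``
* primers:  ``gene,efficiency``  (fractional, e.g. 1.028)
* quantification summary:
  ``gene,sample,ct_mean,efficiency,r0,relative_quantity,outlier_excluded``
* expression matrix (long): ``gene,sample,relative_quantity``
* sample annotation: ``sample,group``
* subsets: JSON object ``{subset_name: [sample, ...]}``
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .genorm import GeNormResult
from .normfinder import GroupDesign, NormFinderResult
from .quantify import FluorescenceTrace

__all__ = [
    "read_traces",
    "write_traces",
    "read_ct_table",
    "read_primer_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "read_subsets",
    "write_subsets",
    "write_genorm_result",
    "write_normfinder_result",
    "write_manifest",
]


class SchemaError(ValueError):
    """A CSV is missing required columns or contains invalid rows."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(df.columns)}")


def read_traces(path) -> list[FluorescenceTrace]:
    """Read a long trace CSV into per-well traces."""
    df = pd.read_csv(path)
    _require_columns(df, ["well", "gene", "sample", "cycle", "fluorescence"], path)
    bad = df[df["fluorescence"].isna() | (df["fluorescence"] < 0)]
    if len(bad):
        raise SchemaError(
            f"{path}: invalid fluorescence at row {int(bad.index[0]) + 2}"
        )
    traces = []
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("cycle")
        genes, samples = grp["gene"].unique(), grp["sample"].unique()
        if len(genes) != 1 or len(samples) != 1:
            raise SchemaError(f"{path}: well {well!r} maps to multiple genes/samples")
        traces.append(
            FluorescenceTrace(
                well_id=str(well),
                gene=str(genes[0]),
                sample=str(samples[0]),
                cycles=grp["cycle"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return traces


def write_traces(traces: list[FluorescenceTrace], path) -> None:
    rows = []
    for t in traces:
        for c, f in zip(t.cycles, t.fluorescence):
            rows.append(
                {
                    "well": t.well_id,
                    "gene": t.gene,
                    "sample": t.sample,
                    "cycle": int(c),
                    "fluorescence": f,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    """Ct table with one row per well; bio_rep/tech_rep columns optional."""
    df = pd.read_csv(path)
    _require_columns(df, ["gene", "sample", "ct"], path)
    if df["ct"].isna().any() or (df["ct"] < 0).any():
        row = int(df[df["ct"].isna() | (df["ct"] < 0)].index[0]) + 2
        raise SchemaError(f"{path}: invalid ct at row {row}")
    return df


def read_primer_table(path) -> pd.Series:
    df = pd.read_csv(path)
    _require_columns(df, ["gene", "efficiency"], path)
    return df.set_index("gene")["efficiency"].astype(float)


def read_expression_matrix(path, value_column: str = "relative_quantity") -> pd.DataFrame:
    """Long CSV (gene, sample, value) -> genes x samples wide matrix."""
    df = pd.read_csv(path)
    _require_columns(df, ["gene", "sample", value_column], path)
    wide = df.pivot(index="gene", columns="sample", values=value_column)
    present = wide.stack()
    if (present <= 0).any():
        raise SchemaError(f"{path}: {value_column} values must be positive")
    return wide


def write_expression_matrix(
    m: pd.DataFrame, path, value_column: str = "relative_quantity"
) -> None:
    long = m.stack().rename(value_column).reset_index()
    long.columns = ["gene", "sample", value_column]
    long.to_csv(path, index=False)


def read_annotation(path) -> GroupDesign:
    df = pd.read_csv(path)
    _require_columns(df, ["sample", "group"], path)
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate sample {dup.iloc[0]!r}")
    return GroupDesign(dict(zip(df["sample"].astype(str), df["group"].astype(str))))


def read_subsets(path, known_samples: list[str] | None = None) -> dict[str, list[str]]:
    with open(path) as fh:
        subsets = json.load(fh)
    if not isinstance(subsets, dict):
        raise SchemaError(f"{path}: expected a JSON object of name -> sample list")
    if known_samples is not None:
        known = set(known_samples)
        for name, samples in subsets.items():
            unknown = [s for s in samples if s not in known]
            if unknown:
                raise SchemaError(f"{path}: subset {name!r} names unknown samples {unknown}")
    return {k: list(v) for k, v in subsets.items()}


def write_subsets(subsets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        json.dump(subsets, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_genorm_result(res: GeNormResult, out_dir, prefix: str = "genorm") -> dict:
    """Write ranking CSV (round, gene, M), V-series CSV and JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"round": r, "gene": g, "M": m}
        for r, round_m in enumerate(res.m_trajectory)
        for g, m in sorted(round_m.items(), key=lambda kv: kv[1])
    ]
    pd.DataFrame(rows).to_csv(out_dir / f"{prefix}_ranking.csv", index=False)
    pd.DataFrame(
        [{"n": n, "V": v} for n, v in sorted(res.v_series.items())]
    ).to_csv(out_dir / f"{prefix}_v_series.csv", index=False)
    summary = {
        "ranking_least_stable_first": res.ranking,
        "most_stable_pair": list(res.stable_pair),
        "recommended_n": res.recommended_n,
        "cutoff": res.cutoff,
        "exceeds_cutoff": res.exceeds_cutoff,
        "v_series": {str(n): v for n, v in sorted(res.v_series.items())},
        "final_m": res.final_m(),
        "ties": [list(t) for t in res.ties],
    }
    with open(out_dir / f"{prefix}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    return summary


def write_normfinder_result(res: NormFinderResult, out_dir, prefix: str = "normfinder") -> dict:
    """Write per-gene stability CSV and JSON summary (best gene + pair)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame({"rho": res.rho})
    table["rank"] = table["rho"].rank(method="first").astype(int)
    for g in res.d_raw.columns:
        table[f"d_{g}"] = res.d_raw[g]
        table[f"sigma2_{g}"] = res.sigma2[g]
    table.index.name = "gene"
    table.sort_values("rank").to_csv(out_dir / f"{prefix}_stability.csv")
    summary = {
        "ranking_most_stable_first": res.ranking,
        "best_gene": res.best_gene,
        "best_pair": list(res.best_pair),
        "best_pair_rho": res.best_pair_rho,
        "gamma2": res.gamma2,
        "ungrouped": res.ungrouped,
        "rho": {g: float(v) for g, v in res.rho.items()},
    }
    with open(out_dir / f"{prefix}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    return summary


def write_manifest(out_dir, command: str, params: dict, inputs: list | None = None) -> Path:
    """Run manifest: command, parameters, input hashes, versions, time."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_records = []
    for p in inputs or []:
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
        input_records.append({"path": str(p), "sha256": digest})
    from . import __version__

    manifest = {
        "command": command,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "inputs": input_records,
        "versions": {
            "refstab": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v
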