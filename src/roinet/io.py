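"""Plain-text interchange formats.

Everything the pipeline reads or writes is TSV/CSV/JSON/YAML:

- time-series TSV: one column per ROI label, one row per volume;
- confound TSV: the six motion columns, then the nuisance components;
- connectivity CSV: ROI labels as header row and index column, plus a JSON
  sidecar recording kind/orientation/scale;
- cohort manifest CSV: subject_id, group, tr and relative file paths;
- node-metric TSV and group-stats TSV.

Numbers are serialised with 17 significant digits so a write-read
round-trip is exact for float64. Malformed files raise :class:`FormatError`
naming the file and, where possible, the offending row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MOTION_COLUMNS, ConfoundSet, ConnectivityMatrix, RoiTimeSeries

FLOAT_FORMAT = "%.17g"


class FormatError(ValueError):
    """A file does not conform to its documented format."""


def _read_numeric_table(
    path: Path, sep: str, index_col=None, allow_nan: bool = False
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path, sep=sep, index_col=index_col, float_precision="round_trip")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    for col in non_numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric cell in column {col!r} at data row {row}"
            )
        df[col] = coerced
    if not allow_nan and df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy()][0]
        row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
        raise FormatError(f"{path}: missing value in column {col!r} at data row {row}")
    return df


def write_timeseries(ts: RoiTimeSeries, path: Path) -> None:
    ts.data.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_timeseries(path: Path, tr: float, subject_id: str | None = None) -> RoiTimeSeries:
    df = _read_numeric_table(Path(path), sep="\t")
    return RoiTimeSeries(df, tr=tr, subject_id=subject_id)


def write_confounds(conf: ConfoundSet, path: Path) -> None:
    table = pd.concat([conf.motion, conf.nuisance_components], axis=1)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_confounds(path: Path) -> ConfoundSet:
    df = _read_numeric_table(Path(path), sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing motion columns {missing}")
    motion = df[list(MOTION_COLUMNS)]
    rest = df.drop(columns=list(MOTION_COLUMNS))
    return ConfoundSet(motion=motion, nuisance_components=rest)


def write_matrix(matrix: ConnectivityMatrix, path: Path) -> None:
    """Connectivity CSV (labels as header/index) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.roi_labels, columns=matrix.roi_labels)
    df.to_csv(path, float_format=FLOAT_FORMAT, index_label="roi")
    sidecar = {
        "kind": matrix.kind,
        "is_z": matrix.is_z,
        "n_clipped": matrix.n_clipped,
        "orientation": "rows = seed/predictor, columns = target"
        if matrix.kind == "EFF"
        else "symmetric",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise FormatError(f"{path}: row and column labels differ")
    return ConnectivityMatrix(
        df.to_numpy(dtype=float),
        kind=sidecar["kind"],
        roi_labels=labels,
        is_z=bool(sidecar.get("is_z", False)),
        n_clipped=int(sidecar.get("n_clipped", 0)),
    )


def write_manifest(rows: list[dict], path: Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path)
    required = {"subject_id", "group", "tr", "timeseries_path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    base = path.parent
    for _, row in df.iterrows():
        ts_path = base / row["timeseries_path"]
        if not ts_path.exists():
            raise FormatError(
                f"{path}: subject {row['subject_id']}: "
                f"time-series file {ts_path} does not exist"
            )
    return df


def write_metric_table(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="roi")


def read_metric_table(path: Path) -> pd.DataFrame:
    # NaN allowed: average path length is undefined for isolated nodes
    return _read_numeric_table(Path(path), sep="\t", index_col=0, allow_nan=True)


def write_stats_table(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_config(cfg: dict, path: Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=1, sort_keys=True))


def read_config(path: Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
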