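"""CSV/TSV readers and writers plus run configuration handling."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .knockoffs import DesignMatrix

__all__ = [
    "RunConfig",
    "read_matrix",
    "read_response",
    "write_matrix",
    "write_selection",
    "write_study",
]


@dataclass
class RunConfig:
    """Resolved settings of one selection or simulation run.

    File values (flat YAML or JSON) are overridden by CLI flags; the full
    resolved config is embedded in every output for provenance.
    """

    task: str = "auto"
    q: float = 0.1
    statistic: str = "shap_diff"
    s_method: str = "equi"
    shrinkage: str = "auto"
    booster: str = "lightgbm"
    tune_budget: int = 0
    seed: int = 0
    x_path: str | None = None
    y_path: str | None = None
    out_path: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def updated(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_matrix(
    path: str | Path,
    orientation: str = "samples_by_features",
    delimiter: str | None = None,
) -> DesignMatrix:
    """Read a numeric design matrix from CSV/TSV.

    The first row is used as a header when it is non-numeric; otherwise
    names V1..Vp are generated.  ``features_by_samples`` input is transposed
    on read.  Non-numeric cells raise with their row/column location.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter(path, delimiter)
    try:
        raw = pd.read_csv(
            path, sep=sep, header=None, dtype=str, skipinitialspace=True, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if raw.empty:
        raise ValueError(f"{path}: empty file")

    first = raw.iloc[0]
    has_header = not first.map(_is_number).all()
    if has_header:
        names = [str(v) for v in first]
        body = raw.iloc[1:].reset_index(drop=True)
        header_rows = 1
    else:
        names = None
        body = raw
        header_rows = 0

    values = np.empty(body.shape, dtype=float)
    for i in range(body.shape[0]):
        for j in range(body.shape[1]):
            cell = body.iat[i, j]
            if cell is None or not _is_number(cell):
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 1 + header_rows}, column {j + 1}"
                )
            values[i, j] = float(cell)

    if orientation == "features_by_samples":
        # a header row names samples, not features, so names are regenerated
        return DesignMatrix(values=values.T, feature_names=None)
    return DesignMatrix(values=values, feature_names=names)


def _is_number(cell) -> bool:
    try:
        float(cell)
        return True
    except (TypeError, ValueError):
        return False


def read_response(path: str | Path, task: str = "regression") -> tuple[np.ndarray, dict | None]:
    """Read a single-column response; returns (vector, label_mapping).

    Regression responses become floats; classification labels are mapped to
    0..k-1 (lexicographic order) with the mapping returned so callers can
    report results in original label terms.
    """
    sep = _delimiter(path, None)
    try:
        raw = pd.read_csv(
            path, sep=sep, header=None, dtype=str, skipinitialspace=True, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty response file") from None
    if raw.empty:
        raise ValueError(f"{path}: empty response file")
    col = raw.iloc[:, 0]
    # a header is a lone non-numeric first cell above numeric data; an all-text
    # column is a label column, not a header
    if len(col) > 1 and not _is_number(col.iloc[0]) and _is_number(col.iloc[1]):
        col = col.iloc[1:].reset_index(drop=True)
    if col.empty:
        raise ValueError(f"{path}: response has no data rows")

    if task == "regression":
        bad = [v for v in col if not _is_number(v)]
        if bad:
            raise ValueError(f"{path}: non-numeric response value {bad[0]!r}")
        return col.astype(float).to_numpy(), None

    labels = sorted(col.unique(), key=lambda v: (not _is_number(v), str(v)))
    if len(labels) > 20:
        raise ValueError(
            f"{path}: {len(labels)} distinct labels; did you mean a regression task?"
        )
    mapping = {lab: i for i, lab in enumerate(labels)}
    return col.map(mapping).to_numpy(dtype=float), mapping


def write_matrix(x: DesignMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = _delimiter(path, delimiter)
    pd.DataFrame(x.values, columns=x.feature_names).to_csv(path, sep=sep, index=False)


def write_selection(result, config: RunConfig, path: str | Path) -> None:
    """SelectionResult -> JSON with full config and package version embedded."""
    from . import __version__

    payload = result.to_dict()
    payload["config"] = config.to_dict()
    payload["package_version"] = __version__
    Path(path).write_text(json.dumps(payload, indent=2))


def write_study(study, config: RunConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """StudyResult -> tidy per-rep CSV plus a JSON summary."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{study.scenario.kind}_{study.method}_reps.csv"
    study.to_frame().to_csv(csv_path, index=False)
    summary = study.summary()
    summary["config"] = config.to_dict()
    summary["package_version"] = __version__
    json_path = out / f"{study.scenario.kind}_{study.method}_summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return csv_path, json_path
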