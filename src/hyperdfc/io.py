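"""Delimited-text file formats.

Regional time series travel as TSV (rows = time points, columns = regions,
header row of region ids) with a YAML sidecar run manifest (task label,
n_volumes, sampling_period per run).  Measure tables are CSV with a
category-map CSV; hypergraphs are written as membership, metrics, and
node-degree CSVs with 0-based ids documented in the header comment.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dfc import EdgeIndexMap, RegionalTimeSeries
from .hypergraph import Hypergraph, NodeDegreeProfile
from .indiff import MeasureTable, RegressionResult

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "manifest_path",
    "write_measure_table",
    "read_measure_table",
    "write_hypergraph",
    "write_node_degree",
    "write_window_labels",
    "write_regression_result",
    "write_r2_changes",
]


def manifest_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".manifest.yaml")


def write_timeseries(series: RegionalTimeSeries, path: str | Path) -> Path:
    """TSV with a region-id header, plus the sidecar run manifest."""
    path = Path(path)
    header = "\t".join(f"region_{i}" for i in range(series.n_regions))
    np.savetxt(path, series.values, delimiter="\t", header=header, comments="")
    starts = (0,) + series.run_boundaries[:-1]
    runs = [
        {
            "task": task,
            "n_volumes": int(stop - start),
            "sampling_period": float(tr),
        }
        for task, tr, start, stop in zip(
            series.task_labels, series.sampling_period, starts, series.run_boundaries
        )
    ]
    manifest_path(path).write_text(yaml.safe_dump({"runs": runs}, sort_keys=False))
    return path


def read_timeseries(path: str | Path, manifest: str | Path | None = None) -> RegionalTimeSeries:
    """Read a TSV + run-manifest pair, validating shape against the manifest.

    Errors name the offending line for ragged rows and the row/column for
    non-numeric cells; a manifest whose volume total disagrees with the row
    count is rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    n_regions = len(header)
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n_regions:
            raise ValueError(
                f"{path}: line {lineno} has {len(cells)} columns, expected {n_regions}"
            )
        row = []
        for col, cell in enumerate(cells):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at line {lineno}, "
                    f"column {col + 1} ({header[col]}): {cell!r}"
                ) from None
        rows.append(row)
    values = np.asarray(rows)
    mpath = Path(manifest) if manifest is not None else manifest_path(path)
    spec = yaml.safe_load(mpath.read_text())
    runs = spec["runs"]
    boundaries = np.cumsum([int(r["n_volumes"]) for r in runs])
    if boundaries[-1] != values.shape[0]:
        raise ValueError(
            f"{mpath}: manifest totals {boundaries[-1]} volumes but "
            f"{path} has {values.shape[0]} rows"
        )
    return RegionalTimeSeries(
        values,
        tuple(float(r["sampling_period"]) for r in runs),
        tuple(int(b) for b in boundaries),
        tuple(str(r["task"]) for r in runs),
    )


def write_measure_table(table: MeasureTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index_label="subject")
    cat = pd.DataFrame(
        {"measure": list(table.category_of), "category": list(table.category_of.values())}
    )
    cat.to_csv(path.with_suffix(".categories.csv"), index=False)
    return path


def read_measure_table(path: str | Path, category_map: str | Path | None = None) -> MeasureTable:
    path = Path(path)
    data = pd.read_csv(path, index_col="subject")
    cpath = Path(category_map) if category_map else path.with_suffix(".categories.csv")
    cats = pd.read_csv(cpath)
    return MeasureTable(data, dict(zip(cats["measure"], cats["category"])))


def write_hypergraph(
    hg: Hypergraph, index: EdgeIndexMap, path: str | Path
) -> Path:
    """Membership CSV: one row per member edge of each non-singleton
    hyperedge (0-based hyperedge id, edge id, node i, node j)."""
    path = Path(path)
    records = []
    for hid, h in enumerate(hg.hyperedges):
        for edge_id in sorted(h.edge_ids):
            i, j = index.pair_of(edge_id)
            records.append((hid, edge_id, i, j))
    df = pd.DataFrame(records, columns=["hyperedge_id", "edge_id", "node_i", "node_j"])
    with open(path, "w") as fh:
        fh.write("# 0-based hyperedge, edge, and node ids\n")
        df.to_csv(fh, index=False)
    return path


def write_node_degree(profile: NodeDegreeProfile, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"region": np.arange(profile.degree.size), "hyperedge_degree": profile.degree}
    )
    with open(path, "w") as fh:
        fh.write("# 0-based region ids\n")
        df.to_csv(fh, index=False)
    return path


def write_window_labels(window_task, path: str | Path) -> Path:
    """Per-window task labels (one row per window, 0-based window ids)."""
    path = Path(path)
    pd.DataFrame(
        {"window": np.arange(len(window_task)), "task": list(window_task)}
    ).to_csv(path, index=False)
    return path


def write_r2_changes(result: RegressionResult, path: str | Path) -> Path:
    """Tidy CSV of per-category R^2 changes (raw and normalized)."""
    path = Path(path)
    pd.DataFrame(
        {
            "category": list(result.r2_change),
            "r2_change": list(result.r2_change.values()),
            "normalized_r2_change": [
                result.normalized_r2_change[c] for c in result.r2_change
            ],
        }
    ).to_csv(path, index=False)
    return path


def write_regression_result(result: RegressionResult, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "coefficients": result.coefficients.to_dict(),
        "p_values": result.p_values.to_dict(),
        "r_squared": result.r_squared,
        "r2_change": result.r2_change,
        "normalized_r2_change": result.normalized_r2_change,
        "significant": {k: bool(v) for k, v in result.significant.items()},
        "bonferroni_m": result.bonferroni_m,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
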