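"""File formats: TSV tables for all tabular artifacts, npz checkpoints.

Conventions: tab-delimited UTF-8 with '.' decimal, 0-based ROI and node
indices everywhere.  Time-series files carry their record metadata in
``# key=value`` comment lines so a write/read round trip reproduces both
values (to full printed precision) and metadata exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fc_graph import FcMatrix, KnnGraph, RoiTimeSeries
from .nn import CgcnConfig, CgcnModel
from .saliency import SaliencyMap

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_manifest",
    "read_manifest",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_graph",
    "read_graph",
    "write_saliency",
    "save_checkpoint",
    "load_checkpoint",
]

_META_KEYS = ("subject_id", "session_id", "class_label", "site_label")


def write_timeseries(record: RoiTimeSeries, path: str | Path) -> None:
    """Write one record as TSV: metadata comments, ROI-label header, frame rows."""
    path = Path(path)
    n = record.n_rois
    with path.open("w", encoding="utf-8") as fh:
        for key in _META_KEYS:
            fh.write(f"# {key}={getattr(record, key)}\n")
        fh.write("\t".join(f"roi{j}" for j in range(n)) + "\n")
        for row in record.signals:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_timeseries(path: str | Path) -> RoiTimeSeries:
    """Read a time-series TSV written by :func:`write_timeseries`.

    Files without metadata comments or header still parse: ROIs are then
    labeled by 0-based column index and metadata fields are empty strings.
    Ragged or non-numeric rows raise with the offending 1-based line number.
    """
    path = Path(path)
    meta = {k: "" for k in _META_KEYS}
    rows: list[list[float]] = []
    width = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    if key.strip() in meta:
                        meta[key.strip()] = value.strip()
                continue
            cells = line.split("\t")
            try:
                values = [float(c) for c in cells]
            except ValueError:
                if not rows and width is None:
                    width = len(cells)  # header row of ROI labels
                    continue
                raise ValueError(f"{path}: non-numeric cell at line {lineno}")
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(values)} cells, expected {width})"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    label = meta["class_label"]
    try:
        label = int(label)
    except ValueError:
        pass
    return RoiTimeSeries(
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        class_label=label,
        site_label=meta["site_label"],
        signals=np.array(rows),
    )


def write_manifest(records: list[RoiTimeSeries], paths: list[str | Path],
                   manifest_path: str | Path) -> None:
    rows = []
    for record, p in zip(records, paths):
        rows.append({
            "record_path": str(p),
            "subject_id": record.subject_id,
            "session_id": record.session_id,
            "class_label": record.class_label,
            "site_label": record.site_label,
            "n_frames": record.n_frames,
            "n_rois": record.n_rois,
        })
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)


def read_manifest(manifest_path: str | Path, load: bool = True
                  ) -> list[RoiTimeSeries] | pd.DataFrame:
    """Load a manifest; with ``load=True`` also read every referenced record."""
    table = pd.read_csv(manifest_path, sep="\t")
    if table["n_rois"].nunique() > 1:
        raise ValueError("manifest rows disagree on n_rois")
    base = Path(manifest_path).parent
    if not load:
        return table
    records = []
    for _, row in table.iterrows():
        p = Path(row["record_path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file {p}")
        records.append(read_timeseries(p))
    return records


def write_fc_matrix(fc: FcMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(fc.values,
                         columns=[str(j) for j in range(fc.n_rois)])
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# n_records_averaged={fc.n_records_averaged}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_fc_matrix(path: str | Path) -> FcMatrix:
    n_avg = 1
    with Path(path).open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            n_avg = int(first.partition("=")[2])
            table = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            table = pd.read_csv(fh, sep="\t")
    return FcMatrix(values=table.to_numpy(), n_records_averaged=n_avg)


def write_graph(graph: KnnGraph, path: str | Path) -> None:
    """Edge-list TSV: one row per directed edge (source, target, rank, fc_value)."""
    rows = []
    for i in range(graph.n_nodes):
        for rank in range(graph.k):
            value = (float(graph.edge_values[i, rank])
                     if graph.edge_values is not None else float("nan"))
            rows.append({"source": i, "target": int(graph.neighbors[i, rank]),
                         "rank": rank, "fc_value": value})
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# n_nodes={graph.n_nodes}\tk={graph.k}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_graph(path: str | Path) -> KnnGraph:
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing graph header line")
        parts = dict(p.split("=") for p in header[1:].strip().split("\t"))
        n, k = int(parts["n_nodes"]), int(parts["k"])
        table = pd.read_csv(fh, sep="\t")
    neighbors = np.empty((n, k), dtype=np.int64)
    values = np.full((n, k), np.nan)
    for _, row in table.iterrows():
        neighbors[int(row["source"]), int(row["rank"])] = int(row["target"])
        values[int(row["source"]), int(row["rank"])] = row["fc_value"]
    edge_values = None if np.all(np.isnan(values)) else values
    return KnnGraph(n_nodes=n, k=k, neighbors=neighbors, edge_values=edge_values)


def write_saliency(saliency: SaliencyMap, path: str | Path,
                   roi_labels: list[str] | None = None) -> None:
    """Saliency TSV sorted by accuracy drop, largest first."""
    n = saliency.n_rois
    labels = roi_labels if roi_labels is not None else [f"roi{j}" for j in range(n)]
    order = np.argsort(-saliency.per_roi_drop, kind="stable")
    rows = [{"roi_index": int(j), "roi_label": labels[j],
             "accuracy_drop": saliency.per_roi_drop[j]} for j in order]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# baseline_accuracy={saliency.baseline_accuracy!r}"
                 f"\tn_records={saliency.n_records}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def save_checkpoint(model: CgcnModel, path: str | Path, classes: list | None = None) -> None:
    """Single-archive checkpoint: config, graph, parameters, BN buffers.

    Reloading reproduces forward outputs bit-identically on the same
    platform (all arrays are stored at full precision).
    """
    arrays = {f"param/{k}": v for k, v in model.params.items()}
    arrays.update({f"buffer/{k}": v for k, v in model.buffers.items()})
    arrays["graph/neighbors"] = model.graph.neighbors
    if model.graph.edge_values is not None:
        arrays["graph/edge_values"] = model.graph.edge_values
    meta = {"config": json.loads(model.config.to_json()),
            "n_nodes": model.graph.n_nodes, "k": model.graph.k,
            "classes": [repr(c) for c in (classes or [])],
            "classes_raw": classes if classes is not None else []}
    arrays["meta"] = np.frombuffer(json.dumps(meta, default=str).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[CgcnModel, list]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = CgcnConfig.from_json(json.dumps(meta["config"]))
        graph = KnnGraph(
            n_nodes=int(meta["n_nodes"]), k=int(meta["k"]),
            neighbors=data["graph/neighbors"],
            edge_values=data["graph/edge_values"] if "graph/edge_values" in data else None,
        )
        params = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        buffers = {k[len("buffer/"):]: data[k] for k in data.files if k.startswith("buffer/")}
        classes = meta.get("classes_raw", [])
    return CgcnModel(config, graph, params, buffers), classes
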