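"""Serialization: edge lists, delimited response tables, JSON manifests."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .generation import WeightedNetwork

__all__ = [
    "write_edge_list", "read_edge_list", "write_responses", "read_responses",
    "write_json", "read_json",
]

MISSING_SENTINELS = {"", "NA"}


def write_edge_list(network, path: str | Path, metadata: dict | None = None) -> None:
    """Tab-separated ``node_i  node_j  weight`` lines; optional JSON sidecar."""
    w = np.asarray(network.weight_matrix)
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        k = w.shape[0]
        for i in range(k):
            for j in range(i + 1, k):
                if w[i, j] != 0:
                    writer.writerow([i, j, repr(float(w[i, j]))])
    if metadata is not None:
        write_json(metadata, path.with_suffix(path.suffix + ".json"))


def read_edge_list(path: str | Path, k_nodes: int | None = None) -> WeightedNetwork:
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if line.strip():
                i, j, wij = line.split("\t")
                rows.append((int(i), int(j), float(wij)))
    k = k_nodes if k_nodes is not None else (
        max(max(i, j) for i, j, _ in rows) + 1 if rows else 0)
    w = np.zeros((k, k))
    for i, j, wij in rows:
        w[i, j] = w[j, i] = wij
    return WeightedNetwork(k_nodes=k, weight_matrix=w)


def write_responses(responses: np.ndarray, path: str | Path,
                    columns: list[str] | None = None) -> None:
    responses = np.asarray(responses)
    cols = columns or [f"item_{i}" for i in range(responses.shape[1])]
    pd.DataFrame(responses, columns=cols).to_csv(path, sep="\t", index=False)


def read_responses(path: str | Path, dropna: bool = True) -> tuple[np.ndarray, list[str]]:
    """Read a delimited survey table (TSV/CSV sniffed); casewise deletion.

    Rows with any missing value (empty field or "NA") are dropped, with the
    count reported via the returned frame's attrs.
    """
    path = Path(path)
    with path.open() as fh:
        sample_text = fh.read(4096)
    delim = "\t" if sample_text.count("\t") >= sample_text.count(",") else ","
    df = pd.read_csv(path, sep=delim, na_values=list(MISSING_SENTINELS))
    n_before = len(df)
    if dropna:
        df = df.dropna()
        n_dropped = n_before - len(df)
        if n_dropped:
            import logging

            logging.getLogger(__name__).info(
                "casewise deletion: dropped %d of %d rows", n_dropped, n_before)
    return df.to_numpy(), list(df.columns)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
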