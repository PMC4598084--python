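"""Plain-text file formats shared across the package.

Histogram files are two-column tab-separated (repeat_number, count) with a
header line; bout-count files carry one integer repeat number per line;
rasters are tab-separated (time_ms, neuron_id) with a JSON sidecar mapping
neuron ids to (chain, pool).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .repeat_model import RepeatHistogram

__all__ = [
    "write_histogram",
    "read_histogram",
    "write_bout_counts",
    "read_bout_counts",
    "write_raster",
    "read_raster",
    "write_json",
]


def write_histogram(hist: RepeatHistogram, path) -> None:
    df = pd.DataFrame(
        sorted(hist.counts.items()), columns=["repeat_number", "count"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_histogram(path) -> RepeatHistogram:
    df = pd.read_csv(path, sep="\t")
    counts = dict(zip(df["repeat_number"].astype(int), df["count"].astype(int)))
    return RepeatHistogram(counts=counts)


def write_bout_counts(repeat_numbers, path) -> None:
    arr = np.asarray(repeat_numbers, dtype=int)
    Path(path).write_text("\n".join(str(int(n)) for n in arr) + "\n")


def read_bout_counts(path) -> RepeatHistogram:
    arr = np.array(
        [int(line) for line in Path(path).read_text().split() if line.strip()]
    )
    return RepeatHistogram.from_bouts(arr)


def write_raster(times_ms, neuron_ids, id_map: dict, path) -> None:
    """Raster as TSV plus a JSON sidecar mapping ids to (chain, pool)."""
    df = pd.DataFrame({"time_ms": times_ms, "neuron_id": neuron_ids})
    df.to_csv(path, sep="\t", index=False)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({str(k): v for k, v in id_map.items()}, indent=1))


def read_raster(path):
    df = pd.read_csv(path, sep="\t")
    sidecar = Path(str(path) + ".json")
    id_map = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df, id_map


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default) + "\n")
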