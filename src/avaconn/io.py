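"""Readers and writers for the pipeline's on-disk formats.

Matrices (time series, connectomes, transition matrices) travel as
tab-delimited text with region labels, or as NumPy ``.npz`` containers for
bulk raster data.  Tables (avalanche catalogues, coupling results,
perturbation logs) are tab-delimited with headers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import Avalanche, StructuralConnectome, TransitionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_connectome",
    "write_connectome",
    "read_timeseries",
    "write_timeseries",
    "write_tm",
    "read_tm",
    "write_avalanche_catalogue",
    "write_avalanche_rasters",
    "read_avalanche_rasters",
    "write_table",
]


def write_matrix(path, values: np.ndarray, labels: Sequence[str] = None) -> None:
    """Write a 2-D matrix as TSV (row index = labels when given)."""
    df = pd.DataFrame(np.asarray(values), index=labels)
    df.to_csv(path, sep="\t", header=False)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a TSV matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def write_connectome(path, sc: StructuralConnectome) -> None:
    write_matrix(path, sc.weights, sc.region_labels)


def read_connectome(path) -> StructuralConnectome:
    w, labels = read_matrix(path)
    return StructuralConnectome(weights=w, region_labels=labels)


def write_timeseries(path, ts: np.ndarray, labels: Sequence[str] = None) -> None:
    """Write a regions x samples series; ``.npz`` suffix selects the binary
    container, anything else tab-delimited text."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, values=np.asarray(ts), labels=np.asarray(labels or [], dtype=str)
        )
    else:
        write_matrix(path, ts, labels)


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            values = z["values"]
            labels = [str(x) for x in z["labels"]] or None
        if labels is None:
            labels = [f"R{i:03d}" for i in range(values.shape[0])]
        return values.astype(float), labels
    return read_matrix(path)


def write_tm(path, tm: TransitionMatrix) -> None:
    """TM probabilities as TSV plus a sidecar ``<path>.counts.tsv`` with the
    per-entry support (ancestor counts or contributing-input counts)."""
    write_matrix(path, tm.probs, tm.region_labels)
    support = tm.ancestor_counts if tm.ancestor_counts is not None else tm.n_contributing
    if support is not None:
        write_matrix(str(path) + ".counts.tsv", support, tm.region_labels)


def read_tm(path, level: str = "group", symmetrized: bool = True) -> TransitionMatrix:
    probs, labels = read_matrix(path)
    return TransitionMatrix(
        probs=probs, level=level, symmetrized=symmetrized, region_labels=labels
    )


def write_avalanche_catalogue(path, avalanches: Sequence[Avalanche]) -> None:
    """Catalogue columns: avalanche_id, start_bin, end_bin, duration, size."""
    rows = [
        {
            "avalanche_id": i,
            "start_bin": av.start_bin,
            "end_bin": av.end_bin,
            "duration": av.duration,
            "size": av.size,
        }
        for i, av in enumerate(avalanches)
    ]
    pd.DataFrame(
        rows, columns=["avalanche_id", "start_bin", "end_bin", "duration", "size"]
    ).to_csv(path, sep="\t", index=False)


def write_avalanche_rasters(path, avalanches: Sequence[Avalanche]) -> None:
    """Per-avalanche boolean rasters in one ``.npz`` container."""
    arrays = {f"raster_{i:06d}": av.raster for i, av in enumerate(avalanches)}
    arrays.update(
        {f"events_{i:06d}": av.events_per_bin for i, av in enumerate(avalanches)}
    )
    starts = np.array([av.start_bin for av in avalanches], dtype=np.int64)
    np.savez_compressed(path, start_bins=starts, **arrays)


def read_avalanche_rasters(path) -> list[Avalanche]:
    with np.load(path, allow_pickle=False) as z:
        starts = z["start_bins"]
        avalanches = []
        for i, s in enumerate(starts):
            raster = z[f"raster_{i:06d}"]
            events = z[f"events_{i:06d}"]
            avalanches.append(
                Avalanche(
                    raster=raster,
                    start_bin=int(s),
                    events_per_bin=events,
                )
            )
    return avalanches


def write_table(path, df: pd.DataFrame) -> None:
    if not isinstance(df, pd.DataFrame):
        raise ParameterError("write_table expects a DataFrame")
    df.to_csv(path, sep="\t", index=False)
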