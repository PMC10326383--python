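"""Readers and writers for matrices, time series, manifests, checkpoints.

On-disk formats: connectivity matrices as headerless R×R CSV or as HDF5
datasets (one dataset per modality); regional time series as TSV with
the region label in the first column and timepoints in the remaining
columns; the dataset manifest as a JSON array of records

    {"subject_id": ..., "label": 0/1, "brain_volume": ...,
     "matrices": {"functional": path, "structural": path}}

with paths relative to the manifest's directory.  Network checkpoints
are NPZ archives of named weight arrays plus a JSON sidecar holding the
config and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .network_construction import (ConnectivityMatrix, MultiModalSample,
                                   TimeSeriesSet)

logger = logging.getLogger(__name__)


def save_matrix_csv(path, matrix: np.ndarray):
    np.savetxt(path, np.asarray(matrix), delimiter=",")


def load_matrix_csv(path) -> np.ndarray:
    m = np.loadtxt(path, delimiter=",", ndmin=2)
    logger.debug("read %dx%d matrix from %s", m.shape[0], m.shape[1], path)
    return m


def save_matrix_hdf5(path, matrix: np.ndarray, dataset: str):
    with h5py.File(path, "a") as f:
        if dataset in f:
            del f[dataset]
        f.create_dataset(dataset, data=np.asarray(matrix))


def load_matrix_hdf5(path, dataset: str) -> np.ndarray:
    with h5py.File(path, "r") as f:
        m = np.asarray(f[dataset])
    logger.debug("read %dx%d matrix from %s:%s", m.shape[0], m.shape[1],
                 path, dataset)
    return m


def load_matrix(path) -> np.ndarray:
    """Dispatch on extension: ``.h5``/``.hdf5`` (dataset after '#') or CSV."""
    spath = str(path)
    if "#" in spath:
        fpath, dataset = spath.rsplit("#", 1)
        return load_matrix_hdf5(fpath, dataset)
    if spath.endswith((".h5", ".hdf5")):
        raise ValueError("HDF5 paths must name a dataset as file.h5#dataset")
    return load_matrix_csv(spath)


def read_timeseries(path, subject_id: str) -> TimeSeriesSet:
    """TSV/CSV, rows = regions, first column = region label."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, header=None)
    regions = df.iloc[:, 0].astype(str).tolist()
    series = df.iloc[:, 1:].to_numpy(dtype=float)
    logger.info("read time series %s: %d regions x %d timepoints",
                path, series.shape[0], series.shape[1])
    return TimeSeriesSet(subject_id, regions, series)


def write_timeseries(path, ts: TimeSeriesSet):
    df = pd.DataFrame(ts.series, index=ts.regions)
    df.to_csv(path, sep="\t", header=False)


def write_manifest(path, records: list[dict]):
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def load_manifest(path) -> list[dict]:
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise ValueError("manifest must be a JSON array of subject records")
    logger.info("manifest %s: %d records", path, len(records))
    return records


def save_samples(out_dir, samples: list[MultiModalSample],
                 manifest_name: str = "manifest.json") -> Path:
    """Write each channel as CSV plus a manifest; returns the manifest path.

    Augmented variants carry their shift count in the file name, e.g.
    ``sub0001_s3_functional.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for s in samples:
        rec = {"subject_id": s.subject_id, "label": int(s.label),
               "is_original": bool(s.is_original), "shift": int(s.shift),
               "matrices": {}}
        for c in s.channels:
            fname = f"{s.subject_id}_s{s.shift}_{c.modality}.csv"
            save_matrix_csv(out / fname, c.matrix)
            rec["matrices"][c.modality] = fname
        records.append(rec)
    mpath = out / manifest_name
    write_manifest(mpath, records)
    return mpath


def load_samples(manifest_path) -> list[MultiModalSample]:
    base = Path(manifest_path).parent
    samples = []
    for rec in load_manifest(manifest_path):
        chans = []
        for modality, rel in rec["matrices"].items():
            m = load_matrix(base / rel)
            chans.append(ConnectivityMatrix(rec["subject_id"], modality, m))
        samples.append(MultiModalSample(
            rec["subject_id"], chans, int(rec["label"]),
            is_original=bool(rec.get("is_original", True)),
            shift=int(rec.get("shift", 0))))
    return samples


def save_checkpoint(path, networks: dict, meta: dict):
    """NPZ of '<net>.<param>' arrays + '<path>.json' config sidecar."""
    arrays = {}
    for net_name, net in networks.items():
        for k, v in net.state_arrays().items():
            arrays[f"{net_name}.{k}"] = v
    np.savez(path, **arrays)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1) + "\n")


def load_checkpoint(path) -> tuple[dict, dict]:
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(Path(str(path) + ".json").read_text())
    return arrays, meta


def restore_network(net, arrays: dict, prefix: str):
    state = {k[len(prefix) + 1:]: v for k, v in arrays.items()
             if k.startswith(prefix + ".")}
    net.load_state_arrays(state)
    return net
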