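"""Reading and writing snapshot datasets as plain CSV with a manifest.

A dataset on disk is a directory of per-snapshot CSV files (rows = cells,
columns = features) plus ``manifest.csv`` with columns
``time,file,n_cells,sampling_fraction``.  Sampling fractions feed the
relative-population calculation (sequential-harvest designs); fractions of
1 mean counts are proportional to population.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Snapshot, TimeSeriesDataset
from .density import relative_populations


@dataclass
class ManifestEntry:
    time: float
    path: Path
    n_cells: int
    sampling_fraction: float = 1.0


def write_dataset(dataset: TimeSeriesDataset, outdir, truth=None,
                  feature_names=None) -> Path:
    """Write one CSV per snapshot plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = dataset.n_features
    cols = feature_names or [f"x{j}" for j in range(d)]
    rows = []
    for i, snap in enumerate(dataset):
        fname = f"snapshot_{i:02d}.csv"
        pd.DataFrame(snap.X, columns=cols).to_csv(outdir / fname, index=False)
        rows.append({"time": snap.time, "file": fname,
                     "n_cells": snap.n_cells, "sampling_fraction": 1.0})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if truth is not None:
        gt_rows = []
        for i, (labels, gp) in enumerate(zip(truth.group_labels, truth.division_probs)):
            for j, (lab, g) in enumerate(zip(labels, gp)):
                gt_rows.append({"snapshot": i, "cell": j, "group": lab,
                                "division_prob": g})
        pd.DataFrame(gt_rows).to_csv(outdir / "ground_truth.csv", index=False)
    return manifest


def validate_manifest(manifest_path) -> list[str]:
    """Structural checks; returns a list of human-readable findings."""
    manifest_path = Path(manifest_path)
    findings: list[str] = []
    if not manifest_path.exists():
        return [f"manifest not found: {manifest_path}"]
    mf = pd.read_csv(manifest_path)
    required = {"time", "file"}
    missing = required - set(mf.columns)
    if missing:
        return [f"manifest missing columns: {sorted(missing)}"]
    times = mf["time"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        findings.append("times not strictly increasing")
    ncols = None
    for _, row in mf.iterrows():
        fpath = manifest_path.parent / row["file"]
        if not fpath.exists():
            findings.append(f"missing snapshot file: {row['file']}")
            continue
        df = pd.read_csv(fpath)
        if ncols is None:
            ncols = df.shape[1]
        elif df.shape[1] != ncols:
            findings.append(
                f"{row['file']}: {df.shape[1]} columns, expected {ncols}"
            )
        nan_rows, nan_cols = np.nonzero(df.isna().to_numpy())
        for r, c in zip(nan_rows, nan_cols):
            findings.append(f"NaN at ({row['file']}, row {r}, col {df.columns[c]})")
    return findings


def read_manifest(manifest_path, mass_mode: str = "equal_culture") -> TimeSeriesDataset:
    """Load a dataset from its manifest.

    mass_mode: 'equal_culture' (mass proportional to counts),
    'sequential_harvest' (use sampling fractions), or 'explicit' (manifest
    has a relative_population column).
    """
    manifest_path = Path(manifest_path)
    findings = validate_manifest(manifest_path)
    if findings:
        raise ValueError("invalid manifest: " + "; ".join(findings))
    mf = pd.read_csv(manifest_path)
    mats = [
        pd.read_csv(manifest_path.parent / f).to_numpy(dtype=float)
        for f in mf["file"]
    ]
    counts = np.array([m.shape[0] for m in mats])
    if mass_mode == "equal_culture":
        masses = relative_populations(counts)
    elif mass_mode == "sequential_harvest":
        masses = relative_populations(
            counts, mf["sampling_fraction"].to_numpy(dtype=float)
        )
    elif mass_mode == "explicit":
        masses = mf["relative_population"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown mass_mode: {mass_mode}")
    return TimeSeriesDataset([
        Snapshot(t, X, m)
        for t, X, m in zip(mf["time"].to_numpy(dtype=float), mats, masses)
    ])
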