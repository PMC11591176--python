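"""Readers and writers for the cohort interchange formats.

Signals travel as headerless CSV, one file per record, one row per channel
(12 x 5000 for a full recording, 12 x 1500 for a 3 s strip, C x 375 for
beat tensors), values in millivolts with period decimals.  Cohorts are
described by a tab-separated manifest (case_id, path, lvef, ef_class, af,
split_role).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import EcgRecord

SPLIT_ROLES = ("train", "dev", "test", "external", "unassigned")

MANIFEST_COLUMNS = ("case_id", "path", "lvef", "ef_class", "af", "split_role")


def read_record_csv(path: str | os.PathLike, expected_rows: int) -> np.ndarray:
    """Read a headerless signal CSV and enforce its shape contract.

    Raises ValueError with row/column diagnostics on a wrong row count,
    ragged rows, or non-numeric cells; never silently truncates or pads.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric or ragged CSV content: {exc}") from exc
    mat = df.to_numpy()
    if mat.shape[0] != expected_rows:
        raise ValueError(
            f"{path}: expected {expected_rows} rows, found {mat.shape[0]}")
    if not np.isfinite(mat).all():
        bad = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"{path}: non-finite value at row {bad[0]}, column {bad[1]}")
    return mat


def write_record_csv(matrix: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a signal matrix as headerless CSV with >=6 significant digits."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError(f"matrix must be 2-D, got shape {matrix.shape}")
    if not np.isfinite(matrix).all():
        raise ValueError("matrix contains non-finite values; refusing to write")
    path = Path(path)
    np.savetxt(path, matrix, delimiter=",", fmt="%.8g")
    return path


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a cohort manifest as TSV with header."""
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest["case_id"].duplicated().any():
        raise ValueError("manifest case_id values must be unique")
    path = Path(path)
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | os.PathLike, check_paths: bool = True
                  ) -> pd.DataFrame:
    """Read a cohort manifest; optionally verify the signal files exist."""
    path = Path(path)
    manifest = pd.read_csv(path, sep="\t", dtype={"case_id": str, "path": str})
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns: {sorted(missing)}")
    if manifest["case_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate case_id values")
    bad_roles = set(manifest["split_role"]) - set(SPLIT_ROLES)
    if bad_roles:
        raise ValueError(f"{path}: unknown split roles {sorted(bad_roles)}")
    if check_paths:
        base = path.parent
        for p in manifest["path"]:
            full = base / p
            if not full.exists():
                raise FileNotFoundError(f"manifest entry not found: {full}")
    return manifest


def write_cohort(records: list[EcgRecord], out_dir: str | os.PathLike,
                 split_roles: dict[str, str] | None = None) -> Path:
    """Export a cohort: one CSV per record plus ``manifest.tsv``.

    Returns the manifest path. Record paths in the manifest are relative to
    the manifest's directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.case_id}.csv"
        write_record_csv(rec.signal, out_dir / fname)
        role = (split_roles or {}).get(rec.case_id, "unassigned")
        rows.append({"case_id": rec.case_id, "path": fname, "lvef": rec.lvef,
                     "ef_class": rec.ef_class, "af": rec.af, "split_role": role})
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    return write_manifest(manifest, out_dir / "manifest.tsv")


def load_cohort_signals(manifest_path: str | os.PathLike,
                        expected_rows: int = 12) -> dict[str, np.ndarray]:
    """Load every signal referenced by a manifest, keyed by case_id."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    return {row.case_id: read_record_csv(base / row.path, expected_rows)
            for row in manifest.itertuples()}
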