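"""Delimited-text readers and writers.

Everything on disk is delimited text for diffability and language-agnostic
reuse: per-time-point N x N connectivity matrices plus a JSON manifest,
T x N time-series tables (optional header row of region labels), membership
and temporal-weight tables, a region-metadata table and flat ``key = value``
run-metadata/config files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, StructuralError
from .factorization import CommunityModel
from .group import GroupDynamicNetwork
from .jackknife import RoiTimeSeries

__all__ = [
    "RegionMetadata",
    "read_timeseries",
    "write_timeseries",
    "load_timeseries_dir",
    "write_tensor_dir",
    "read_tensor_dir",
    "write_model",
    "read_model",
    "read_region_metadata",
    "write_keyvalues",
    "read_keyvalues",
]

RSN_LABELS = {"SMN", "VN", "AN", "DMN", "LSN", "unlabeled"}


@dataclass
class RegionMetadata:
    """Region lookup table: full name, abbreviation, ROI index, RSN label."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"full_name", "abbreviation", "roi_index", "rsn_label"}
        missing = required - set(self.table.columns)
        if missing:
            raise StructuralError(f"region metadata missing columns: {sorted(missing)}")
        roi = self.table["roi_index"]
        if roi.duplicated().any() or (roi <= 0).any():
            raise StructuralError("roi_index values must be unique and positive")
        bad = set(self.table["rsn_label"]) - RSN_LABELS
        if bad:
            raise StructuralError(
                f"unknown RSN labels {sorted(bad)}; expected one of {sorted(RSN_LABELS)}"
            )

    def __len__(self) -> int:
        return len(self.table)


def read_region_metadata(path) -> RegionMetadata:
    """Read a region-metadata table (TSV or CSV, sniffed from the header)."""
    sep = _sniff_delimiter(Path(path))
    return RegionMetadata(pd.read_csv(path, sep=sep))


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _is_numeric_row(fields: list[str]) -> bool:
    try:
        [float(f) for f in fields]
        return True
    except ValueError:
        return False


def read_timeseries(path, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a T x N delimited time-series file, header row optional.

    NaN/Inf values are rejected with the offending (row, column) coordinates
    in the error message; row numbers count data rows from 0.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        first = fh.readline().strip().split(sep)
    header = 0 if not _is_numeric_row(first) else None
    df = pd.read_csv(path, sep=sep, header=header)
    labels = [str(c) for c in df.columns] if header == 0 else []
    values = df.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise StructuralError(f"{path.name}: non-finite value at row {r}, column {c}")
    return RoiTimeSeries(
        values=values,
        region_labels=labels,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=ts.region_labels).to_csv(path, sep="\t", index=False)


def load_timeseries_dir(path, metadata: RegionMetadata | None = None) -> list[RoiTimeSeries]:
    """Read every delimited file in a directory as one subject each.

    Per-file errors are aggregated into a single report; all subjects must
    share the same region count and (when present) the same labels.
    """
    path = Path(path)
    if not path.is_dir():
        raise StructuralError(f"not a directory: {path}")
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".tsv", ".csv", ".txt"}
    )
    if not files:
        raise StructuralError(f"no time-series files found in {path}")
    series: list[RoiTimeSeries] = []
    problems: list[str] = []
    for f in files:
        try:
            series.append(read_timeseries(f))
        except Exception as exc:  # aggregate, then report once
            problems.append(f"{f.name}: {exc}")
    if problems:
        raise StructuralError("invalid time-series files:\n" + "\n".join(problems))
    n = series[0].n_regions
    labels = series[0].region_labels
    for ts in series[1:]:
        if ts.n_regions != n:
            problems.append(f"{ts.subject_id}: {ts.n_regions} regions, expected {n}")
        elif ts.region_labels != labels:
            problems.append(f"{ts.subject_id}: region labels differ from {series[0].subject_id}")
    if metadata is not None and len(metadata) != n:
        problems.append(f"metadata has {len(metadata)} regions, data has {n}")
    if problems:
        raise StructuralError("inconsistent time-series directory:\n" + "\n".join(problems))
    return series


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_tensor_dir(tensor: np.ndarray, outdir, region_labels=None, provenance=None) -> Path:
    """Write an (N, N, T) tensor as one N x N TSV per time point plus manifest."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3 or tensor.shape[0] != tensor.shape[1]:
        raise StructuralError("tensor must have shape (N, N, T)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    N, _, T = tensor.shape
    files = []
    for t in range(T):
        name = f"t{t:04d}.tsv"
        np.savetxt(outdir / name, tensor[:, :, t], delimiter="\t", fmt="%.10g")
        files.append(name)
    if provenance is not None:
        np.savetxt(outdir / "provenance.tsv", np.asarray(provenance, dtype=int),
                   delimiter="\t", fmt="%d")
    manifest = {
        "n_regions": N,
        "n_timepoints": T,
        "files": files,
        "region_labels": list(region_labels) if region_labels else
                         [f"R{j + 1:03d}" for j in range(N)],
        "checksums": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_tensor_dir(path) -> GroupDynamicNetwork:
    """Read a tensor directory back into a GroupDynamicNetwork."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    N, T = manifest["n_regions"], manifest["n_timepoints"]
    tensor = np.empty((N, N, T))
    for t, name in enumerate(manifest["files"]):
        mat = np.loadtxt(path / name, delimiter="\t", ndmin=2)
        if mat.shape != (N, N):
            raise StructuralError(f"{name}: shape {mat.shape}, expected ({N}, {N})")
        tensor[:, :, t] = mat
    prov_file = path / "provenance.tsv"
    provenance = (
        np.loadtxt(prov_file, delimiter="\t", dtype=int, ndmin=2)
        if prov_file.exists()
        else None
    )
    return GroupDynamicNetwork(
        F=tensor, provenance=provenance, region_labels=manifest["region_labels"]
    )


def write_model(model: CommunityModel, outdir, region_labels=None) -> Path:
    """Write membership, temporal weights and run metadata for one fit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    N, k = model.C.shape
    labels = list(region_labels) if region_labels else [f"R{j + 1:03d}" for j in range(N)]
    mem = pd.DataFrame(model.C, columns=[f"community_{p + 1}" for p in range(k)])
    mem.insert(0, "region", labels)
    mem.to_csv(outdir / "membership.tsv", sep="\t", index=False)
    pd.DataFrame(
        model.Z, columns=[f"community_{p + 1}" for p in range(k)]
    ).to_csv(outdir / "temporal_weights.tsv", sep="\t", index=False)
    write_keyvalues(
        outdir / "run_metadata.txt",
        {
            "k": model.k,
            "beta": model.beta,
            "seed": model.seed,
            "objective": float(model.objective_trace[-1]),
            "sweeps": len(model.objective_trace) - 1,
            "converged": model.converged,
            "restart_index": model.restart_index,
        },
    )
    np.savetxt(outdir / "objective_trace.tsv", model.objective_trace, fmt="%.12g")
    return outdir


def read_model(path) -> CommunityModel:
    path = Path(path)
    mem = pd.read_csv(path / "membership.tsv", sep="\t")
    C = mem.drop(columns=["region"]).to_numpy(dtype=float)
    Z = pd.read_csv(path / "temporal_weights.tsv", sep="\t").to_numpy(dtype=float)
    meta = read_keyvalues(path / "run_metadata.txt")
    trace = np.loadtxt(path / "objective_trace.tsv", ndmin=1)
    return CommunityModel(
        C=C,
        Z=Z,
        k=int(meta["k"]),
        beta=float(meta["beta"]),
        objective_trace=trace,
        seed=int(meta["seed"]),
        converged=str(meta["converged"]).lower() == "true",
        restart_index=int(meta["restart_index"]),
    )


def write_keyvalues(path, mapping: dict) -> None:
    """Write a flat ``key = value`` text file."""
    lines = [f"{key} = {value}" for key, value in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_keyvalues(path) -> dict[str, str]:
    """Read a flat ``key = value`` file; '#' starts a comment line."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParameterError(f"{path}: line {lineno} is not 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
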