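"""Readers and writers: aligned FASTA, coordinate/distance tables, reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .estimator import IDEstimate
from .metrics import DistanceSet, load_precomputed
from .scaling import ScalingProfile
from .shapes import PointCloud

__all__ = [
    "MSA",
    "read_fasta_msa",
    "read_points",
    "read_distances",
    "write_points",
    "write_report",
    "write_profile",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class MSA:
    """Multiple sequence alignment: equal-length uppercase strings.

    Sequences are case-folded and '.' gaps normalized to '-'; the alphabet
    is not restricted (comparison downstream is literal).
    """

    ids: list
    sequences: list

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an MSA needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            bad = [i for i, s in zip(self.ids, self.sequences)
                   if len(s) != len(self.sequences[0])]
            raise ValueError(f"ragged alignment; offending ids: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)


def read_fasta_msa(path) -> MSA:
    """Read an aligned FASTA file into an :class:`MSA`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper().replace(".", "-") for r in records]
    return MSA(ids, seqs)


def _read_table(path) -> np.ndarray:
    """Delimited numeric table with header autodetection (CSV or TSV)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    first = pd.read_csv(path, sep=sep, header=None, nrows=1, comment="#")
    has_header = first.iloc[0].map(
        lambda v: isinstance(v, str)
        and not v.lstrip("+-").replace(".", "", 1).replace("e", "", 1)
        .replace("E", "", 1).replace("-", "", 1).replace("+", "", 1)
        .isdigit()).any()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     comment="#")
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        rows, cols = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(f"non-finite value at row {rows}, column {cols} "
                         f"of {path}")
    return arr


def read_points(path) -> PointCloud:
    """Read an N x M coordinate table (TSV/CSV, optional header)."""
    return PointCloud(_read_table(path))


def read_distances(path) -> DistanceSet:
    """Read a distance matrix: square symmetric table, or a condensed
    vector with an ``# n_points=N`` comment line."""
    path = Path(path)
    n_points = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "n_points=" in line:
                n_points = int(line.split("n_points=")[1].strip())
            if not line.startswith("#"):
                break
    arr = _read_table(path)
    if arr.ndim == 2 and 1 in arr.shape:
        arr = arr.ravel()
    return load_precomputed(arr, n_points=n_points)


def write_points(cloud: PointCloud, path) -> None:
    """Write a headered TSV of coordinates (x0, x1, ...)."""
    df = pd.DataFrame(cloud.coords,
                      columns=[f"x{i}" for i in range(cloud.n_dims)])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_report(estimate: IDEstimate, path,
                 profile: ScalingProfile | None = None,
                 profile_path=None) -> dict:
    """Write the JSON estimate report (and optionally a profile TSV).

    The report is bit-stable for identical inputs and settings: no
    timestamps, sorted keys, fixed float formatting.
    """
    payload = {"schema_version": REPORT_SCHEMA_VERSION}
    payload.update(asdict(estimate))
    payload = _round_floats(payload)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if profile is not None and profile_path is not None:
        write_profile(profile, profile_path)
    return payload


def write_profile(profile: ScalingProfile, path) -> None:
    """Write a scaling profile as a TSV with columns r, C, D."""
    D = (profile.D_values if profile.D_values is not None
         else np.full_like(profile.r_grid, np.nan))
    df = pd.DataFrame({"r": profile.r_grid, "C": profile.C_values, "D": D})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.generic):
        return _round_floats(obj.item(), ndigits)
    return obj
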