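"""Tabular I/O for methylation-array artifacts.

All on-disk formats are plain delimited text (TSV by default, CSV via
``sep=","``).  Genomic coordinates are handled in two conventions:

* internal / manifest coordinates are **1-based inclusive** base-pair
  positions (the convention of array manifests and printed tables);
* CpG-island interval files use the **BED** convention (0-based,
  half-open) and are converted on read/write, so interval length is
  preserved exactly (``end - start + 1 == bed_end - bed_start``).

Writers emit a single ``#`` header comment carrying the tool version and
the genome-build label; readers skip comment lines.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_islands",
    "write_islands",
    "map_probes_to_islands",
    "MANIFEST_COLUMNS",
    "ISLAND_COLUMNS",
]

#: manifest schema: ``island_relation`` is one of in_island / flank /
#: open_sea; ``island_id`` is empty for open-sea probes and
#: ``island_distance`` (bp to the nearest island edge) is 0 unless the
#: probe is a flank probe.
MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "island_relation",
    "island_id",
    "island_distance",
]

#: island schema, internal 1-based inclusive coordinates
ISLAND_COLUMNS = ["island_id", "chromosome", "start", "end"]

VALID_GROUPS = frozenset({"case", "control"})
VALID_RELATIONS = frozenset({"in_island", "flank", "open_sea"})


class ValidationError(ValueError):
    """An input table violated a structural or range invariant."""


def _header_comment(genome_build: str) -> str:
    return f"# epiewas v{__version__} build={genome_build}\n"


# ---------------------------------------------------------------------------
# BetaMatrix


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample.  Cells
        are methylation fractions (beta values) in ``[0, 1]``; missing
        values are ``NaN``.
    sample_meta
        DataFrame indexed by sample id with a mandatory ``group`` column
        (``case`` or ``control``) and an optional ``sex`` column.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def case_ids(self) -> list[str]:
        g = self.sample_meta["group"]
        return list(g.index[g == "case"])

    @property
    def control_ids(self) -> list[str]:
        g = self.sample_meta["group"]
        return list(g.index[g == "control"])

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (cases, controls) value arrays, probes x samples."""
        return (
            self.values[self.case_ids].to_numpy(float),
            self.values[self.control_ids].to_numpy(float),
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dup = vals.index[vals.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if vals.columns.has_duplicates:
            dup = vals.columns[vals.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        arr = vals.to_numpy(float)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{vals.index[i]!r}, sample {vals.columns[j]!r}"
            )
        missing = vals.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValidationError(
                f"samples without metadata: {sorted(missing)[:5]}"
            )
        if "group" not in self.sample_meta.columns:
            raise ValidationError("sample metadata lacks a 'group' column")
        groups = set(self.sample_meta.loc[vals.columns, "group"])
        bad_groups = groups - VALID_GROUPS
        if bad_groups:
            raise ValidationError(f"unknown sample group(s): {sorted(bad_groups)}")
        # keep metadata aligned to the matrix columns
        self.sample_meta = self.sample_meta.loc[vals.columns]


def read_beta_matrix(path, meta_path, sep: str = "\t") -> BetaMatrix:
    """Read a beta matrix and its sample-metadata table.

    The matrix file has the probe id in the first column and one column
    per sample; empty cells are read as missing (never as 0).  The
    metadata file maps ``sample_id`` to ``group`` and, optionally,
    ``sex``.
    """
    vals = pd.read_csv(
        path, sep=sep, comment="#", index_col=0, float_precision="round_trip"
    )
    vals.index = vals.index.astype(str)
    vals.index.name = "probe_id"
    for col in vals.columns:
        try:
            vals[col] = pd.to_numeric(vals[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"non-numeric beta value in sample column {col!r}: {exc}"
            ) from None
    meta = pd.read_csv(meta_path, sep=sep, comment="#", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata file lacks a 'sample_id' column")
    meta = meta.set_index("sample_id")
    return BetaMatrix(vals.astype(float), meta)


def write_beta_matrix(
    matrix: BetaMatrix,
    path,
    meta_path,
    sep: str = "\t",
    genome_build: str = "GRCh37",
) -> None:
    """Write a beta matrix plus metadata; inverse of :func:`read_beta_matrix`."""
    for target, frame, index in (
        (path, matrix.values, True),
        (meta_path, matrix.sample_meta.reset_index(names="sample_id"), False),
    ):
        with open(target, "w") as fh:
            fh.write(_header_comment(genome_build))
            frame.to_csv(fh, sep=sep, index=index)


# ---------------------------------------------------------------------------
# Probe manifests


def _validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest lacks column(s) {missing}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"duplicate probe id {dup!r} in manifest")
    if (df["position"] < 1).any():
        raise ValidationError("manifest positions must be >= 1 (1-based)")
    bad = set(df["island_relation"]) - VALID_RELATIONS
    if bad:
        raise ValidationError(f"unknown island_relation value(s): {sorted(bad)}")
    return df


def read_manifest(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=sep,
        comment="#",
        dtype={"probe_id": str, "chromosome": str, "island_id": str},
    )
    df["island_id"] = df["island_id"].fillna("")
    df["position"] = df["position"].astype(int)
    df["island_distance"] = df["island_distance"].fillna(0).astype(int)
    return _validate_manifest(df)


def write_manifest(
    df: pd.DataFrame, path, sep: str = "\t", genome_build: str = "GRCh37"
) -> None:
    _validate_manifest(df)
    with open(path, "w") as fh:
        fh.write(_header_comment(genome_build))
        df.to_csv(fh, sep=sep, index=False, columns=MANIFEST_COLUMNS)


# ---------------------------------------------------------------------------
# CpG islands (BED on disk, 1-based inclusive in memory)


def _validate_islands(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ISLAND_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"island table lacks column(s) {missing}")
    if df["island_id"].duplicated().any():
        dup = df.loc[df["island_id"].duplicated(), "island_id"].iloc[0]
        raise ValidationError(f"duplicate island id {dup!r}")
    bad = df["start"] > df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValidationError(
            f"empty or inverted island interval {row['island_id']!r}: "
            f"start {row['start']} > end {row['end']}"
        )
    return df


def read_islands(path, sep: str = "\t") -> pd.DataFrame:
    """Read CpG islands from a BED-like file.

    BED is 0-based half-open; internal coordinates are 1-based
    inclusive, so ``start = bed_start + 1`` and ``end = bed_end``.  A
    zero-length BED interval (``bed_start == bed_end``) is rejected.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        comment="#",
        header=None,
        names=["chromosome", "bed_start", "bed_end", "island_id"],
        dtype={"chromosome": str, "island_id": str},
    )
    out = pd.DataFrame(
        {
            "island_id": df["island_id"],
            "chromosome": df["chromosome"],
            "start": df["bed_start"].astype(int) + 1,
            "end": df["bed_end"].astype(int),
        }
    )
    return _validate_islands(out)


def write_islands(
    df: pd.DataFrame, path, sep: str = "\t", genome_build: str = "GRCh37"
) -> None:
    """Write islands as BED (inverse coordinate conversion of read)."""
    _validate_islands(df)
    bed = pd.DataFrame(
        {
            "chromosome": df["chromosome"],
            "bed_start": df["start"].astype(int) - 1,
            "bed_end": df["end"].astype(int),
            "island_id": df["island_id"],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_comment(genome_build))
        bed.to_csv(fh, sep=sep, index=False, header=False)


# ---------------------------------------------------------------------------
# Probe -> island mapping


def map_probes_to_islands(
    manifest: pd.DataFrame, islands: pd.DataFrame, flank_bp: int = 250
) -> pd.DataFrame:
    """Assign each probe an island relation.

    A probe inside an island interval is ``in_island``; otherwise, if it
    lies within ``flank_bp`` of an island edge it is ``flank`` with the
    distance to the nearest edge; otherwise ``open_sea``.  When a probe
    is within range of several islands it is assigned to the island with
    the nearest edge (ties broken by island id).  The flank window is
    symmetric (strand-agnostic): probes on either side of an island
    count as flanking it.

    Returns a new manifest; the input is not modified.
    """
    if flank_bp < 0:
        raise ValidationError("flank_bp must be >= 0")
    _validate_islands(islands)
    out = manifest.copy()
    relation = np.full(len(out), "open_sea", dtype=object)
    island_id = np.full(len(out), "", dtype=object)
    distance = np.zeros(len(out), dtype=int)

    pos = out["position"].to_numpy(int)
    for chrom, isl in islands.groupby("chromosome", sort=False):
        on_chrom = (out["chromosome"] == chrom).to_numpy()
        if not on_chrom.any():
            continue
        p = pos[on_chrom]
        # distance 0 inside the island, else bp to the nearest edge
        starts = isl["start"].to_numpy(int)[:, None]
        ends = isl["end"].to_numpy(int)[:, None]
        dist = np.maximum.reduce([starts - p, p - ends, np.zeros_like(starts - p)])
        order = np.argsort(isl["island_id"].to_numpy())  # tie-break: island id
        best_local = order[np.argmin(dist[order], axis=0)]
        best_dist = dist[best_local, np.arange(len(p))]
        ids = isl["island_id"].to_numpy()[best_local]

        idx = np.flatnonzero(on_chrom)
        inside = best_dist == 0
        near = (best_dist > 0) & (best_dist <= flank_bp)
        relation[idx[inside]] = "in_island"
        relation[idx[near]] = "flank"
        hit = inside | near
        island_id[idx[hit]] = ids[hit]
        distance[idx[near]] = best_dist[near]

    out["island_relation"] = relation
    out["island_id"] = island_id
    out["island_distance"] = distance
    return _validate_manifest(out)
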