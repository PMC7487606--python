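"""Readers and writers for BED region sets, signal matrices, target tables,
precomputed feature-contribution-score matrices, and ranked result tables.

The canonical exchange format for all matrices is a tab-delimited table with
a header row. Signal matrices carry coordinate columns first (``chrom``,
``start``, ``end`` for region-resolution data; ``chrom``, ``position`` for
nucleotide-resolution data, with a declared 1-based convention) followed by
one numeric column per sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet, RegionSetDatabase

logger = logging.getLogger(__name__)

__all__ = [
    "SignalMatrix",
    "TargetVariableSet",
    "read_bed",
    "load_region_db",
    "read_signal_matrix",
    "write_signal_matrix",
    "read_targets",
    "write_results",
]

RESULT_COLUMNS = [
    "region_set",
    "target",
    "score",
    "n_regions_covered",
    "n_features",
    "p_value",
    "q_value",
    "p_source",
    "rank",
]


@dataclass
class SignalMatrix:
    """Loci-by-samples matrix of epigenetic signal with genomic coordinates.

    Parameters
    ----------
    coords : list of GenomicInterval
        One interval per matrix row. Nucleotide-resolution matrices (e.g.
        CpG methylation) use single-base intervals; region-resolution
        matrices (e.g. ATAC-seq peaks) use wider ones.
    values : ndarray, shape (n_loci, n_samples)
        Signal values; NaN marks missing cells.
    sample_ids : list of str
        Unique column labels.
    resolution : {"nucleotide", "region"}
    is_methylation : bool
        Declares bounded [0, 1] beta-value semantics; enforced on init.
    """

    coords: list[GenomicInterval]
    values: np.ndarray
    sample_ids: list[str]
    resolution: str
    is_methylation: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if len(self.coords) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.coords)} coords but {self.values.shape[0]} value rows"
            )
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length must match value columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.resolution not in ("nucleotide", "region"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        if self.resolution == "nucleotide" and any(
            c.width != 1 for c in self.coords
        ):
            raise ValueError("nucleotide resolution requires single-base coords")
        if self.is_methylation:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("methylation values must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class TargetVariableSet:
    """Samples-by-targets matrix of phenotypes or latent-factor scores."""

    values: np.ndarray
    target_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must match value rows")
        if len(self.target_names) != self.values.shape[1]:
            raise ValueError("target_names length must match value columns")
        if len(set(self.target_names)) != len(self.target_names):
            raise ValueError("target names must be unique")
        # Constant targets have no covariation to annotate: warn and drop.
        keep = []
        for j, name in enumerate(self.target_names):
            col = self.values[:, j]
            col = col[np.isfinite(col)]
            if col.size and np.ptp(col) == 0:
                warnings.warn(
                    f"target {name!r} is constant across samples; dropped",
                    stacklevel=2,
                )
            else:
                keep.append(j)
        if len(keep) != len(self.target_names):
            self.values = self.values[:, keep]
            self.target_names = [self.target_names[j] for j in keep]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def aligned_to(self, sample_ids: list[str]) -> "TargetVariableSet":
        """Reorder rows to match a signal matrix's sample order."""
        if set(sample_ids) != set(self.sample_ids):
            missing = sorted(set(sample_ids) - set(self.sample_ids))
            extra = sorted(set(self.sample_ids) - set(sample_ids))
            raise ValueError(
                f"sample ID mismatch: missing from targets {missing}, "
                f"unknown in targets {extra}"
            )
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        order = [pos[s] for s in sample_ids]
        return TargetVariableSet(
            self.values[order], list(self.target_names), list(sample_ids)
        )


def _normalize_chrom(chrom: str) -> str:
    return chrom if chrom.startswith("chr") else "chr" + chrom


def read_bed(
    path: str | Path,
    name: str | None = None,
    normalize_chroms: bool = False,
) -> RegionSet:
    """Read a BED file (3+ tab-separated columns) into a RegionSet.

    Track/browser/comment lines are skipped; columns beyond the first three
    are ignored. Malformed lines raise with the offending line number.
    """
    path = Path(path)
    regions: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            if normalize_chroms:
                chrom = _normalize_chrom(chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            regions.append(GenomicInterval(chrom, start, end))
    return RegionSet(name=name or path.stem, regions=regions)


def load_region_db(
    directory: str | Path,
    annotation: str | Path | None = None,
    genome_label: str = "",
    normalize_chroms: bool = False,
) -> RegionSetDatabase:
    """Load every BED file in a directory as one RegionSetDatabase.

    Files are loaded in sorted-filename order so the database is independent
    of filesystem listing order. If an annotation sheet (TSV/CSV with a
    ``filename`` key column) is given, its rows are attached as metadata;
    rows naming a file that does not exist are skipped with a warning.
    """
    directory = Path(directory)
    bed_paths = sorted(directory.glob("*.bed"))
    if not bed_paths:
        raise ValueError(f"no .bed files found in {directory}")
    meta: dict[str, dict] = {}
    if annotation is not None:
        annotation = Path(annotation)
        sep = "," if annotation.suffix.lower() == ".csv" else "\t"
        sheet = pd.read_csv(annotation, sep=sep)
        if "filename" not in sheet.columns:
            raise ValueError("annotation sheet must have a 'filename' column")
        known = {p.name for p in bed_paths}
        for _, row in sheet.iterrows():
            fname = str(row["filename"])
            if fname not in known:
                warnings.warn(
                    f"annotation row for {fname!r} has no matching BED file; skipped",
                    stacklevel=2,
                )
                continue
            meta[fname] = {
                k: v for k, v in row.items() if k != "filename" and pd.notna(v)
            }
    sets = []
    for p in bed_paths:
        rs = read_bed(p, normalize_chroms=normalize_chroms)
        rs.metadata = meta.get(p.name, {})
        sets.append(rs)
    return RegionSetDatabase(sets=sets, genome_label=genome_label)


def read_signal_matrix(
    path: str | Path,
    resolution: str,
    one_based: bool = True,
    is_methylation: bool = False,
    normalize_chroms: bool = False,
) -> SignalMatrix:
    """Read a tab-delimited signal matrix.

    Region resolution expects columns ``chrom``, ``start``, ``end``;
    nucleotide resolution expects ``chrom``, ``position`` (1-based by
    default, so position p becomes the interval [p-1, p)) or, equivalently,
    ``chrom``, ``start``, ``end`` with unit widths. Remaining columns are
    samples; non-numeric cells become missing values.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"{path}: duplicate sample column names {dupes}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = list(df.columns)
    if "chrom" not in cols:
        raise ValueError(f"{path}: missing 'chrom' column")
    if {"start", "end"}.issubset(cols):
        coord_cols = ["chrom", "start", "end"]
        starts = df["start"].astype(np.int64).to_numpy()
        ends = df["end"].astype(np.int64).to_numpy()
    elif "position" in cols:
        if resolution != "nucleotide":
            raise ValueError("'position' column implies nucleotide resolution")
        coord_cols = ["chrom", "position"]
        pos = df["position"].astype(np.int64).to_numpy()
        starts = pos - 1 if one_based else pos
        ends = starts + 1
    else:
        raise ValueError(
            f"{path}: need 'start'/'end' or 'position' coordinate columns"
        )
    sample_cols = [c for c in cols if c not in coord_cols]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    if len(set(sample_cols)) != len(sample_cols):
        raise ValueError(f"{path}: duplicate sample column names")
    chroms = df["chrom"].astype(str)
    if normalize_chroms:
        chroms = chroms.map(_normalize_chrom)
    coords = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(chroms, starts, ends)
    ]
    values = (
        df[sample_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    )
    return SignalMatrix(
        coords=coords,
        values=values,
        sample_ids=sample_cols,
        resolution=resolution,
        is_methylation=is_methylation,
    )


def write_signal_matrix(signal: SignalMatrix, path: str | Path) -> None:
    """Write a signal matrix in the canonical tab-delimited layout."""
    df = pd.DataFrame(
        {
            "chrom": [c.chrom for c in signal.coords],
            "start": [c.start for c in signal.coords],
            "end": [c.end for c in signal.coords],
        }
    )
    for j, sid in enumerate(signal.sample_ids):
        df[sid] = signal.values[:, j]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_targets(path: str | Path) -> TargetVariableSet:
    """Read a target-variable table: ``sample_id`` column plus one numeric
    column per target variable."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    target_names = [c for c in df.columns if c != "sample_id"]
    if not target_names:
        raise ValueError(f"{path}: no target columns found")
    values = (
        df[target_names].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    )
    return TargetVariableSet(
        values=values,
        target_names=target_names,
        sample_ids=[str(s) for s in df["sample_id"]],
    )


def write_targets(targets: TargetVariableSet, path: str | Path) -> None:
    df = pd.DataFrame(targets.values, columns=targets.target_names)
    df.insert(0, "sample_id", targets.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked result table, sorted per target by descending score.

    Ties are broken by region_set name ascending. An empty frame yields a
    header-only file.
    """
    out = results.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out = out[RESULT_COLUMNS]
    if len(out):
        out = out.sort_values(
            ["target", "score", "region_set"],
            ascending=[True, False, True],
            kind="stable",
        )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
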