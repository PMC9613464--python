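"""Readers and writers for the plain-text formats the pipeline exchanges.

BED3/BED6/narrowPeak peak files, bedGraph-style 4-column copy-number
tracks, ``dose,tested,responders`` assay CSVs, genes x samples expression
TSVs, GMT gene-set files, 2-column weight TSVs, and JSON group labels.
Coordinates are 0-based half-open on disk and in memory.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cnv import CNBinTrack
from .cores import CRESet
from .lda import LDAssay
from .stemness import GeneSignature

__all__ = [
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
    "read_weighted_signature",
    "read_matrix",
    "write_matrix",
    "read_assay",
    "write_assay",
    "read_cn",
    "write_cn",
    "read_groups",
    "write_groups",
    "read_sample_sheet",
]

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path) -> list[tuple]:
    """Parse BED3/BED6/narrowPeak into sorted (chrom, start, end, *extras).

    Comment, track and browser lines are skipped.  Malformed coordinates
    raise with the offending line number; extra columns are preserved
    opaquely as strings.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            intervals.append((chrom, start, end, *fields[3:]))
    intervals.sort(key=lambda t: (t[0], t[1], t[2]))
    return intervals


def write_bed(intervals: Iterable[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_cre_set(path: str | Path, sample_id: str, group: str) -> CRESet:
    peaks = tuple((c, s, e) for c, s, e, *_ in read_bed(path))
    return CRESet(sample_id, group, peaks)


def read_gmt(path: str | Path) -> dict[str, GeneSignature]:
    """GMT: one set per line, ``name <tab> description <tab> gene...``."""
    signatures = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, genes = fields[0], tuple(g for g in fields[2:] if g)
            if name in signatures:
                raise ValueError(f"{path}:{lineno}: duplicate signature {name!r}")
            signatures[name] = GeneSignature(name=name, genes=genes)
    return signatures


def write_gmt(signatures: Mapping[str, GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, sig in signatures.items():
            fh.write("\t".join([name, "synthetic", *sig.genes]) + "\n")


def read_weighted_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """2-column TSV ``gene <tab> weight`` (header optional)."""
    genes, weights = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns (gene, weight)")
            if lineno == 1 and fields[0].lower() in ("gene", "genes"):
                continue
            try:
                w = float(fields[1])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {fields[1]!r}") from err
            genes.append(fields[0])
            weights.append(w)
    return GeneSignature(name=name or Path(path).stem, genes=tuple(genes),
                         weights=tuple(weights))


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with a header row; validates uniqueness and finiteness."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    try:
        df = df.astype(float)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric expression cell: {err}") from err
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{path}: non-finite expression values")
    if len(df) < 2:
        raise ValueError(f"{path}: need >= 2 genes")
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_assay(path: str | Path) -> LDAssay:
    """CSV with header ``dose,tested,responders``."""
    doses, tested, responders = [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"dose", "tested", "responders"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: header must contain {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                d = float(row["dose"])
                n = int(row["tested"])
                r = int(row["responders"])
            except (TypeError, ValueError) as err:
                raise ValueError(f"{path}: row {i}: non-numeric value") from err
            if d <= 0:
                raise ValueError(f"{path}: row {i}: dose must be positive")
            doses.append(d)
            tested.append(n)
            responders.append(r)
    return LDAssay(tuple(doses), tuple(tested), tuple(responders))


def write_assay(assay: LDAssay, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dose", "tested", "responders"])
        for d, n, r in assay.rows():
            writer.writerow([int(d) if d == int(d) else d, n, r])


def read_cn(path: str | Path) -> CNBinTrack:
    """4-column TSV ``chrom start end cn`` (single chromosome per file).

    Gaps between consecutive bins are tolerated with a warning; overlaps
    are rejected by the track invariants.
    """
    chroms, starts, ends, cn = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns (chrom start end cn)")
            try:
                s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed bin") from err
            chroms.append(fields[0])
            starts.append(s)
            ends.append(e)
            cn.append(v)
    if not starts:
        raise ValueError(f"{path}: empty copy-number track")
    if len(set(chroms)) > 1:
        raise ValueError(f"{path}: multiple chromosomes in one track: {sorted(set(chroms))}")
    starts_a = np.asarray(starts)
    ends_a = np.asarray(ends)
    gaps = int((starts_a[1:] > ends_a[:-1]).sum())
    if gaps:
        warnings.warn(f"{path}: {gaps} gaps between consecutive bins")
    bin_size = int(np.median(ends_a - starts_a)) if len(starts_a) else 1000
    return CNBinTrack(chroms[0], starts_a, ends_a, np.asarray(cn), bin_size)


def write_cn(track: CNBinTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, track.cn):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_groups(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        groups = json.load(fh)
    if not isinstance(groups, dict):
        raise ValueError(f"{path}: group labels must be a JSON object")
    return {str(k): str(v) for k, v in groups.items()}


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(groups), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_sample_sheet(path: str | Path) -> list[dict]:
    """TSV with header ``sample_id  path  group [fraction]``; ids must be unique.

    Relative ``path`` entries are resolved against the sheet's directory.
    """
    rows = []
    seen = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "path", "group"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: header must contain {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            sid = row["sample_id"]
            if sid in seen:
                raise ValueError(f"{path}: row {i}: duplicate sample_id {sid!r}")
            seen.add(sid)
            row = dict(row)
            p = Path(row["path"])
            if not p.is_absolute():
                row["path"] = str(Path(path).parent / p)
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty sample sheet")
    return rows
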