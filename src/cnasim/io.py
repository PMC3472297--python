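"""Readers and writers for on-disk artefacts.

Formats
-------
signal table : tab-separated, ``Name Chr Position "Log R Ratio" "B Allele Freq"``,
    1-based positions (Illumina-style per-SNP report); LRR/BAF at 4 decimals,
    missing BAF written as ``NaN``.
.pfb : PennCNV dialect, ``Name Chr Position PFB`` with a header row.
truth bed : BED-like TSV with 0-based half-open bp coordinates.
calls : TSV ``chrom start end copy_number[ loh]``; ``#`` comments tolerated.
scaffold : TSV ``length_snps cn ratio germline_loh [fractions]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CallRecord",
    "write_signal_table",
    "read_signal_table",
    "write_pfb",
    "read_pfb",
    "write_truth_bed",
    "read_truth_bed",
    "write_calls",
    "read_calls",
]

LOH_STATES = ("none", "somatic", "germline", "unspecified")


@dataclass(frozen=True)
class CallRecord:
    """One caller segment: bp interval (0-based half-open) plus copy number."""

    chrom: str
    start: int
    end: int
    copy_number: int
    loh: str = "unspecified"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"call {self.chrom}:{self.start}-{self.end}: "
                             "end must exceed start")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.loh not in LOH_STATES:
            raise ValueError(f"loh must be one of {LOH_STATES}")

    @property
    def length(self) -> int:
        return self.end - self.start


def write_signal_table(grid, track, path) -> None:
    """Write the per-SNP LRR/BAF report consumed by downstream callers."""
    if len(grid) != len(track):
        raise ValueError("grid and track lengths differ")
    df = pd.DataFrame({
        "Name": grid.probe_name,
        "Chr": grid.chrom,
        "Position": grid.position,
        "Log R Ratio": track.lrr,
        "B Allele Freq": track.baf,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.4f", na_rep="NaN")


def read_signal_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NaN"])
    expected = ["Name", "Chr", "Position", "Log R Ratio", "B Allele Freq"]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected signal-table columns in {path}: "
                         f"{list(df.columns)}")
    return df


def write_pfb(grid, path) -> None:
    pd.DataFrame({
        "Name": grid.probe_name,
        "Chr": [str(c).removeprefix("chr") for c in grid.chrom],
        "Position": grid.position,
        "PFB": np.asarray(grid.pfb, dtype=float),
    }).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_pfb(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise IOError(f"cannot parse PFB file {path}: {exc}") from exc
    if list(df.columns)[:4] != ["Name", "Chr", "Position", "PFB"]:
        raise IOError(f"{path}: expected header 'Name Chr Position PFB'")
    vals = df["PFB"].to_numpy(dtype=float)
    bad = np.where((vals < 0) | (vals > 1) | ~np.isfinite(vals))[0]
    if len(bad):
        raise IOError(f"{path}: PFB outside [0,1] at line {int(bad[0]) + 2}")
    return df


def _subclone_descriptor(region) -> str:
    return ",".join(f"{f:.4g}:{c}" for f, c in
                    zip(region.fractions, region.cns))


def write_truth_bed(truth, path) -> None:
    """BED-like truth annotation; one row per region, genome order."""
    rows = []
    for i, r in enumerate(truth.regions):
        rows.append({
            "chrom": r.chrom,
            "start": r.start_bp,
            "end": r.end_bp,
            "name": r.name or f"region{i:04d}",
            "copy_number": ",".join(str(c) for c in r.cns),
            "loh_status": r.loh_status,
            "subclone_descriptor": _subclone_descriptor(r),
            "n_snps": r.n_snps,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_bed(path):
    """Read a truth annotation back into ``TruthRegion`` records."""
    from .builder import TruthRegion  # deferred: io must not cycle on builder

    df = pd.read_csv(path, sep="\t")
    regions = []
    for _, row in df.iterrows():
        desc = str(row["subclone_descriptor"])
        fracs, cns = [], []
        for part in desc.split(","):
            f, c = part.split(":")
            fracs.append(float(f))
            cns.append(int(c))
        regions.append(TruthRegion(
            chrom=str(row["chrom"]), start_bp=int(row["start"]),
            end_bp=int(row["end"]), snp_start=-1, snp_end=-1,
            cns=tuple(cns), fractions=tuple(fracs),
            loh_status=str(row["loh_status"]), name=str(row["name"]),
            n_snps=int(row["n_snps"])))
    return regions


def write_calls(calls, path) -> None:
    pd.DataFrame([{
        "chrom": c.chrom, "start": c.start, "end": c.end,
        "copy_number": c.copy_number, "loh": c.loh,
    } for c in calls]).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list:
    """Parse caller output.  Overlapping calls are legal but counted and
    reported through a ``UserWarning``."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("chrom", "chr", "chromosome"):
                continue  # header row
            if len(fields) < 4:
                raise IOError(f"{path}:{lineno}: expected at least 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                cn = int(fields[3])
            except ValueError as exc:
                raise IOError(f"{path}:{lineno}: {exc}") from exc
            loh = fields[4].strip() if len(fields) > 4 and fields[4].strip() \
                else "unspecified"
            try:
                records.append(CallRecord(chrom=fields[0], start=start,
                                          end=end, copy_number=cn, loh=loh))
            except ValueError as exc:
                raise IOError(f"{path}:{lineno}: {exc}") from exc
    n_overlap = _count_overlaps(records)
    if n_overlap:
        warnings.warn(f"{path}: {n_overlap} overlapping call pair(s)",
                      UserWarning, stacklevel=2)
    return records


def _count_overlaps(records) -> int:
    n = 0
    by_chrom = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rs in by_chrom.values():
        rs = sorted(rs, key=lambda r: (r.start, r.end))
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                n += 1
    return n
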