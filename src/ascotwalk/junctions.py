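"""Splice-junction count tables: domain types and file I/O.

A *junction* is an intron inferred from split-read alignments, identified by
chromosome, the 1-based positions of its first and last intronic base, and a
strand. A :class:`JunctionTable` holds one count per junction per sample —
the only evidence the downstream event discovery and PSI quantification use.

Two on-disk dialects are supported: STAR ``SJ.out.tab`` files (one per
sample) and a single junction-matrix TSV where each row is a junction and
each column a sample/run accession.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Junction",
    "JunctionTable",
    "read_star_sj",
    "read_junction_matrix",
    "read_sample_metadata",
    "write_junction_matrix",
    "write_star_sj",
    "write_psi_matrix",
    "write_events_bed",
]

#: default minimum intron length; shorter "junctions" are treated as
#: alignment artifacts and dropped at load time.
MIN_INTRON_LENGTH = 20

_STRANDS = ("+", "-", ".")

_STAR_STRAND = {0: ".", 1: "+", 2: "-"}

_MATRIX_KEY_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class Junction:
    """One intron with a per-sample count vector.

    Coordinates are 1-based and fully closed: ``start`` is the first
    intronic base, ``end`` the last. ``strand`` is ``+``, ``-`` or ``.``
    (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"junction {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or (counts < 0).any():
            raise ValueError("counts must be a 1-D non-negative integer vector")
        object.__setattr__(self, "counts", counts)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def intron_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class JunctionTable:
    """A sorted, duplicate-free collection of junctions over shared samples."""

    junctions: list[Junction]
    samples: list[str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        for sample in self.groups:
            if sample not in set(self.samples):
                raise ValueError(f"group mapping names unknown sample {sample!r}")
        for j in self.junctions:
            if len(j.counts) != len(self.samples):
                raise ValueError(
                    f"junction {j.chrom}:{j.start}-{j.end} has {len(j.counts)} "
                    f"counts for {len(self.samples)} samples"
                )
        keys = [j.key for j in self.junctions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate junctions in table")
        self.junctions = sorted(
            self.junctions, key=lambda j: (j.chrom, j.start, j.end, j.strand)
        )

    def __len__(self) -> int:
        return len(self.junctions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def count_lookup(self) -> dict[tuple[str, int, int], np.ndarray]:
        """Map (chrom, start, end) -> counts, summing over strands."""
        out: dict[tuple[str, int, int], np.ndarray] = {}
        for j in self.junctions:
            if j.coords in out:
                out[j.coords] = out[j.coords] + j.counts
            else:
                out[j.coords] = j.counts
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {
            "chrom": [j.chrom for j in self.junctions],
            "start": [j.start for j in self.junctions],
            "end": [j.end for j in self.junctions],
            "strand": [j.strand for j in self.junctions],
        }
        counts = (
            np.vstack([j.counts for j in self.junctions])
            if self.junctions
            else np.zeros((0, len(self.samples)), dtype=np.int64)
        )
        frame = pd.DataFrame(data)
        for i, sample in enumerate(self.samples):
            frame[sample] = counts[:, i]
        return frame


def _filter_min_intron(
    rows: dict[tuple[str, int, int, str], np.ndarray], min_intron_length: int
) -> dict[tuple[str, int, int, str], np.ndarray]:
    return {
        key: v
        for key, v in rows.items()
        if key[2] - key[1] + 1 >= min_intron_length
    }


def read_star_sj(
    paths: Sequence[str | os.PathLike],
    sample_ids: Sequence[str],
    min_intron_length: int = MIN_INTRON_LENGTH,
) -> JunctionTable:
    """Load the union of several STAR ``SJ.out.tab`` files into one table.

    Columns per STAR: chrom, intron start, intron end, strand code
    (0 unknown / 1 ``+`` / 2 ``-``), intron motif, annotated flag, unique
    reads, multi-mapped reads. Only unique-read counts are kept. A junction
    absent from a sample gets count 0.
    """
    if len(paths) != len(sample_ids):
        raise ValueError(
            f"{len(paths)} paths but {len(sample_ids)} sample ids"
        )
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in sample_ids")
    n = len(sample_ids)
    rows: dict[tuple[str, int, int, str], np.ndarray] = {}
    for col, path in enumerate(paths):
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 8:
                    raise ValueError(
                        f"{path}:{lineno}: expected 8 tab-separated columns, "
                        f"got {len(fields)}"
                    )
                try:
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    strand = _STAR_STRAND[int(fields[3])]
                    unique = int(fields[6])
                except (ValueError, KeyError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
                key = (chrom, start, end, strand)
                if key not in rows:
                    rows[key] = np.zeros(n, dtype=np.int64)
                rows[key][col] += unique
    rows = _filter_min_intron(rows, min_intron_length)
    junctions = [
        Junction(chrom=k[0], start=k[1], end=k[2], strand=k[3], counts=v)
        for k, v in rows.items()
    ]
    return JunctionTable(junctions=junctions, samples=list(sample_ids))


def read_sample_metadata(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column sample metadata TSV (sample_id, group)."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"{path}: metadata is missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return dict(zip(meta["sample_id"], meta["group"]))


def read_junction_matrix(
    path: str | os.PathLike,
    metadata_path: str | os.PathLike | None = None,
    min_intron_length: int = MIN_INTRON_LENGTH,
) -> JunctionTable:
    """Read a junction-matrix TSV: one row per junction, one column per sample."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    missing = [c for c in _MATRIX_KEY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: header is missing required columns {missing}")
    samples = [c for c in frame.columns if c not in _MATRIX_KEY_COLUMNS]
    for sample in samples:
        col = frame[sample]
        if not np.issubdtype(col.dtype, np.integer):
            coerced = pd.to_numeric(col, errors="coerce")
            bad = coerced.isna() | (coerced != coerced.round())
            if bad.any():
                row = frame.loc[bad.idxmax()]
                raise ValueError(
                    f"{path}: non-integer count for sample {sample!r} at "
                    f"{row['chrom']}:{row['start']}-{row['end']}"
                )
            frame[sample] = coerced.astype(np.int64)
    groups: dict[str, str] = {}
    if metadata_path is not None:
        meta = read_sample_metadata(metadata_path)
        unknown = sorted(set(meta) - set(samples))
        if unknown:
            raise ValueError(
                f"metadata samples not present in matrix: {', '.join(unknown)}"
            )
        groups = {s: meta.get(s, "ungrouped") for s in samples}
    counts = frame[samples].to_numpy(dtype=np.int64)
    rows: dict[tuple[str, int, int, str], np.ndarray] = {}
    for i, rec in enumerate(frame[_MATRIX_KEY_COLUMNS].itertuples(index=False)):
        key = (str(rec.chrom), int(rec.start), int(rec.end), str(rec.strand))
        if key in rows:
            rows[key] = rows[key] + counts[i]
        else:
            rows[key] = counts[i]
    rows = _filter_min_intron(rows, min_intron_length)
    junctions = [
        Junction(chrom=k[0], start=k[1], end=k[2], strand=k[3], counts=v)
        for k, v in rows.items()
    ]
    return JunctionTable(junctions=junctions, samples=samples, groups=groups)


def write_junction_matrix(table: JunctionTable, path: str | os.PathLike) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_star_sj(table: JunctionTable, outdir: str | os.PathLike) -> list[str]:
    """Write one STAR-style SJ.out.tab per sample; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    code = {".": 0, "+": 1, "-": 2}
    paths = []
    for i, sample in enumerate(table.samples):
        path = os.path.join(outdir, f"{sample}.SJ.out.tab")
        with open(path, "w") as handle:
            for j in table.junctions:
                if j.counts[i] == 0:
                    continue
                handle.write(
                    f"{j.chrom}\t{j.start}\t{j.end}\t{code[j.strand]}\t0\t0\t"
                    f"{int(j.counts[i])}\t0\n"
                )
        paths.append(path)
    return paths


def write_psi_matrix(psi_matrix, path: str | os.PathLike, header_comment: str | None = None) -> None:
    """Serialize a PSI matrix to TSV.

    One row per event with its identifying columns, then one PSI column per
    sample. Missing cells are written as ``NA``; PSI is printed with one
    decimal on the 0-100 scale.
    """
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    cols = ["event_id", "event_type", "chrom", "exon_intervals", "strand", "annotated"]
    buf.write("\t".join(cols + list(psi_matrix.samples)) + "\n")
    for i, event in enumerate(psi_matrix.events):
        cells = []
        for s in range(len(psi_matrix.samples)):
            value = psi_matrix.psi[i, s]
            cells.append("NA" if np.isnan(value) else f"{value:.1f}")
        exons = ";".join(f"{a}-{b}" for a, b in event.exon_intervals)
        row = [
            event.event_id,
            event.event_type,
            event.chrom,
            exons,
            event.strand,
            event.annotated,
        ]
        buf.write("\t".join(row + cells) + "\n")
    with open(path, "w") as handle:
        handle.write(buf.getvalue())


def write_events_bed(events: Iterable, psi_matrix=None, path: str | os.PathLike = "events.bed") -> None:
    """Write events as BED6 (0-based half-open; name = event id; score =
    rounded mean PSI over informative cells, 0 when none)."""
    mean_psi: Mapping[str, float] = {}
    if psi_matrix is not None:
        with np.errstate(invalid="ignore"):
            means = np.nanmean(
                np.where(np.isnan(psi_matrix.psi), np.nan, psi_matrix.psi), axis=1
            )
        mean_psi = {
            e.event_id: (0.0 if np.isnan(m) else float(m))
            for e, m in zip(psi_matrix.events, means)
        }
    with open(path, "w") as handle:
        for event in events:
            start = min(a for a, _ in event.exon_intervals) - 1
            end = max(b for _, b in event.exon_intervals)
            score = int(round(mean_psi.get(event.event_id, 0.0)))
            strand = event.strand if event.strand in ("+", "-") else "."
            handle.write(
                f"{event.chrom}\t{start}\t{end}\t{event.event_id}\t{score}\t{strand}\n"
            )
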