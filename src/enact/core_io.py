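"""Domain types and file I/O for the regulatory-genomics pipeline.

All coordinates are 0-based half-open (BED convention) throughout the
package.  Minus-strand coverage is stored as a non-negative magnitude;
the sign sometimes seen in browser tracks is a display convention and is
stripped on read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# interval and gene types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand/name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand, TSS, exon structure and a promoter window.

    The TSS is the strand-aware 5' end: ``body.start`` on the plus strand
    and ``body.end - 1`` on the minus strand.  The promoter spans 1000 bp
    upstream to 500 bp downstream of the TSS in transcribed orientation.
    """

    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    promoter_upstream: int = 1000
    promoter_downstream: int = 500

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError("gene body requires a +/- strand")
        prev_start = -1
        for ex in self.exons:
            if ex.chrom != self.body.chrom:
                raise ValueError("exon on wrong chromosome")
            if ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError("exon outside gene body")
            if ex.start < prev_start:
                raise ValueError("exons must be sorted by start")
            prev_start = ex.start

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand == "+" else self.body.end - 1

    @property
    def promoter(self) -> GenomicInterval:
        if self.body.strand == "+":
            lo = self.tss - self.promoter_upstream
            hi = self.tss + self.promoter_downstream
        else:
            lo = self.tss - self.promoter_downstream + 1
            hi = self.tss + self.promoter_upstream + 1
        return GenomicInterval(self.body.chrom, max(0, lo), max(1, hi), self.body.strand)


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced accessibility fragment for one cell barcode."""

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment length must be >= 1 ({self.start}>={self.end})")
        if self.count < 1:
            raise ValueError("fragment count must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


@dataclass
class StrandedCoverage:
    """Per-chromosome, per-strand base-resolution signal vectors.

    ``plus[chrom]`` and ``minus[chrom]`` are float vectors of length
    ``chrom_lengths[chrom]``; values are non-negative signal magnitudes.
    """

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, n in self.chrom_lengths.items():
            for tracks in (self.plus, self.minus):
                v = tracks[chrom]
                if len(v) != n:
                    raise ValueError(f"coverage length mismatch on {chrom}")
                if np.any(v < 0):
                    raise ValueError(f"negative coverage on {chrom}")

    @classmethod
    def zeros(cls, chrom_lengths: Mapping[str, int]) -> "StrandedCoverage":
        return cls(
            plus={c: np.zeros(n) for c, n in chrom_lengths.items()},
            minus={c: np.zeros(n) for c, n in chrom_lengths.items()},
            chrom_lengths=dict(chrom_lengths),
        )

    def strand(self, name: str) -> dict[str, np.ndarray]:
        if name == "+":
            return self.plus
        if name == "-":
            return self.minus
        raise ValueError(f"unknown strand {name!r}")

    def total(self) -> float:
        return float(
            sum(v.sum() for v in self.plus.values())
            + sum(v.sum() for v in self.minus.values())
        )

    def combined(self) -> dict[str, np.ndarray]:
        """Strand-summed signal per chromosome."""
        return {c: self.plus[c] + self.minus[c] for c in self.chrom_lengths}


# ---------------------------------------------------------------------------
# count matrix and label table
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Features x samples count matrix with optional feature lengths (bp)."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    feature_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.feature_lengths is not None:
            self.feature_lengths = np.asarray(self.feature_lengths, dtype=float)
            if len(self.feature_lengths) != len(self.feature_ids):
                raise ValueError("feature_lengths inconsistent with ids")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def cpm(self) -> np.ndarray:
        lib = np.maximum(self.library_sizes, 1e-12)
        return self.counts / lib * 1e6

    def rpkm(self) -> np.ndarray:
        if self.feature_lengths is None:
            raise ValueError("rpkm requires feature_lengths")
        kb = np.maximum(self.feature_lengths, 1e-12)[:, None] / 1000.0
        return self.cpm() / kb

    def subset(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            feature_ids=[self.feature_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep],
            feature_lengths=None
            if self.feature_lengths is None
            else self.feature_lengths[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class CellLabelTable:
    """Barcode -> cluster/state label, with an optional condition field."""

    labels: dict[str, str]
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for bc, lab in self.labels.items():
            if not lab:
                raise ValueError(f"empty label for barcode {bc}")

    @property
    def barcodes(self) -> list[str]:
        return list(self.labels)

    def clusters(self) -> list[str]:
        return sorted(set(self.labels.values()))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_intervals(path: str | Path, min_columns: int = 3) -> list[GenomicInterval]:
    """Read a BED3/BED6(+) file into a list of intervals, in file order."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_columns or len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= {max(min_columns, 3)} columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name, score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (score formatted with full precision)."""
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.score:.10g}\t{iv.strand}\n"
            )


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a BED6+ gene table.

    Columns: chrom, start, end, name, score, strand, then optionally
    comma-separated exon starts and exon ends (absolute coordinates).
    """
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: gene table requires >= 6 columns")
            try:
                body = GenomicInterval(
                    f[0], int(f[1]), int(f[2]), f[5], f[3], float(f[4]) if f[4] != "." else 0.0
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            exons: tuple[GenomicInterval, ...] = ()
            if len(f) >= 8 and f[6] and f[7]:
                starts = [int(x) for x in f[6].rstrip(",").split(",")]
                ends = [int(x) for x in f[7].rstrip(",").split(",")]
                if len(starts) != len(ends):
                    raise ParseError(f"{path}:{lineno}: exon starts/ends mismatch")
                exons = tuple(
                    GenomicInterval(f[0], s, e, f[5]) for s, e in zip(starts, ends)
                )
            try:
                genes.append(GeneModel(body=body, exons=exons))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons)
            ends = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.body.chrom}\t{g.body.start}\t{g.body.end}\t{g.body.name or '.'}\t"
                f"{g.body.score:.10g}\t{g.body.strand}\t{starts}\t{ends}\n"
            )


def _read_bedgraph_into(path: str | Path, vec: Mapping[str, np.ndarray]) -> None:
    """Add bedGraph records into dense per-chromosome vectors (magnitudes)."""
    covered: dict[str, np.ndarray] = {c: np.zeros(len(v), dtype=bool) for c, v in vec.items()}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph requires 4 columns")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in vec:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            if end > len(vec[chrom]):
                raise ParseError(f"{path}:{lineno}: record beyond chromosome length")
            if covered[chrom][start:end].any():
                raise ParseError(f"{path}:{lineno}: overlapping bedGraph records")
            covered[chrom][start:end] = True
            vec[chrom][start:end] = abs(value)


def read_stranded_coverage(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_lengths: Mapping[str, int],
) -> StrandedCoverage:
    """Read a plus/minus bedGraph pair into dense stranded coverage."""
    cov = StrandedCoverage.zeros(chrom_lengths)
    _read_bedgraph_into(plus_path, cov.plus)
    _read_bedgraph_into(minus_path, cov.minus)
    return cov


def write_bedgraph(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write dense per-base vectors as run-length-collapsed bedGraph.

    Zero runs are omitted, so a write/read round trip through
    :func:`read_stranded_coverage` is exact.
    """
    with open(path, "wt") as fh:
        for chrom in sorted(track):
            v = np.asarray(track[chrom])
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.10g}\n")


def read_fragments(path: str | Path) -> Iterator[FragmentRecord]:
    """Stream a 10x-convention 5-column fragments TSV (plain or gzipped).

    The fifth (duplicate count) column defaults to 1 when absent.  Header
    lines starting with ``#`` are skipped.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: fragments require >= 4 columns")
            try:
                start, end = int(f[1]), int(f[2])
                count = int(f[4]) if len(f) > 4 else 1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad integer field") from exc
            try:
                yield FragmentRecord(f[0], start, end, f[3], count)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def write_fragments(records: Iterable[FragmentRecord], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.barcode}\t{r.count}\n")


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix: header row = sample ids, first column = feature ids.

    An optional ``length`` column (if present) is split out as feature lengths.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if "length" in df.columns:
        lengths = df["length"].to_numpy(float)
        df = df.drop(columns=["length"])
    return CountMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        counts=df.to_numpy(float),
        feature_lengths=lengths,
    )


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    if matrix.feature_lengths is not None:
        df = df.copy()
        df["length"] = matrix.feature_lengths
    df.to_csv(path, sep="\t", index_label="feature")


def read_cell_labels(path: str | Path) -> CellLabelTable:
    """Read a barcode -> label TSV (columns: barcode, label[, condition])."""
    labels: dict[str, str] = {}
    condition: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "barcode":  # header
                continue
            if len(f) < 2:
                raise ParseError(f"{path}:{lineno}: expected barcode<TAB>label")
            if f[0] in labels:
                raise ParseError(f"{path}:{lineno}: duplicate barcode {f[0]}")
            labels[f[0]] = f[1]
            if len(f) > 2:
                condition[f[0]] = f[2]
    return CellLabelTable(labels=labels, condition=condition)


def write_cell_labels(table: CellLabelTable, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("barcode\tlabel\tcondition\n")
        for bc, lab in table.labels.items():
            fh.write(f"{bc}\t{lab}\t{table.condition.get(bc, '')}\n")


# ---------------------------------------------------------------------------
# region arithmetic helpers shared across modules
# ---------------------------------------------------------------------------


def region_sum(track: Mapping[str, np.ndarray], iv: GenomicInterval) -> float:
    """Sum of a dense signal track over one interval."""
    v = track.get(iv.chrom)
    if v is None:
        return 0.0
    return float(v[iv.start : iv.end].sum())


def sort_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
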