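"""Readers, writers and coordinate-addressed containers for genomic tracks.

Every coordinate in this package is 0-based, half-open (BED convention):
an interval ``[start, end)`` covers bases ``start .. end-1``.  All parsers
are strict — a malformed line raises :class:`ParseError` naming the line
number rather than silently skipping it.

Formats handled here: BED5 / ENCODE narrowPeak (peaks), bedGraph and
optionally bigWig (coverage step functions), BEDPE (paired-anchor loops),
BED4 subcompartment annotations, chrom.sizes, BED4 genome segmentations,
and the TSV feature matrix produced by :mod:`compartmarks.features`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SUBCOMPARTMENTS = ("A1", "A2", "B1", "B2", "B3", "B4")


class ParseError(ValueError):
    """A malformed record in a genomic text file."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{self.path}:{line_number}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """An enriched-signal interval (ChIP-seq/DNase-seq etc.) with a signal value."""

    interval: GenomicInterval
    signal: float

    def __post_init__(self):
        if not (math.isfinite(self.signal) and self.signal >= 0):
            raise ValueError(f"peak signal must be finite and >= 0, got {self.signal}")


@dataclass(frozen=True)
class Loop:
    """A paired-anchor chromatin loop; the span runs anchor-start to anchor-end.

    The span interval (used for labeling and feature extraction) is the
    anchor-to-anchor extent including the loop interior.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    category: str
    name: str = ""

    def __post_init__(self):
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.anchor1.chrom,
            min(self.anchor1.start, self.anchor2.start),
            max(self.anchor1.end, self.anchor2.end),
        )


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length (bp)."""

    def __init__(self, sizes: Mapping[str, int]):
        for name, length in sizes.items():
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        self._sizes = dict(sizes)

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"


class CoverageTrack:
    """A per-chromosome step function: sorted non-overlapping (interval, value) steps.

    Positions outside every step have implicit value 0, so the mean over a
    region is always defined.
    """

    def __init__(self, steps: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # steps: chrom -> (starts, ends, values), each validated sorted/disjoint
        self._steps = {}
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("starts/ends/values length mismatch")
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted step")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping or unsorted steps")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: non-finite step value")
            self._steps[chrom] = (starts, ends, values)

    @classmethod
    def from_step_list(
        cls, steps: Iterable[tuple[GenomicInterval, float]]
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, val in steps:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, val))
        out = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.array(rows, dtype=np.float64)
            out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(out)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    def mean_over(self, region: GenomicInterval) -> float:
        """Length-weighted mean over every base of the region (uncovered = 0)."""
        starts, ends, values = self.steps(region.chrom)
        if len(starts) == 0:
            return 0.0
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], region.end) - np.maximum(
            starts[lo:hi], region.start
        )
        total = float(np.dot(ov, values[lo:hi]))
        return total / region.length


@dataclass(frozen=True)
class AnnotatedWindow:
    interval: GenomicInterval
    subcompartment: str


class CompartmentAnnotation:
    """Subcompartment-labeled genomic windows (Rao-style A1/A2/B1..B4)."""

    def __init__(self, windows: Sequence[AnnotatedWindow]):
        for w in windows:
            if w.subcompartment not in SUBCOMPARTMENTS:
                raise ValueError(f"unknown subcompartment label {w.subcompartment!r}")
        self._windows = list(windows)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for w in windows:
            by_chrom.setdefault(w.interval.chrom, []).append(
                (w.interval.start, w.interval.end, w.subcompartment)
            )
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            labels = np.array([r[2] for r in rows], dtype=object)
            self._by_chrom[chrom] = (starts, ends, labels)

    @property
    def windows(self) -> list[AnnotatedWindow]:
        return list(self._windows)

    def __len__(self) -> int:
        return len(self._windows)

    def subcompartments_overlapping(self, region: GenomicInterval) -> list[str]:
        """Subcompartment labels of every annotation window overlapping by >= 1 bp."""
        if region.chrom not in self._by_chrom:
            return []
        starts, ends, labels = self._by_chrom[region.chrom]
        mask = (starts < region.end) & (ends > region.start)
        return list(labels[mask])


@dataclass(frozen=True)
class SegmentationSegment:
    interval: GenomicInterval
    state: str


class Segmentation:
    """Genome-segmentation intervals (ChromHMM/Segway-style) with raw state labels."""

    def __init__(self, segments: Sequence[SegmentationSegment]):
        self._segments = list(segments)
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for s in segments:
            by_chrom.setdefault(s.interval.chrom, []).append(
                (s.interval.start, s.interval.end, s.state)
            )
        self._by_chrom = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            self._by_chrom[chrom] = (
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
                np.array([r[2] for r in rows], dtype=object),
            )

    @property
    def segments(self) -> list[SegmentationSegment]:
        return list(self._segments)

    def segments_overlapping(
        self, region: GenomicInterval
    ) -> list[tuple[GenomicInterval, str]]:
        if region.chrom not in self._by_chrom:
            return []
        starts, ends, states = self._by_chrom[region.chrom]
        mask = (starts < region.end) & (ends > region.start)
        return [
            (GenomicInterval(region.chrom, int(s), int(e)), st)
            for s, e, st in zip(starts[mask], ends[mask], states[mask])
        ]


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def _data_lines(path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) skipping blanks, comments, track lines."""
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield i, line.split("\t") if "\t" in line else line.split()


def _parse_interval(path, lineno: int, fields: Sequence[str]) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
    if end <= start or start < 0:
        raise ParseError(path, lineno, f"invalid interval [{start}, {end})")
    return GenomicInterval(fields[0], start, end)


def read_peaks(path, dialect: str = "narrowPeak") -> list[Peak]:
    """Read a peak file.

    ``dialect="bed5"`` takes the signal from column 5 (score);
    ``dialect="narrowPeak"`` takes it from column 7 (signalValue) — the score
    column of narrowPeak is capped for display and not used.
    """
    if dialect not in ("bed5", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    signal_col = 4 if dialect == "bed5" else 6
    min_cols = 5 if dialect == "bed5" else 7
    peaks = []
    for lineno, fields in _data_lines(path):
        if len(fields) < min_cols:
            raise ParseError(
                path, lineno, f"expected >= {min_cols} columns, got {len(fields)}"
            )
        iv = _parse_interval(path, lineno, fields)
        try:
            signal = float(fields[signal_col])
        except ValueError:
            raise ParseError(
                path, lineno, f"non-numeric signal {fields[signal_col]!r}"
            ) from None
        if not (math.isfinite(signal) and signal >= 0):
            raise ParseError(path, lineno, f"signal must be finite >= 0, got {signal}")
        peaks.append(Peak(iv, signal))
    return peaks


def read_coverage(path, format: str = "bedGraph") -> CoverageTrack:
    """Read a coverage step function from bedGraph or bigWig.

    bedGraph steps must be non-overlapping within a chromosome; overlap is a
    format error (a step function would be ambiguous).
    """
    if format == "bedGraph":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for lineno, fields in _data_lines(path):
            if len(fields) < 4:
                raise ParseError(path, lineno, "bedGraph needs 4 columns")
            iv = _parse_interval(path, lineno, fields)
            try:
                value = float(fields[3])
            except ValueError:
                raise ParseError(
                    path, lineno, f"non-numeric value {fields[3]!r}"
                ) from None
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
        steps = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ParseError(path, 0, f"overlapping bedGraph steps on {chrom}")
            steps[chrom] = (starts, ends, np.array([r[2] for r in rows]))
        return CoverageTrack(steps)
    if format == "bigWig":
        try:
            import pyBigWig  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional backend
            raise RuntimeError("bigWig support requires pyBigWig") from exc
        bw = pyBigWig.open(str(path))
        steps = {}
        try:
            for chrom in bw.chroms():
                ivals = bw.intervals(chrom) or []
                if ivals:
                    arr = np.array(ivals, dtype=np.float64)
                    steps[chrom] = (
                        arr[:, 0].astype(np.int64),
                        arr[:, 1].astype(np.int64),
                        arr[:, 2],
                    )
        finally:
            bw.close()
        return CoverageTrack(steps)
    raise ValueError(f"unknown coverage format {format!r}")


def read_loops(path, category: str) -> list[Loop]:
    """Read a BEDPE-like loop file; anchors may appear in either order.

    Inter-chromosomal rows are dropped (loops here are intra-chromosomal
    domains); the dropped count is logged.
    """
    loops = []
    dropped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(path, lineno, "BEDPE needs >= 6 columns")
        try:
            c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
            c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        if e1 <= s1 or e2 <= s2 or s1 < 0 or s2 < 0:
            raise ParseError(path, lineno, "invalid anchor interval")
        if c1 != c2:
            dropped += 1
            continue
        name = fields[6] if len(fields) > 6 else ""
        a1 = GenomicInterval(c1, s1, e1)
        a2 = GenomicInterval(c2, s2, e2)
        if a1.start > a2.start:  # order-invariant span
            a1, a2 = a2, a1
        loops.append(Loop(a1, a2, category=category, name=name))
    if dropped:
        logger.info("read_loops(%s): dropped %d inter-chromosomal rows", path, dropped)
    return loops


def read_compartment_annotation(path) -> CompartmentAnnotation:
    """Read a BED4 file of subcompartment-labeled windows (A1/A2/B1/B2/B3/B4)."""
    windows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, "annotation needs 4 columns")
        iv = _parse_interval(path, lineno, fields)
        label = fields[3]
        if label not in SUBCOMPARTMENTS:
            raise ParseError(path, lineno, f"unknown subcompartment label {label!r}")
        windows.append(AnnotatedWindow(iv, label))
    return CompartmentAnnotation(windows)


def read_segmentation(path) -> Segmentation:
    """Read a BED4 genome-segmentation file; states are kept verbatim."""
    segments = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, "segmentation needs 4 columns")
        iv = _parse_interval(path, lineno, fields)
        segments.append(SegmentationSegment(iv, fields[3]))
    return Segmentation(segments)


def read_chrom_sizes(path) -> ChromSizes:
    sizes: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "chrom.sizes needs 2 columns")
        name = fields[0]
        if name in sizes:
            raise ParseError(path, lineno, f"duplicate chromosome {name!r}")
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer length {fields[1]!r}") from None
        if length <= 0:
            raise ParseError(path, lineno, f"non-positive length for {name!r}")
        sizes[name] = length
    return ChromSizes(sizes)


# ---------------------------------------------------------------------------
# Writers (used by the synthetic generator and the pipeline)
# ---------------------------------------------------------------------------


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def write_peaks(peaks: Sequence[Peak], path, dialect: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            if dialect == "bed5":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t{float(p.signal)!r}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t0\t.\t"
                    f"{float(p.signal)!r}\t-1\t-1\t-1\n"
                )


def write_coverage(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            starts, ends, values = track.steps(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def write_loops(loops: Sequence[Loop], path) -> None:
    with open(path, "w") as fh:
        for i, lp in enumerate(loops):
            a1, a2 = lp.anchor1, lp.anchor2
            name = lp.name or f"loop{i}"
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t"
                f"{a2.chrom}\t{a2.start}\t{a2.end}\t{name}\n"
            )


def write_compartment_annotation(annotation: CompartmentAnnotation, path) -> None:
    with open(path, "w") as fh:
        for w in annotation.windows:
            iv = w.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{w.subcompartment}\n")


def write_segmentation(segmentation: Segmentation, path) -> None:
    with open(path, "w") as fh:
        for s in segmentation.segments:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.state}\n")


def write_feature_matrix(matrix, path) -> None:
    """TSV with region_id, label, then one column per "mark:representation"."""
    matrix.to_tsv(path)


def read_feature_matrix(path):
    from .features import FeatureMatrix

    return FeatureMatrix.from_tsv(path)
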