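"""Per-region feature representations of genomic marks.

Each mark contributes up to four numeric representations per region:

* ``fraction`` — fraction of the region covered by the merged union of peaks;
* ``peak_sum`` / ``peak_mean`` — sum / mean of signal of peaks overlapping
  the region by >= 1 bp (full peak signal, not pro-rated by overlap length;
  a pro-rated variant is available via ``prorate=True``);
* ``whole_signal_mean`` — length-weighted mean of the coverage step function
  over the region, uncovered bases contributing 0;
* ``state_fraction:<state>`` — fraction of the region in each collapsed
  segmentation class (active / repressed / heterochromatin); bases not
  assigned to a repressed or heterochromatin segment count as active.

Regions with no overlapping peaks get 0.0 for sum and mean so that the
feature matrix stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GenomicInterval, Peak, Segmentation
from .labeling import LabeledRegion

logger = logging.getLogger(__name__)

SEGMENTATION_CLASSES = ("active", "repressed", "heterochromatin")

#: Default collapse of common segmentation-state vocabularies onto the three
#: classes; states absent from the mapping are a configuration error, except
#: that unsegmented *territory* is active by definition.
DEFAULT_STATE_MAP = {
    "active": "active",
    "promoter": "active",
    "enhancer": "active",
    "transcribed": "active",
    "insulator": "active",
    "repressed": "repressed",
    "polycomb": "repressed",
    "heterochromatin": "heterochromatin",
    "repetitive": "heterochromatin",
    "cnv": "heterochromatin",
}

REPRESENTATIONS = ("fraction", "peak_mean", "peak_sum", "whole_signal_mean")


@dataclass(frozen=True)
class FeatureDescriptor:
    """One column of the feature matrix: a mark and how it is summarized."""

    mark: str
    representation: str

    @property
    def identifier(self) -> str:
        return f"{self.mark}:{self.representation}"

    @classmethod
    def from_identifier(cls, identifier: str) -> "FeatureDescriptor":
        mark, _, representation = identifier.partition(":")
        if not mark or not representation:
            raise ValueError(f"bad feature identifier {identifier!r}")
        return cls(mark, representation)


@dataclass
class FeatureMatrix:
    """Regions x features table with A/B labels and per-column metadata."""

    region_ids: list[str]
    labels: np.ndarray  # array of "A"/"B" strings
    descriptors: list[FeatureDescriptor]
    values: np.ndarray  # shape (n_regions, n_features), float64

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n, d = len(self.region_ids), len(self.descriptors)
        if self.values.shape != (n, d):
            raise ValueError(
                f"values shape {self.values.shape} != ({n}, {d})"
            )
        if len(self.labels) != n:
            raise ValueError("labels length mismatch")
        if n and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        ids = [dd.identifier for dd in self.descriptors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature identifiers")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    @property
    def feature_ids(self) -> list[str]:
        return [d.identifier for d in self.descriptors]

    def column(self, identifier: str) -> np.ndarray:
        try:
            j = self.feature_ids.index(identifier)
        except ValueError:
            raise KeyError(f"no feature {identifier!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df.insert(0, "label", self.labels)
        df.insert(0, "region_id", self.region_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        if list(df.columns[:2]) != ["region_id", "label"]:
            raise ValueError("feature matrix TSV must start with region_id, label")
        descriptors = [FeatureDescriptor.from_identifier(c) for c in df.columns[2:]]
        return cls(
            region_ids=[str(r) for r in df["region_id"]],
            labels=df["label"].to_numpy(dtype=object),
            descriptors=descriptors,
            values=df.iloc[:, 2:]
            .to_numpy(dtype=np.float64)
            .reshape(len(df), len(descriptors)),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.region_ids == other.region_ids
            and list(self.labels) == list(other.labels)
            and self.descriptors == other.descriptors
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )


# ---------------------------------------------------------------------------
# Per-region summaries
# ---------------------------------------------------------------------------


class PeakIndex:
    """Per-chromosome arrays of peak coordinates/signals for fast overlap
    queries; the public per-region functions and the matrix builder share
    this one code path."""

    def __init__(self, peaks: Sequence[Peak]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for p in peaks:
            by_chrom.setdefault(p.interval.chrom, []).append(
                (p.interval.start, p.interval.end, p.signal)
            )
        self._by_chrom = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            self._by_chrom[chrom] = (
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
                np.array([r[2] for r in rows], dtype=np.float64),
            )

    def hits(
        self, region: GenomicInterval
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, signals) of peaks overlapping the region by >= 1 bp."""
        if region.chrom not in self._by_chrom:
            empty = np.empty(0)
            return empty.astype(np.int64), empty.astype(np.int64), empty
        starts, ends, signals = self._by_chrom[region.chrom]
        mask = (starts < region.end) & (ends > region.start)
        return starts[mask], ends[mask], signals[mask]

    def fraction_covered(self, region: GenomicInterval) -> float:
        starts, ends, _ = self.hits(region)
        covered = 0
        cur_start: Optional[int] = None
        cur_end = 0
        # starts already sorted; merge clipped intervals in one sweep
        for s, e in zip(
            np.maximum(starts, region.start), np.minimum(ends, region.end)
        ):
            if cur_start is None:
                cur_start, cur_end = s, e
            elif s <= cur_end:
                cur_end = max(cur_end, e)
            else:
                covered += cur_end - cur_start
                cur_start, cur_end = s, e
        if cur_start is not None:
            covered += cur_end - cur_start
        return covered / region.length

    def signal_sum(self, region: GenomicInterval, prorate: bool = False) -> float:
        starts, ends, signals = self.hits(region)
        if prorate and len(signals):
            frac_inside = (
                np.minimum(ends, region.end) - np.maximum(starts, region.start)
            ) / (ends - starts)
            return float(np.dot(signals, frac_inside))
        return float(signals.sum())

    def signal_mean(self, region: GenomicInterval, prorate: bool = False) -> float:
        _, _, signals = self.hits(region)
        if len(signals) == 0:
            return 0.0
        return self.signal_sum(region, prorate=prorate) / len(signals)


def fraction_covered(region: GenomicInterval, peaks: Sequence[Peak]) -> float:
    """Fraction of the region covered by the merged union of peak intervals."""
    return PeakIndex(peaks).fraction_covered(region)


def peak_signal_sum(
    region: GenomicInterval, peaks: Sequence[Peak], prorate: bool = False
) -> float:
    """Sum of signal over peaks overlapping the region by >= 1 bp (0.0 if
    none).  With ``prorate=True`` each peak's signal is scaled by the
    fraction of the peak inside the region."""
    return PeakIndex(peaks).signal_sum(region, prorate=prorate)


def peak_signal_mean(
    region: GenomicInterval, peaks: Sequence[Peak], prorate: bool = False
) -> float:
    """Mean signal of peaks overlapping the region (0.0 if none)."""
    return PeakIndex(peaks).signal_mean(region, prorate=prorate)


def whole_signal_mean(region: GenomicInterval, track: CoverageTrack) -> float:
    """Length-weighted mean of a coverage step function over the region."""
    return track.mean_over(region)


def state_fractions(
    region: GenomicInterval,
    segmentation: Segmentation,
    state_map: Mapping[str, str] = DEFAULT_STATE_MAP,
) -> dict[str, float]:
    """Fraction of the region in each collapsed segmentation class.

    Bases covered by no segment are active (states other than repressed and
    heterochromatin — including "no state" — collapse to active).  Fractions
    sum to 1.  Overlapping segments within one class are counted once; if
    segments of different classes overlap, repressed/heterochromatin take
    precedence over the active default via per-base resolution.
    """
    hits = segmentation.segments_overlapping(region)
    for _, state in hits:
        if state not in state_map:
            raise ValueError(f"segmentation state {state!r} has no class mapping")
        if state_map[state] not in SEGMENTATION_CLASSES:
            raise ValueError(
                f"state {state!r} maps to unknown class {state_map[state]!r}"
            )
    # Per-base resolution over the region: cheap at window/loop scale and
    # unambiguous when segments overlap.
    classes = np.zeros(region.length, dtype=np.int8)  # 0 active, 1 repr, 2 het
    code = {"active": 0, "repressed": 1, "heterochromatin": 2}
    for iv, state in hits:
        c = code[state_map[state]]
        if c == 0:
            continue
        s = max(iv.start, region.start) - region.start
        e = min(iv.end, region.end) - region.start
        classes[s:e] = np.maximum(classes[s:e], c)
    n = region.length
    return {
        "active": float(np.count_nonzero(classes == 0)) / n,
        "repressed": float(np.count_nonzero(classes == 1)) / n,
        "heterochromatin": float(np.count_nonzero(classes == 2)) / n,
    }


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------


@dataclass
class MarkTracks:
    """Loaded tracks for one mark; any subset of the three kinds."""

    peaks: Optional[Sequence[Peak]] = None
    coverage: Optional[CoverageTrack] = None
    segmentation: Optional[Segmentation] = None
    state_map: Mapping[str, str] = field(default_factory=lambda: DEFAULT_STATE_MAP)


def _check_plan(plan: Sequence[FeatureDescriptor], catalog: Mapping[str, MarkTracks]):
    for desc in plan:
        if desc.mark not in catalog:
            raise KeyError(f"feature {desc.identifier!r}: mark not in catalog")
        tracks = catalog[desc.mark]
        rep = desc.representation
        if rep in ("fraction", "peak_mean", "peak_sum") and tracks.peaks is None:
            raise KeyError(f"feature {desc.identifier!r}: no peak track loaded")
        if rep == "whole_signal_mean" and tracks.coverage is None:
            raise KeyError(f"feature {desc.identifier!r}: no coverage track loaded")
        if rep.startswith("state_fraction:"):
            if tracks.segmentation is None:
                raise KeyError(f"feature {desc.identifier!r}: no segmentation loaded")
            state = rep.split(":", 1)[1]
            if state not in SEGMENTATION_CLASSES:
                raise KeyError(f"feature {desc.identifier!r}: unknown class {state!r}")
        elif rep not in REPRESENTATIONS:
            raise KeyError(f"unknown representation {rep!r}")


def build_feature_matrix(
    regions: Sequence[LabeledRegion],
    catalog: Mapping[str, MarkTracks],
    plan: Sequence[FeatureDescriptor],
    prorate_peak_signal: bool = False,
) -> FeatureMatrix:
    """Evaluate every planned feature on every labeled region.

    Column order follows the plan; the whole plan is validated against the
    catalog before any computation starts.
    """
    _check_plan(plan, catalog)
    n, d = len(regions), len(plan)
    values = np.zeros((n, d), dtype=np.float64)
    peak_indexes: dict[str, PeakIndex] = {}

    def _index(mark: str) -> PeakIndex:
        if mark not in peak_indexes:
            peak_indexes[mark] = PeakIndex(catalog[mark].peaks)
        return peak_indexes[mark]

    for j, desc in enumerate(plan):
        tracks = catalog[desc.mark]
        rep = desc.representation
        if rep == "fraction":
            idx = _index(desc.mark)
            col = [idx.fraction_covered(r.interval) for r in regions]
        elif rep == "peak_sum":
            idx = _index(desc.mark)
            col = [
                idx.signal_sum(r.interval, prorate_peak_signal) for r in regions
            ]
        elif rep == "peak_mean":
            idx = _index(desc.mark)
            col = [
                idx.signal_mean(r.interval, prorate_peak_signal) for r in regions
            ]
        elif rep == "whole_signal_mean":
            col = [whole_signal_mean(r.interval, tracks.coverage) for r in regions]
        else:  # state_fraction:<class>
            state = rep.split(":", 1)[1]
            col = [
                state_fractions(r.interval, tracks.segmentation, tracks.state_map)[
                    state
                ]
                for r in regions
            ]
        values[:, j] = col
    return FeatureMatrix(
        region_ids=[r.region_id for r in regions],
        labels=np.array([r.label.value for r in regions], dtype=object),
        descriptors=list(plan),
        values=values,
    )


def default_plan(catalog: Mapping[str, MarkTracks]) -> list[FeatureDescriptor]:
    """Every representation supported by each mark's loaded tracks."""
    plan = []
    for mark in catalog:
        tracks = catalog[mark]
        if tracks.peaks is not None:
            for rep in ("fraction", "peak_mean", "peak_sum"):
                plan.append(FeatureDescriptor(mark, rep))
        if tracks.coverage is not None:
            plan.append(FeatureDescriptor(mark, "whole_signal_mean"))
        if tracks.segmentation is not None:
            for cls in SEGMENTATION_CLASSES:
                plan.append(FeatureDescriptor(mark, f"state_fraction:{cls}"))
    return plan
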