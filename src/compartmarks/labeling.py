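"""A/B compartment labeling of loops and genomic windows.

Hi-C subcompartments map many-to-one onto the two principal compartments:
A1 and A2 belong to compartment A (broadly active chromatin), B1–B4 to
compartment B (inactive).  A region is labeled A (or B) when every
annotation window it touches belongs to that compartment; regions touching
both compartments, or only unannotated territory, are excluded from
classification — a region of mixed compartment state has no single class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Sequence, Union

from .genomic_io import ChromSizes, CompartmentAnnotation, GenomicInterval, Loop

SUBCOMPARTMENT_TO_COMPARTMENT = {
    "A1": "A",
    "A2": "A",
    "B1": "B",
    "B2": "B",
    "B3": "B",
    "B4": "B",
}

DEFAULT_WINDOW_WIDTH = 100_000


class RegionLabel(str, Enum):
    A = "A"
    B = "B"
    EXCLUDED = "EXCLUDED"


Region = Union[Loop, GenomicInterval]


@dataclass(frozen=True)
class LabeledRegion:
    """A loop or window with its compartment label and source category."""

    region_id: str
    region: Region
    label: RegionLabel
    category: str

    @property
    def interval(self) -> GenomicInterval:
        return self.region.span if isinstance(self.region, Loop) else self.region


def map_subcompartment(label: str) -> str:
    """A1, A2 -> "A"; B1..B4 -> "B"."""
    try:
        return SUBCOMPARTMENT_TO_COMPARTMENT[label]
    except KeyError:
        raise ValueError(f"unknown subcompartment label {label!r}") from None


def tile_genome(
    sizes: ChromSizes, width: int = DEFAULT_WINDOW_WIDTH
) -> list[GenomicInterval]:
    """Consecutive non-overlapping windows per chromosome; trailing partial
    windows (shorter than ``width``) are dropped."""
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    windows = []
    for chrom, length in sizes.items():
        for start in range(0, length - width + 1, width):
            windows.append(GenomicInterval(chrom, start, start + width))
    return windows


def label_region(region: Region, annotation: CompartmentAnnotation) -> RegionLabel:
    """Compartment of a region from the annotation windows it overlaps.

    Overlap is >= 1 bp.  Pure-A overlap -> A; pure-B -> B; both, or no
    annotated overlap at all -> EXCLUDED.
    """
    interval = region.span if isinstance(region, Loop) else region
    compartments = {
        map_subcompartment(sc)
        for sc in annotation.subcompartments_overlapping(interval)
    }
    if compartments == {"A"}:
        return RegionLabel.A
    if compartments == {"B"}:
        return RegionLabel.B
    return RegionLabel.EXCLUDED


def label_all(
    regions: Sequence[Region],
    annotation: CompartmentAnnotation,
    category: str = "",
) -> tuple[list[LabeledRegion], dict]:
    """Label every region, drop EXCLUDED ones, and summarize.

    Returns the kept regions (input order preserved) and a summary dict with
    total/kept counts, the kept fraction, and per-class counts.  Raises if no
    region survives or the kept set is single-class — classification is
    undefined then.
    """
    if not regions:
        raise ValueError("no regions to label")
    kept: list[LabeledRegion] = []
    counts = {"A": 0, "B": 0}
    for i, region in enumerate(regions):
        label = label_region(region, annotation)
        if label is RegionLabel.EXCLUDED:
            continue
        cat = category or (region.category if isinstance(region, Loop) else "window")
        name = getattr(region, "name", "") or f"{cat}_{i}"
        kept.append(LabeledRegion(name, region, label, cat))
        counts[label.value] += 1
    summary = {
        "total": len(regions),
        "kept": len(kept),
        "kept_fraction": len(kept) / len(regions),
        "class_counts": counts,
        "a_fraction_of_kept": counts["A"] / len(kept) if kept else float("nan"),
    }
    if not kept:
        raise ValueError("all regions excluded; classification undefined")
    if counts["A"] == 0 or counts["B"] == 0:
        raise ValueError(
            "kept regions all in one compartment; classification undefined "
            f"(counts={counts})"
        )
    return kept, summary


def write_labeled_regions(regions: Sequence[LabeledRegion], path) -> None:
    """TSV: region id, chrom, start, end, category, label."""
    with open(path, "w") as fh:
        fh.write("region_id\tchrom\tstart\tend\tcategory\tlabel\n")
        for r in regions:
            iv = r.interval
            fh.write(
                f"{r.region_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{r.category}\t{r.label.value}\n"
            )


def write_label_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
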