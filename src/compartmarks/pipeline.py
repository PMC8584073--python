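"""End-to-end stage drivers shared by the CLI, the analysis scripts and tests.

A pipeline run is: load (or simulate) a compartment annotation, loops and
mark tracks; label regions A/B; build the feature matrix; rank features by
MCFS RI x ANOVA F; benchmark the classifier battery.  The stage functions
here operate on in-memory objects so every entry point (CLI subcommand,
analysis driver, acceptance script) shares one code path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .features import (
    DEFAULT_STATE_MAP,
    FeatureDescriptor,
    FeatureMatrix,
    MarkTracks,
    build_feature_matrix,
    default_plan,
)
from .genomic_io import (
    CompartmentAnnotation,
    read_chrom_sizes,
    read_compartment_annotation,
    read_coverage,
    read_loops,
    read_peaks,
    read_segmentation,
)
from .harness import ClassifierReport, evaluate_battery
from .labeling import LabeledRegion, label_all, tile_genome
from .ranking import MCFSParams, rank_features
from .simulate import SyntheticDataset


@dataclass
class MarkSource:
    """Where one mark's tracks come from on disk."""

    name: str
    kind: str  # "peak" | "coverage" | "segmentation"
    path: str
    dialect: str = "narrowPeak"  # peak dialect, or coverage format
    state_map: Mapping[str, str] = field(default_factory=lambda: DEFAULT_STATE_MAP)


def load_catalog(sources: Sequence[MarkSource], base_dir=".") -> dict[str, MarkTracks]:
    base = Path(base_dir)
    catalog: dict[str, MarkTracks] = {}
    for src in sources:
        path = base / src.path
        if src.kind == "peak":
            catalog[src.name] = MarkTracks(peaks=read_peaks(path, src.dialect))
        elif src.kind == "coverage":
            fmt = src.dialect if src.dialect in ("bedGraph", "bigWig") else "bedGraph"
            catalog[src.name] = MarkTracks(coverage=read_coverage(path, fmt))
        elif src.kind == "segmentation":
            catalog[src.name] = MarkTracks(
                segmentation=read_segmentation(path), state_map=src.state_map
            )
        else:
            raise ValueError(f"unknown mark kind {src.kind!r}")
    return catalog


def catalog_from_manifest(dataset_dir) -> tuple[dict[str, MarkTracks], dict]:
    """Load the mark catalog of a generated synthetic dataset from its manifest."""
    dataset_dir = Path(dataset_dir)
    with open(dataset_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    sources = []
    for mark in manifest["marks"]:
        key = f"mark:{mark['name']}"
        dialect = {"peak": "narrowPeak", "coverage": "bedGraph", "segmentation": ""}[
            mark["kind"]
        ]
        sources.append(
            MarkSource(mark["name"], mark["kind"], manifest["files"][key], dialect)
        )
    return load_catalog(sources, base_dir=dataset_dir), manifest


def label_regions(
    annotation: CompartmentAnnotation,
    mode: str,
    loops: Optional[Sequence] = None,
    chrom_sizes=None,
    window_width: int = 100_000,
) -> tuple[list[LabeledRegion], dict]:
    """Label loops or tiled genome windows A/B against the annotation."""
    if mode == "loops":
        if not loops:
            raise ValueError("loops mode needs loops")
        return label_all(list(loops), annotation)
    if mode == "windows":
        if chrom_sizes is None:
            raise ValueError("windows mode needs chromosome sizes")
        windows = tile_genome(chrom_sizes, window_width)
        return label_all(windows, annotation, category="window")
    raise ValueError(f"unknown region mode {mode!r}")


def features_stage(
    regions: Sequence[LabeledRegion],
    catalog: Mapping[str, MarkTracks],
    plan: Optional[Sequence[FeatureDescriptor]] = None,
) -> FeatureMatrix:
    plan = list(plan) if plan is not None else default_plan(catalog)
    return build_feature_matrix(regions, catalog, plan)


def dataset_feature_matrix(
    dataset: SyntheticDataset,
    mode: str = "windows",
    loop_category: Optional[str] = None,
) -> tuple[FeatureMatrix, dict]:
    """Labeled feature matrix straight from an in-memory synthetic dataset."""
    if mode == "loops":
        if loop_category is not None:
            loops = dataset.loops[loop_category]
        else:
            loops = [lp for cat in dataset.loops.values() for lp in cat]
        regions, summary = label_regions(dataset.annotation, "loops", loops=loops)
    else:
        regions, summary = label_regions(
            dataset.annotation,
            "windows",
            chrom_sizes=dataset.config.chrom_sizes,
            window_width=dataset.config.window_width,
        )
    return features_stage(regions, dataset.catalog), summary


def ranking_stage(
    matrix: FeatureMatrix,
    params: Optional[MCFSParams] = None,
    with_auc: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    return rank_features(matrix, params=params, with_auc=with_auc, seed=seed)


def classify_stage(
    matrix: FeatureMatrix, k: int = 10, seed: int = 0
) -> ClassifierReport:
    return evaluate_battery(matrix, k=k, seed=seed)


def provenance_header(seed, config: Optional[dict] = None) -> str:
    """One-line '# ...' comment with version, config hash and seed, prepended
    to pipeline output files so results are traceable."""
    digest = hashlib.sha1(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# compartmarks v{__version__} seed={seed} config_sha1={digest}\n"


def write_with_header(text_writer, path, seed, config: Optional[dict] = None) -> None:
    """Write a table via ``text_writer(buffer)`` with a provenance header."""
    import io

    buf = io.StringIO()
    text_writer(buf)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config))
        fh.write(buf.getvalue())
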