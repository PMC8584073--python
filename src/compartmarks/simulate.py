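"""Synthetic epigenome generator with planted compartment structure.

The generator emulates the statistical shape of the real inputs the pipeline
consumes, at desk scale:

* a genome partitioned into alternating A/B compartment blocks whose lengths
  are geometric in 100 kb window units (A/B switching on a ~400 kb scale),
  each window carrying a subcompartment label (A1/A2 inside A, B1/B2/B3
  inside B);
* chromatin loops with log-normal spans (median 185 kb) truncated to
  [40 kb, 3 Mb], 5 kb anchors, placed uniformly, split into CTCF-convergent,
  CTCF-tandem and RNAPII categories;
* genomic-mark tracks — peak files, coverage step functions, and a 3-state
  genome segmentation — where an *informative* mark's distribution differs
  between compartments with effect size ``delta`` (peak rate multiplied by
  ``1 + delta`` in the enriched compartment; coverage mean shifted by
  ``delta`` step-SDs; segmentation state odds tilted by ``delta``), while
  noise marks are identically distributed in A and B.

Everything is deterministic given the configuration seed, and every emitted
file parses back through :mod:`compartmarks.genomic_io`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import genomic_io as gio
from .features import DEFAULT_STATE_MAP, MarkTracks
from .genomic_io import (
    AnnotatedWindow,
    ChromSizes,
    CompartmentAnnotation,
    CoverageTrack,
    GenomicInterval,
    Loop,
    Peak,
    Segmentation,
    SegmentationSegment,
)

A_SUBCOMPARTMENTS = ("A1", "A2")
B_SUBCOMPARTMENTS = ("B1", "B2", "B3")

LOOP_CATEGORIES = ("ctcf_convergent", "ctcf_tandem", "rnapii")


@dataclass(frozen=True)
class MarkConfig:
    """One synthetic mark: its track kind and planted effect size.

    ``delta`` = 0 makes the mark pure noise (identical A/B distributions);
    ``enriched_in`` says which compartment gets the excess signal.
    """

    name: str
    kind: str  # "peak" | "coverage" | "segmentation"
    delta: float = 0.0
    enriched_in: str = "A"
    peak_density: float = 1.0 / 40_000.0  # expected peaks per bp
    peak_width: tuple[int, int] = (200, 1500)
    signal_scale: float = 5.0
    coverage_bin: int = 10_000
    coverage_mean: float = 1.0
    coverage_sd: float = 0.3
    segment_length: int = 25_000

    def __post_init__(self):
        if self.kind not in ("peak", "coverage", "segmentation"):
            raise ValueError(f"unknown mark kind {self.kind!r}")
        if self.delta < 0:
            raise ValueError("effect size delta must be >= 0")
        if self.enriched_in not in ("A", "B"):
            raise ValueError("enriched_in must be 'A' or 'B'")

    @property
    def informative(self) -> bool:
        return self.delta > 0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12_000_000, "chr2": 8_000_000}
    )
    window_width: int = 100_000
    block_scale: int = 400_000  # mean A<->B switching distance
    a_fraction: float = 0.6
    loops_per_category: dict[str, int] = field(
        default_factory=lambda: {
            "ctcf_convergent": 120,
            "ctcf_tandem": 60,
            "rnapii": 120,
        }
    )
    loop_median: float = 185_000.0
    loop_sigma: float = 0.6  # log-scale SD; ~99% of mass in [40 kb, 3 Mb]
    loop_bounds: tuple[int, int] = (40_000, 3_000_000)
    anchor_width: int = 5_000
    marks: list[MarkConfig] = field(default_factory=list)

    def __post_init__(self):
        if not self.marks:
            self.marks = default_marks()
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if not (0 < self.a_fraction < 1):
            raise ValueError("a_fraction must be in (0, 1)")
        if self.block_scale < self.window_width:
            raise ValueError("block scale must be >= one window")

    @property
    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes(self.chromosomes)


def default_marks(
    n_informative: int = 5, n_noise: int = 10, delta: float = 2.0
) -> list[MarkConfig]:
    """A default catalog: informative peak/coverage/segmentation marks plus
    pure-noise peak marks, alternating the enriched compartment."""
    marks: list[MarkConfig] = []
    kinds = ["peak", "coverage", "segmentation"]
    for i in range(n_informative):
        marks.append(
            MarkConfig(
                name=f"inf_{kinds[i % 3]}_{i}",
                kind=kinds[i % 3],
                delta=delta,
                enriched_in="A" if i % 2 == 0 else "B",
            )
        )
    for i in range(n_noise):
        marks.append(MarkConfig(name=f"noise_peak_{i}", kind="peak", delta=0.0))
    return marks


# ---------------------------------------------------------------------------
# Compartments
# ---------------------------------------------------------------------------


def simulate_compartments(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> CompartmentAnnotation:
    """Alternating A/B blocks, geometric lengths in window units.

    The mean block length of compartment c is ``2 * f_c * block_scale`` so
    that the long-run fraction of A territory is ``a_fraction`` while the
    average block is ``block_scale``.  Each 100 kb window gets a
    subcompartment drawn uniformly within its block's compartment.
    Chromosomes shorter than one window are skipped.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    w = config.window_width
    mean_windows = {
        "A": max(2 * config.a_fraction * config.block_scale / w, 1.0),
        "B": max(2 * (1 - config.a_fraction) * config.block_scale / w, 1.0),
    }
    windows: list[AnnotatedWindow] = []
    for chrom, length in config.chromosomes.items():
        n_windows = length // w
        if n_windows == 0:
            continue
        comp = "A" if rng.random() < config.a_fraction else "B"
        i = 0
        while i < n_windows:
            block = max(int(rng.geometric(1.0 / mean_windows[comp])), 1)
            for j in range(i, min(i + block, n_windows)):
                sub = rng.choice(
                    A_SUBCOMPARTMENTS if comp == "A" else B_SUBCOMPARTMENTS
                )
                windows.append(
                    AnnotatedWindow(GenomicInterval(chrom, j * w, (j + 1) * w), str(sub))
                )
            i += block
            comp = "B" if comp == "A" else "A"
    return CompartmentAnnotation(windows)


# ---------------------------------------------------------------------------
# Loops
# ---------------------------------------------------------------------------


def _sample_loop_size(config: SimulationConfig, rng: np.random.Generator) -> int:
    lo, hi = config.loop_bounds
    mu = np.log(config.loop_median)
    for _ in range(1000):
        size = int(np.exp(rng.normal(mu, config.loop_sigma)))
        if lo <= size <= hi:
            return size
    raise RuntimeError("loop size sampling failed to hit the truncation bounds")


def simulate_loops(
    config: SimulationConfig,
    annotation: CompartmentAnnotation,
    rng: np.random.Generator | None = None,
) -> dict[str, list[Loop]]:
    """Uniformly placed loops with truncated log-normal spans per category."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    chroms = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in chroms], dtype=np.float64)
    probs = lengths / lengths.sum()
    out: dict[str, list[Loop]] = {}
    aw = config.anchor_width
    for category, n_loops in config.loops_per_category.items():
        loops = []
        for i in range(n_loops):
            for attempt in range(100):
                chrom = chroms[rng.choice(len(chroms), p=probs)]
                size = _sample_loop_size(config, rng)
                limit = config.chromosomes[chrom] - size
                if limit > 0:
                    break
            else:
                raise RuntimeError(
                    f"could not place a loop of any sampled size on {chrom}"
                )
            start = int(rng.integers(0, limit))
            a1 = GenomicInterval(chrom, start, start + aw)
            a2 = GenomicInterval(chrom, start + size - aw, start + size)
            loops.append(Loop(a1, a2, category=category, name=f"{category}_{i}"))
        out[category] = loops
    return out


# ---------------------------------------------------------------------------
# Mark tracks
# ---------------------------------------------------------------------------


def _window_compartments(
    config: SimulationConfig, annotation: CompartmentAnnotation
) -> dict[str, np.ndarray]:
    """Per-chromosome array of "A"/"B"/"" for each whole window."""
    from .labeling import map_subcompartment

    w = config.window_width
    out = {}
    for chrom, length in config.chromosomes.items():
        n = length // w
        comp = np.array([""] * n, dtype=object)
        for win in annotation.windows:
            if win.interval.chrom != chrom:
                continue
            i0 = win.interval.start // w
            i1 = min(win.interval.end, n * w) // w
            comp[i0:i1] = map_subcompartment(win.subcompartment)
        out[chrom] = comp
    return out


def _simulate_peak_mark(
    mark: MarkConfig,
    config: SimulationConfig,
    window_comp: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> list[Peak]:
    w = config.window_width
    peaks = []
    for chrom, comps in window_comp.items():
        for i, comp in enumerate(comps):
            rate = mark.peak_density * w
            if comp == mark.enriched_in:
                rate *= 1.0 + mark.delta
            n = rng.poisson(rate)
            if n == 0:
                continue
            starts = np.sort(rng.integers(i * w, (i + 1) * w, size=n))
            widths = rng.integers(mark.peak_width[0], mark.peak_width[1], size=n)
            signals = np.exp(rng.normal(0.0, 0.5, size=n)) * mark.signal_scale
            for s, width, sig in zip(starts, widths, signals):
                end = min(int(s) + int(width), (i + 1) * w)
                if end > s:
                    peaks.append(Peak(GenomicInterval(chrom, int(s), end), float(sig)))
    # enforce the non-overlap-free container contract? peaks may overlap: fine
    return peaks


def _simulate_coverage_mark(
    mark: MarkConfig,
    config: SimulationConfig,
    window_comp: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> CoverageTrack:
    w = config.window_width
    steps = {}
    for chrom, comps in window_comp.items():
        length = len(comps) * w
        bin_ = mark.coverage_bin
        n_bins = length // bin_
        starts = np.arange(n_bins, dtype=np.int64) * bin_
        ends = starts + bin_
        win_of_bin = starts // w
        shift = np.array(
            [
                mark.delta * mark.coverage_sd
                if comps[wi] == mark.enriched_in
                else 0.0
                for wi in win_of_bin
            ]
        )
        values = rng.normal(mark.coverage_mean + shift, mark.coverage_sd)
        values = np.clip(values, 0.0, None)
        steps[chrom] = (starts, ends, values)
    return CoverageTrack(steps)


def _simulate_segmentation_mark(
    mark: MarkConfig,
    config: SimulationConfig,
    window_comp: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> Segmentation:
    """3-state segmentation: active odds tilted up by delta in A territory,
    repressed/heterochromatin odds tilted up in B; uniform when delta = 0."""
    w = config.window_width
    seg_len = mark.segment_length
    states = np.array(["active", "repressed", "heterochromatin"])
    segments = []
    for chrom, comps in window_comp.items():
        length = len(comps) * w
        for start in range(0, length - seg_len + 1, seg_len):
            comp = comps[start // w]
            weights = np.ones(3)
            if comp == "A":
                weights[0] *= 1.0 + mark.delta
            elif comp == "B":
                weights[1] *= 1.0 + mark.delta / 2.0
                weights[2] *= 1.0 + mark.delta / 2.0
            p = weights / weights.sum()
            state = states[rng.choice(3, p=p)]
            segments.append(
                SegmentationSegment(
                    GenomicInterval(chrom, start, start + seg_len), str(state)
                )
            )
    return Segmentation(segments)


def simulate_mark_tracks(
    config: SimulationConfig,
    annotation: CompartmentAnnotation,
    rng: np.random.Generator | None = None,
) -> dict[str, MarkTracks]:
    """In-memory tracks for every configured mark."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    window_comp = _window_compartments(config, annotation)
    catalog: dict[str, MarkTracks] = {}
    for mark in config.marks:
        if mark.kind == "peak":
            catalog[mark.name] = MarkTracks(
                peaks=_simulate_peak_mark(mark, config, window_comp, rng)
            )
        elif mark.kind == "coverage":
            catalog[mark.name] = MarkTracks(
                coverage=_simulate_coverage_mark(mark, config, window_comp, rng)
            )
        else:
            catalog[mark.name] = MarkTracks(
                segmentation=_simulate_segmentation_mark(
                    mark, config, window_comp, rng
                ),
                state_map=DEFAULT_STATE_MAP,
            )
    return catalog


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """In-memory dataset plus (optionally) the files it was written to."""

    config: SimulationConfig
    annotation: CompartmentAnnotation
    loops: dict[str, list[Loop]]
    catalog: dict[str, MarkTracks]
    files: dict[str, str] = field(default_factory=dict)

    @property
    def informative_marks(self) -> list[str]:
        return [m.name for m in self.config.marks if m.informative]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate annotation, loops and mark tracks in memory, deterministically."""
    annotation = simulate_compartments(
        config, np.random.default_rng(config.seed)
    )
    loops = simulate_loops(config, annotation, np.random.default_rng(config.seed + 1))
    catalog = simulate_mark_tracks(
        config, annotation, np.random.default_rng(config.seed + 2)
    )
    return SyntheticDataset(config, annotation, loops, catalog)


def generate_dataset(config: SimulationConfig, outdir) -> SyntheticDataset:
    """Generate and write a full dataset plus a ground-truth manifest.

    Emits chrom.sizes, the BED4 compartment annotation, one BEDPE per loop
    category, one narrowPeak / bedGraph / BED4 file per mark, and
    ``manifest.json`` listing every file, the informative marks and their
    effect sizes.  Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    files: dict[str, str] = {}

    def _emit(key: str, name: str, writer, obj):
        path = outdir / name
        writer(obj, path)
        files[key] = name

    _emit("chrom_sizes", "genome.chrom.sizes", gio.write_chrom_sizes, config.chrom_sizes)
    _emit(
        "compartments", "compartments.bed", gio.write_compartment_annotation,
        ds.annotation,
    )
    for category, loops in ds.loops.items():
        _emit(f"loops:{category}", f"loops_{category}.bedpe", gio.write_loops, loops)
    for mark in config.marks:
        tracks = ds.catalog[mark.name]
        if mark.kind == "peak":
            _emit(
                f"mark:{mark.name}", f"{mark.name}.narrowPeak", gio.write_peaks,
                tracks.peaks,
            )
        elif mark.kind == "coverage":
            _emit(
                f"mark:{mark.name}", f"{mark.name}.bedGraph", gio.write_coverage,
                tracks.coverage,
            )
        else:
            _emit(
                f"mark:{mark.name}", f"{mark.name}.segmentation.bed",
                gio.write_segmentation, tracks.segmentation,
            )
    manifest = {
        "seed": config.seed,
        "files": files,
        "marks": [
            {
                "name": m.name,
                "kind": m.kind,
                "delta": m.delta,
                "enriched_in": m.enriched_in,
                "informative": m.informative,
            }
            for m in config.marks
        ],
        "informative_marks": ds.informative_marks,
        "loop_categories": list(config.loops_per_category),
        "config": _config_to_jsonable(config),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["manifest"] = "manifest.json"
    ds.files = files
    return ds


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["loop_bounds"] = list(config.loop_bounds)
    for m in d["marks"]:
        m["peak_width"] = list(m["peak_width"])
    return d
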