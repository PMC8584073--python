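"""Label regions A/B and build the feature matrices.

Reads the dataset written by 01_simulate.py back through the I/O layer (so
this stage exercises the on-disk formats, not in-memory shortcuts), labels
both 100 kb windows and loops against the compartment annotation, applies
the exclusion rule (loops touching both compartments are dropped), and
writes one feature matrix per region mode to results/.
"""

import json
from pathlib import Path

from compartmarks.genomic_io import (
    read_chrom_sizes,
    read_compartment_annotation,
    read_loops,
)
from compartmarks.labeling import write_label_summary, write_labeled_regions
from compartmarks.pipeline import (
    catalog_from_manifest,
    features_stage,
    label_regions,
)

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "results" / "dataset"
OUT = ROOT / "results"


def main():
    catalog, manifest = catalog_from_manifest(DATASET)
    annotation = read_compartment_annotation(DATASET / manifest["files"]["compartments"])
    sizes = read_chrom_sizes(DATASET / manifest["files"]["chrom_sizes"])
    loops = []
    for cat in manifest["loop_categories"]:
        loops.extend(read_loops(DATASET / manifest["files"][f"loops:{cat}"], cat))

    for mode, kwargs in (
        ("windows", {"chrom_sizes": sizes}),
        ("loops", {"loops": loops}),
    ):
        regions, summary = label_regions(annotation, mode, **kwargs)
        matrix = features_stage(regions, catalog)
        matrix.to_tsv(OUT / f"features_{mode}.tsv")
        write_labeled_regions(regions, OUT / f"regions_{mode}.tsv")
        write_label_summary(summary, OUT / f"labeling_{mode}.json")
        print(
            f"{mode}: kept {summary['kept']}/{summary['total']} regions "
            f"({summary['kept_fraction']:.1%}), "
            f"A share {summary['a_fraction_of_kept']:.1%}; "
            f"matrix {matrix.n_regions} x {matrix.n_features}"
        )


if __name__ == "__main__":
    main()
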