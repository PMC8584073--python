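"""Benchmark compartment predictability with the seven-classifier battery.

Runs GNB, KNN, LDA, ADB, SVM, MLP and RFO under 10-fold stratified
cross-validation on the window and loop feature matrices from
02_features.py, and writes one benchmark table per region mode
(R, P, F-Score, ACC, AUC, SD of fold AUCs, RMSE, plus the Mean row).
"""

from pathlib import Path

from compartmarks.features import FeatureMatrix
from compartmarks.harness import evaluate_battery

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SEED = 1


def main():
    for mode in ("windows", "loops"):
        matrix = FeatureMatrix.from_tsv(OUT / f"features_{mode}.tsv")
        report = evaluate_battery(matrix, k=10, seed=SEED)
        report.to_tsv(OUT / f"classifier_report_{mode}.tsv")
        print(f"== {mode} ({matrix.n_regions} regions x {matrix.n_features} features)")
        print(report.table.round(4).to_string())
        print()


if __name__ == "__main__":
    main()
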