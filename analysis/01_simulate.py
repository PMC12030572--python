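"""Simulate the leaf-scan study: 4 treatment groups x 4 stress durations x
3 leaves, ~30 dot-matrix positions per leaf on a 200-3400 cm^-1 axis.

Writes the full dataset (large) under scratch/data/ and the acquisition
summary under results/.
"""

from pathlib import Path

from leafspot import write_leaf_grids, write_spectra_table, validate_dataset
from leafspot.synthetic import SyntheticConfig, generate_dataset

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    spectra, grids, truth = generate_dataset(SyntheticConfig(seed=SEED))
    write_spectra_table(spectra, DATA / "spectra.csv", DATA / "meta.csv")
    write_leaf_grids(grids, DATA / "grids.json")
    truth.positions.to_csv(DATA / "ground_truth.csv", index=False)

    report = validate_dataset(spectra, grids)
    report.tabulation.to_csv(RESULTS / "01_dataset_counts.csv")
    print(f"simulated {spectra.n_spectra} spectra over {len(grids)} leaves (seed {SEED})")
    print(report.tabulation)
    frac = truth.positions.groupby("duration_h")["is_anomalous"].mean()
    print("\nanomalous-position fraction by stress duration:")
    print(frac.round(3).to_string())
    print("\n-> anomalies are most frequent at 24 h and nearly gone by 168 h,")
    print("   the pattern the downstream screening is meant to recover.")


if __name__ == "__main__":
    main()
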