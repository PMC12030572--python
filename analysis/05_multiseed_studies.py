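"""Multi-seed robustness studies: instrument repeatability of the
acquisition model, recovery of a known baseline, margin enrichment
consistency, and the sign-consistency of the cleansing benefit.

Writes results/05_studies.json. (The acceptance script runs larger
versions of the same studies.)
"""

import json
from pathlib import Path

from leafspot.studies import (
    baseline_recovery_study,
    cleansing_effect_study,
    enrichment_study,
    repeatability_study,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    out = {}

    stab = repeatability_study(n_seeds=50, base_seed=0)
    out["replicate_stability"] = {
        "pass_rate": stab["pass_rate"],
        "floor": stab["floor"],
        "minima_means": {int(k): round(v, 5) for k, v in stab["minima_means"].items()},
    }
    print(f"replicate streams >= {stab['floor']} floor in {stab['pass_rate']:.0%} of 50 seeds")
    print("three-position minima table (first seed):")
    print(stab["minima_table"].round(5))

    base = baseline_recovery_study(seed=0)
    out["baseline_recovery"] = {k: base[k] for k in ("rms_ratio", "n_peaks_recovered", "n_peaks")}
    print(f"\nbaseline recovery: error RMS {base['rms_ratio']:.1%} of baseline RMS; "
          f"{base['n_peaks_recovered']}/{base['n_peaks']} peak centers recovered")

    enrich = enrichment_study(range(10))
    out["margin_enrichment"] = {
        "consistency": float(enrich["margin_gt_interior"].mean()),
        "margin_mean": float(enrich["margin_enrichment"].mean()),
        "interior_mean": float(enrich["interior_enrichment"].mean()),
    }
    print(f"\nmargin > interior enrichment in {enrich['margin_gt_interior'].sum()}/10 seeds "
          f"(margin {enrich['margin_enrichment'].mean():.2f}x, "
          f"interior {enrich['interior_enrichment'].mean():.2f}x)")

    effect = cleansing_effect_study(range(5))
    out["cleansing_effect"] = {
        "positive_gain_seeds": int((effect["mean_dF1_test"] > 0).sum()),
        "n_seeds": len(effect),
        "mean_test_f1_gain": float(effect["mean_dF1_test"].mean()),
        "mean_lv_change": float(effect["mean_dLVs"].mean()),
    }
    print(f"\ncleansing raises mean held-out macro-F1 in "
          f"{(effect['mean_dF1_test'] > 0).sum()}/5 seeds "
          f"(mean gain {effect['mean_dF1_test'].mean():+.2f} points, "
          f"mean LV change {effect['mean_dLVs'].mean():+.2f})")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "05_studies.json").write_text(json.dumps(out, indent=1))
    print("\nwrote results/05_studies.json")


if __name__ == "__main__":
    main()
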