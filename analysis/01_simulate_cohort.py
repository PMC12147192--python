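"""Simulate the synthetic hemiparetic cohort used by the downstream analyses.

Generates 12 treadmill-walking participants with the prescribed deficits —
paretic foot placement 2 cm wider and paretic-step trailing-limb work
reduced by 30% — and writes the trial bundles plus the generator's exact
ground truth under ``data/synthetic_cohort/``.
"""

from pathlib import Path

from comtransfer.synthetic_data import AsymmetrySpec, SyntheticConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "data" / "synthetic_cohort"
SEED = 20240915


def main() -> None:
    spec = AsymmetrySpec(fp_offset_p=0.02, work_scale_p=0.7)
    results = simulate_cohort(12, SyntheticConfig(), spec, seed=SEED, out_dir=OUT)
    n_steps = sum(len(truth.steps) for _, truth in results)
    print(f"wrote {len(results)} trial bundles ({n_steps} scheduled steps) to {OUT}")
    print("ground truth table: ", OUT / "ground_truth.tsv")


if __name__ == "__main__":
    main()
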