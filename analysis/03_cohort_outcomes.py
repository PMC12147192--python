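"""Summarize how the transfer asymmetry evolves across gait events.

Aggregates the participant summaries into cohort-level outcomes: the
asymmetry of the (projected) transfer magnitude at initial contact,
contralateral foot off and completion; the relative contribution of each
phase to the final asymmetry; step-to-step control correlations; and
transfer variability. Writes ``results/cohort_summary.json``.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def ms(x):
    return [float(np.mean(x)), float(np.std(x, ddof=1))]


def main() -> None:
    df = pd.read_csv(OUT / "participant_summary.tsv", sep="\t")
    summary = {
        "n_participants": int(len(df)),
        "asym_ic_m": ms(df.asym_ic),
        "asym_cfo_m": ms(df.asym_cfo),
        "asym_final_m": ms(df.asym_final),
        "contrib_ic_pct": ms(df.contrib_ic),
        "contrib_ds_pct": ms(df.contrib_ds),
        "contrib_ess_pct": ms(df.contrib_ess),
        "mae_p_mm": ms(df.mae_p * 1e3),
        "mae_np_mm": ms(df.mae_np * 1e3),
        "r_p": ms(df.r_p),
        "r_np": ms(df.r_np),
        "sd_ic_p_mm": ms(df.sd_ic_p * 1e3),
        "sd_ic_np_mm": ms(df.sd_ic_np * 1e3),
        "sd_final_p_mm": ms(df.sd_final_p * 1e3),
        "sd_final_np_mm": ms(df.sd_final_np * 1e3),
        "ess_duration_p_ms": ms(df.ess_duration_mean_p * 1e3),
        "ess_duration_np_ms": ms(df.ess_duration_mean_np * 1e3),
    }
    (OUT / "cohort_summary.json").write_text(json.dumps(summary, indent=1))

    a_ic, a_cfo, a_fin = (summary["asym_ic_m"][0], summary["asym_cfo_m"][0],
                          summary["asym_final_m"][0])
    print(f"asymmetry (non-paretic minus paretic, mm): "
          f"IC {1e3 * a_ic:+.1f} -> CFO {1e3 * a_cfo:+.1f} -> final {1e3 * a_fin:+.1f}")
    print(f"phase contributions: IC {summary['contrib_ic_pct'][0]:.1f}%, "
          f"double support {summary['contrib_ds_pct'][0]:.1f}%, "
          f"early single support {summary['contrib_ess_pct'][0]:.1f}%")
    print(f"CFO prediction MAE: paretic {summary['mae_p_mm'][0]:.2f} mm, "
          f"non-paretic {summary['mae_np_mm'][0]:.2f} mm")
    print("full summary written to", OUT / "cohort_summary.json")


if __name__ == "__main__":
    main()
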