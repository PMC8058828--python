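#!/usr/bin/env python
"""One-way (deterministic) sensitivity analysis on the labeling effect.

Re-runs the full pipeline with identical random streams at the
meta-analytic bounds of the labeling effect (4.4% and 8.8% sugar reduction)
around the 6.6% base case. Because the dose-response is linear and the
streams are shared, the base-case outcome is bracketed almost exactly
symmetrically by the bounds. Writes results/dsa.csv.
"""

from pathlib import Path

import pandas as pd

from fopfl_caries import load_config
from fopfl_caries.sensitivity import run_dsa

OUT = Path(__file__).resolve().parents[1] / "results"
EFFECTS = [0.044, 0.066, 0.088]


def main() -> None:
    cfg = load_config(OUT / "synthetic_config.yaml")
    rows = []
    for effect, total in run_dsa(cfg, EFFECTS):
        rows.append({
            "effect_fraction": effect,
            "lesions_prevented": round(total.lesions_prevented),
            "costs_avoided_m_eur": round(total.costs_avoided_undiscounted / 1e6, 2),
            "dalys_averted": round(total.dalys_averted_undiscounted, 2),
            "productivity_avoided_m_eur": round(
                total.productivity_avoided_undiscounted / 1e6, 2),
        })
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "dsa.csv", index=False)
    print(frame.to_string(index=False))

    lo, mid, hi = (r["lesions_prevented"] for r in rows)
    print(f"\nBase case {mid:,} lesions prevented lies between the bounds "
          f"{lo:,} and {hi:,}; midpoint of the bounds is {(lo + hi) / 2:,.0f} "
          f"({100 * abs(mid - (lo + hi) / 2) / mid:.2f}% from the base case — "
          f"near-linear response).")


if __name__ == "__main__":
    main()
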