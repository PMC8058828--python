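#!/usr/bin/env python
"""Audit the published results table for internal arithmetic consistency.

Every published treatment-cost figure should equal its published lesion
count x EUR 74.10 (the stated unit cost) to the printed 2 decimals. The
audit reproduces 10 of the 12 stratum rows, the grand total, and both
one-way-sensitivity bounds; the two female rows that violate the identity
(women 51-64 and 65-80) are flagged as suspect. Writes
results/identity_audit.csv.
"""

from pathlib import Path

from fopfl_caries import verify_paper_identities
from fopfl_caries import reference_values as ref

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = verify_paper_identities()
    frame = report.to_frame()
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "identity_audit.csv", index=False)
    print(frame.to_string(index=False))
    print(f"\n{report.n_matching}/{len(report.rows)} rows satisfy "
          f"cost = lesions x {ref.UNIT_COST}; "
          f"suspect rows: {', '.join(report.mismatched_labels)}.")

    male_sum = sum(lesions for label, lesions, _ in ref.TABLE_ROWS
                   if label.startswith("men"))
    print(f"Published male stratum lesion counts sum to {male_sum:,} vs the "
          f"published male total {ref.MALE_TOTAL_LESIONS:,} "
          f"(difference {male_sum - ref.MALE_TOTAL_LESIONS:+d}, integer rounding).")

    per_lesion = ref.TOTAL_DALYS / ref.TOTAL_LESIONS
    eur_per_daly = ref.TOTAL_PRODUCTIVITY_MILLIONS * 1e6 / ref.TOTAL_DALYS
    print(f"Implied per-lesion DALY: {per_lesion:.4e}; implied EUR/DALY: "
          f"{eur_per_daly:,.0f}. Cross-checks: "
          f"{ref.DSA[0.044]['lesions']:,} lesions -> "
          f"{ref.DSA[0.044]['lesions'] * per_lesion:.2f} DALYs "
          f"(published {ref.DSA[0.044]['dalys']}); "
          f"{ref.DSA[0.088]['dalys']} DALYs -> "
          f"EUR {ref.DSA[0.088]['dalys'] * eur_per_daly / 1e6:.2f}M "
          f"(published {ref.DSA[0.088]['productivity_millions']}).")


if __name__ == "__main__":
    main()
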