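"""Published headline estimates for the German 2017 base case.

These constants are the externally reported results of the original German
front-of-package labeling evaluation that this package re-implements. They
are NOT model outputs and are never fed into the simulation; they exist so
the reporting layer can audit the arithmetic identities the published table
must satisfy (cost = lesions x unit cost; DALY and productivity ratios) and
flag internally inconsistent rows.
"""

from __future__ import annotations

UNIT_COST = 74.10  # EUR per 1-surface restoration, base case

#: (stratum label, lesions prevented, treatment costs avoided in million EUR)
#: over the 10-year horizon, 2017 German population aged 15-80.
TABLE_ROWS = (
    ("men 15-18", 89_638, 6.64),
    ("men 19-24", 152_929, 11.33),
    ("men 25-34", 264_635, 19.61),
    ("men 35-50", 376_715, 27.91),
    ("men 51-64", 269_952, 20.00),
    ("men 65-80", 165_584, 12.27),
    ("women 15-18", 60_061, 4.45),
    ("women 19-24", 109_339, 8.10),
    ("women 25-34", 195_755, 14.51),
    ("women 35-50", 279_713, 20.73),
    ("women 51-64", 191_175, 16.95),
    ("women 65-80", 132_554, 13.16),
)

TOTAL_LESIONS = 2_370_715
TOTAL_COST_MILLIONS = 175.67
MALE_TOTAL_LESIONS = 1_319_452
FEMALE_TOTAL_LESIONS = 1_051_263

TOTAL_DALYS = 677.62
TOTAL_PRODUCTIVITY_MILLIONS = 27.33

#: One-way sensitivity bounds on the labeling effect (fractional sugar
#: reduction): reported totals at 4.4% and 8.8% around the 6.6% base case.
DSA = {
    0.044: {"lesions": 1_592_392, "cost_millions": 118.00,
            "dalys": 455.15, "productivity_millions": 18.36},
    0.066: {"lesions": TOTAL_LESIONS, "cost_millions": TOTAL_COST_MILLIONS,
            "dalys": TOTAL_DALYS, "productivity_millions": TOTAL_PRODUCTIVITY_MILLIONS},
    0.088: {"lesions": 3_143_636, "cost_millions": 232.94,
            "dalys": 898.55, "productivity_millions": 36.24},
}

#: Alternate-unit-cost scenario totals (million EUR).
COPAYMENT_TOTAL_MILLIONS = 280.01
RESTORATION_FAILURE_TOTAL_MILLIONS = 352.60

#: Reported tentative labeling implementation cost range (EUR).
IMPLEMENTATION_COST_RANGE = (5.29e6, 9.56e6)
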