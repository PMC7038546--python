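"""Printed operating characteristics used as golden expectations.

Each row: (algorithm, stratum, cohort, sensitivity, specificity, ppv, npv,
kappa) as printed (percent, 1 decimal; kappa 2 decimals).  ppv None means
the published table marks it undefined.  The confusion matrices themselves
live in :mod:`diabtype.datasets`; these are the independently printed
metric values they must reproduce.
"""

# cohort: "derivation" or "validation"
PRINTED_METRICS = [
    ("A", "all", "derivation", 83.3, 99.0, 34.0, 99.9, 0.48),
    ("B", "all", "derivation", 71.7, 99.7, 57.3, 99.8, 0.63),
    ("C", "all", "derivation", 96.7, 93.9, 8.6, 100.0, 0.15),
    ("D", "all", "derivation", 53.3, 99.9, 78.0, 99.7, 0.63),
    ("A_and_C", "all", "derivation", 81.7, 99.5, 48.5, 99.9, 0.61),
    ("A_and_D", "all", "derivation", 46.7, 100.0, 84.8, 99.7, 0.60),
    ("B_and_C", "all", "derivation", 70.0, 99.8, 68.9, 99.8, 0.69),
    ("B_and_D", "all", "derivation", 41.7, 100.0, 86.2, 99.7, 0.56),
    ("A_or_C", "all", "derivation", 98.3, 93.5, 8.2, 100.0, 0.14),
    ("A_or_D", "all", "derivation", 90.0, 99.0, 34.8, 99.9, 0.50),
    ("B_or_C", "all", "derivation", 98.3, 93.8, 8.6, 100.0, 0.15),
    ("B_or_D", "all", "derivation", 83.3, 99.6, 57.5, 99.9, 0.68),
    ("A", "<20", "derivation", 100.0, 74.3, 71.9, 100.0, 0.70),
    ("B", "<20", "derivation", 91.3, 85.7, 80.8, 93.8, 0.75),
    ("C", "<20", "derivation", 100.0, 62.9, 63.9, 100.0, 0.57),
    ("D", "<20", "derivation", 69.6, 91.4, 84.2, 82.1, 0.63),
    ("A_and_C", "<20", "derivation", 100.0, 77.1, 74.2, 100.0, 0.73),
    ("A_and_D", "<20", "derivation", 69.6, 94.3, 88.9, 82.5, 0.66),
    ("B_and_C", "<20", "derivation", 91.3, 85.7, 80.8, 93.8, 0.75),
    ("B_and_D", "<20", "derivation", 65.2, 94.3, 88.2, 80.5, 0.62),
    ("A_or_C", "<20", "derivation", 100.0, 60.0, 62.2, 100.0, 0.54),
    ("A_or_D", "<20", "derivation", 100.0, 71.4, 69.7, 100.0, 0.66),
    ("B_or_C", "<20", "derivation", 100.0, 62.9, 63.9, 100.0, 0.57),
    ("B_or_D", "<20", "derivation", 95.7, 82.9, 78.6, 96.7, 0.76),
    ("A", "20-39", "derivation", 80.8, 93.0, 28.4, 99.3, 0.39),
    ("B", "20-39", "derivation", 73.1, 97.9, 54.3, 99.1, 0.61),
    ("C", "20-39", "derivation", 96.2, 89.4, 23.8, 99.9, 0.35),
    ("D", "20-39", "derivation", 50.0, 99.6, 81.3, 98.3, 0.61),
    ("A_and_C", "20-39", "derivation", 76.9, 96.9, 46.5, 99.2, 0.56),
    ("A_and_D", "20-39", "derivation", 38.5, 99.9, 90.9, 97.9, 0.53),
    ("B_and_C", "20-39", "derivation", 69.2, 98.9, 69.2, 98.9, 0.68),
    ("B_and_D", "20-39", "derivation", 38.5, 99.9, 90.9, 97.9, 0.53),
    ("A_or_C", "20-39", "derivation", 100.0, 85.4, 19.1, 100.0, 0.28),
    ("A_or_D", "20-39", "derivation", 92.3, 92.7, 30.4, 99.7, 0.43),
    ("B_or_C", "20-39", "derivation", 100.0, 88.3, 22.8, 100.0, 0.34),
    ("B_or_D", "20-39", "derivation", 84.6, 97.6, 55.0, 99.5, 0.65),
    ("A", ">=40", "derivation", 54.5, 99.6, 14.6, 99.9, 0.23),
    ("B", ">=40", "derivation", 27.3, 99.9, 21.4, 99.9, 0.24),
    ("C", ">=40", "derivation", 90.9, 94.4, 1.9, 100.0, 0.03),
    ("D", ">=40", "derivation", 27.3, 100.0, 50.0, 99.9, 0.35),
    ("A_and_C", ">=40", "derivation", 54.5, 99.8, 22.2, 99.9, 0.31),
    ("A_and_D", ">=40", "derivation", 18.2, 100.0, 50.0, 99.9, 0.27),
    ("B_and_C", ">=40", "derivation", 27.3, 99.9, 33.3, 99.9, 0.30),
    ("B_and_D", ">=40", "derivation", 0.0, 100.0, None, 99.9, 0.00),
    ("A_or_C", ">=40", "derivation", 90.9, 94.3, 1.8, 100.0, 0.03),
    ("A_or_D", ">=40", "derivation", 63.6, 99.6, 16.3, 100.0, 0.26),
    ("B_or_C", ">=40", "derivation", 90.9, 94.4, 1.9, 100.0, 0.03),
    ("B_or_D", ">=40", "derivation", 54.5, 99.9, 31.6, 99.9, 0.40),
    ("high_sensitivity_t1", "all", "validation", 95.3, 94.5, 12.8, 100.0, 0.21),
    ("high_sensitivity_t1", "<20", "validation", 100.0, 77.8, 70.0, 100.0, 0.71),
    ("high_sensitivity_t1", "20-39", "validation", 90.5, 88.0, 31.7, 99.3, 0.42),
    ("high_sensitivity_t1", ">=40", "validation", 100.0, 95.0, 3.3, 100.0, 0.06),
    ("high_ppv_t1", "all", "validation", 37.2, 100.0, 100.0, 99.5, 0.54),
    ("high_ppv_t1", "<20", "validation", 57.1, 100.0, 100.0, 81.8, 0.64),
    ("high_ppv_t1", "20-39", "validation", 28.6, 100.0, 100.0, 95.8, 0.43),
    ("high_ppv_t1", ">=40", "validation", 25.0, 100.0, 100.0, 99.9, 0.40),
    ("optimized", "all", "validation", 65.1, 99.8, 75.7, 99.7, 0.70),
    ("optimized", "<20", "validation", 85.7, 100.0, 100.0, 93.1, 0.89),
    ("optimized", "20-39", "validation", 57.1, 97.9, 63.2, 97.4, 0.58),
    ("optimized", ">=40", "validation", 50.0, 100.0, 66.7, 99.9, 0.57),
]

#: (x, n) -> printed exact 95% CI in percent
PRINTED_EXACT_CIS = {
    (41, 43): (84.2, 99.4),   # high-sensitivity rule, validation sensitivity
    (16, 16): (79.4, 100.0),  # high-PPV rule, validation PPV
    (28, 37): (58.8, 88.2),   # optimized rule, validation PPV
    (28, 43): (49.1, 79.0),   # optimized rule, validation sensitivity
}

#: headline operating points, validation cohort, all ages: (sens %, ppv %)
HEADLINE_OPERATING_POINTS = {
    "high_sensitivity_t1": (95.3, 12.8),
    "high_ppv_t1": (37.2, 100.0),
    "optimized": (65.1, 75.7),
}
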