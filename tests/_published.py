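"""Published reference values used by multiple tests.

``PER_100K_FRACTURES`` / ``PER_100K_COSTS`` are the per-100,000 display
rows; ``TOTALS`` the printed eight-country aggregates.  The printed
aggregates were computed from unrounded country values at the source, so
they may differ from the sum of printed country cells by up to 0.5 per
country (see the rounding-propagation tolerances in the acceptance tests).
"""

YEARS = (2020, 2025, 2030, 2035, 2040)
COUNTRIES = ("BE", "FR", "DE", "IE", "PL", "SK", "CH", "GB")

PER_100K_FRACTURES = {
    "BE": (5352, 5247, 5244, 5354, 5517),
    "FR": (5266, 5125, 5237, 5440, 5606),
    "DE": (5382, 5365, 5240, 5131, 5270),
    "IE": (5540, 5526, 5652, 5728, 5846),
    "PL": (3048, 2892, 2924, 3192, 3450),
    "SK": (4648, 4526, 4681, 4893, 5020),
    "CH": (7656, 7813, 7903, 7851, 7918),
    "GB": (6068, 6199, 6291, 6283, 6290),
}

PER_100K_COSTS = {  # € millions per 100,000 women 70+
    "BE": (37.7, 37.2, 37.2, 37.7, 38.8),
    "FR": (80.4, 78.3, 80.0, 82.9, 85.4),
    "DE": (58.7, 58.6, 57.2, 56.2, 57.5),
    "IE": (49.7, 49.1, 50.0, 50.6, 51.3),
    "PL": (8.4, 8.0, 8.0, 8.7, 9.4),
    "SK": (13.2, 13.0, 13.2, 13.7, 14.0),
    "CH": (111.9, 113.8, 115.0, 114.3, 115.3),
    "GB": (43.0, 43.9, 44.5, 44.5, 44.5),
}

TOTALS = {
    "population": (23468741, 25665693, 28082169, 30719695, 32816258),
    "fractures": (1238320, 1338742, 1465247, 1625008, 1784301),
    "costs": (12790, 13782, 15047, 16701, 18376),
}
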