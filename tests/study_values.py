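"""Reference values from the published Zhengzhou metropolitan-area network.

These printed tables serve as *inputs* to desk-scale golden tests: corridor
counts and node counts per subnetwork with their reported indices, the 58
retained corridor lengths (km) by tier, a sample of reported gravity values,
and the land-transfer flows into paddy field (km^2) between the first and
last analysis dates.
"""

# (L corridors, V nodes, alpha, beta, gamma, cost_ratio) per subnetwork
SUBNETWORK_ROWS = {
    "level1_strategic": (10, 10, 0.07, 1.00, 0.42, 1.00),
    "level23_natural": (48, 27, 0.45, 1.78, 0.64, 0.99),
    "level23_artificial": (48, 33, 0.26, 1.45, 0.52, 0.99),
}

# corridor lengths (km), ids 1-58: 1-10 level 1, 11-29 level 2, 30-58 level 3
CORRIDOR_LENGTHS_KM = {
    1: 455.16, 2: 436.14, 3: 471.36, 4: 18.12, 5: 516.24,
    6: 22.38, 7: 88.92, 8: 29.22, 9: 13.86, 10: 333.30,
    11: 455.11, 12: 42.60, 13: 78.30, 14: 81.48, 15: 61.98,
    16: 26.64, 17: 38.22, 18: 51.06, 19: 119.64, 20: 17.10,
    21: 43.92, 22: 113.34, 23: 38.04, 24: 51.24, 25: 23.46,
    26: 84.30, 27: 10.66, 28: 10.08, 29: 55.62,
    30: 43.47, 31: 57.28, 32: 89.31, 33: 96.03, 34: 41.49,
    35: 67.94, 36: 65.82, 37: 154.74, 38: 99.24, 39: 172.74,
    40: 38.46, 41: 81.90, 42: 107.94, 43: 96.54, 44: 90.84,
    45: 48.90, 46: 44.28, 47: 75.96, 48: 31.68, 49: 61.56,
    50: 32.46, 51: 73.86, 52: 151.98, 53: 184.50, 54: 107.76,
    55: 178.98, 56: 529.02, 57: 88.56, 58: 246.24,
}

LEVEL1_IDS = range(1, 11)
LEVEL23_IDS = range(11, 59)

# reported gravity values spanning the three tiers and an exclusion
GRAVITY_SAMPLES = {265.43: 1, 61.18: 2, 5.99: 3, 0.87: None}

# transfers into paddy field (km^2) from each other class, and the printed total
PADDY_INFLOWS_KM2 = [2442.75, 58.03, 53.02, 433.34, 4.5]
PADDY_INFLOW_TOTAL_KM2 = 2991.64
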