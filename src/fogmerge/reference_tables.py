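"""Published reference values for the original 11-participant
freezing-of-gait cohort whose merging-threshold study this package
re-implements.

These per-participant tallies (episode counts per merging threshold,
window sensitivity/specificity, episode identification and delay, MTD
true/false-positive counts with precision, and the 2.5 s no-cue
protocol results) serve as arithmetic worked examples: the package's
``precision`` and ``aggregate_report`` operations must reproduce every
printed precision cell, column total, cohort mean and SD from them.
They are inputs for validation, not outputs of this package.

Layout: per-participant dicts keyed by participant id, then by merging
threshold ``mt`` in seconds where applicable. Window metrics are
``(sensitivity %, specificity %)``; episode metrics are
``(episodes identified %, mean identification delay s)``; MTD tables
are ``(TP, FP, precision %)``.
"""

from __future__ import annotations

PARTICIPANTS = (
    "P01", "P02", "P03", "P04", "P05", "P06", "P07", "P08", "P09", "P10", "P11",
)
FREEZERS = ("P01", "P02", "P03", "P06", "P07", "P08", "P09")
MERGING_THRESHOLDS = (0, 1, 2, 3)

# number of FOG episodes per participant for each merging threshold,
# plus the printed reduction column (mt=0 minus mt=3); None = non-freezer
EPISODE_COUNTS = {
    "P01": {0: 49, 1: 48, 2: 48, 3: 48},
    "P02": {0: 35, 1: 35, 2: 35, 3: 35},
    "P03": {0: 14, 1: 14, 2: 13, 3: 13},
    "P04": {0: 0, 1: 0, 2: 0, 3: 0},
    "P05": {0: 0, 1: 0, 2: 0, 3: 0},
    "P06": {0: 10, 1: 10, 2: 10, 3: 10},
    "P07": {0: 221, 1: 171, 2: 118, 3: 87},
    "P08": {0: 24, 1: 16, 2: 14, 3: 14},
    "P09": {0: 9, 1: 9, 2: 9, 3: 7},
    "P10": {0: 0, 1: 0, 2: 0, 3: 0},
    "P11": {0: 0, 1: 0, 2: 0, 3: 0},
}
EPISODE_REDUCTION_MT3 = {
    "P01": 1, "P02": 0, "P03": 1, "P04": None, "P05": None, "P06": 0,
    "P07": 134, "P08": 10, "P09": 2, "P10": None, "P11": None,
}

# window-based detection model: {pid: {mt: (sens %, spec %)}}
DETECTION_WINDOW = {
    "P01": {0: (88.1, 88.2), 1: (88.3, 88.3), 2: (89.5, 87.3), 3: (88.8, 87.4)},
    "P02": {0: (81.0, 90.2), 1: (81.4, 90.4), 2: (80.6, 90.1), 3: (81.0, 90.2)},
    "P03": {0: (70.6, 93.1), 1: (72.0, 93.0), 2: (74.8, 93.1), 3: (73.4, 93.0)},
    "P06": {0: (90.6, 90.7), 1: (93.8, 90.3), 2: (90.6, 90.6), 3: (93.8, 90.3)},
    "P07": {0: (64.9, 86.9), 1: (65.1, 86.4), 2: (63.2, 86.6), 3: (61.3, 86.8)},
    "P08": {0: (87.2, 87.2), 1: (87.2, 87.2), 2: (86.6, 87.3), 3: (87.0, 87.0)},
    "P09": {0: (94.4, 81.6), 1: (93.1, 80.8), 2: (98.6, 80.4), 3: (94.1, 80.4)},
}
DETECTION_WINDOW_MEAN = {0: (82.4, 88.3), 1: (83.0, 88.1), 2: (83.4, 87.9), 3: (82.8, 87.9)}
DETECTION_WINDOW_SD = {0: (10.1, 3.4), 1: (10.0, 3.6), 2: (10.8, 3.7), 3: (11.0, 3.7)}

# window-based prediction model
PREDICTION_WINDOW = {
    "P01": {0: (70.5, 81.7), 1: (68.8, 80.6), 2: (63.1, 82.0), 3: (67.3, 79.0)},
    "P02": {0: (55.3, 83.5), 1: (57.3, 83.1), 2: (58.2, 83.4), 3: (59.0, 82.3)},
    "P03": {0: (61.7, 93.4), 1: (60.2, 93.9), 2: (57.4, 94.3), 3: (63.1, 93.1)},
    "P06": {0: (87.1, 88.7), 1: (85.1, 89.1), 2: (82.2, 90.7), 3: (82.2, 90.3)},
    "P07": {0: (72.2, 67.5), 1: (68.6, 67.0), 2: (66.2, 66.7), 3: (65.6, 64.7)},
    "P08": {0: (77.6, 84.3), 1: (71.2, 84.5), 2: (69.4, 85.6), 3: (67.2, 82.8)},
    "P09": {0: (89.2, 75.6), 1: (87.8, 76.1), 2: (82.4, 76.7), 3: (78.6, 73.7)},
}
PREDICTION_WINDOW_MEAN = {0: (73.4, 82.1), 1: (71.3, 82.1), 2: (68.4, 82.8), 3: (69.0, 80.9)}
PREDICTION_WINDOW_SD = {0: (11.5, 7.9), 1: (10.7, 8.1), 2: (9.6, 8.4), 3: (7.7, 9.0)}

# episode-based detection model: {pid: {mt: (identified %, mean ID s)}}
DETECTION_EPISODE = {
    "P01": {0: (91.8, 0.02), 1: (91.7, 0.04), 2: (93.8, 0.01), 3: (93.8, 0.03)},
    "P02": {0: (85.7, 0.48), 1: (85.7, 0.49), 2: (85.7, 0.47), 3: (85.7, 0.47)},
    "P03": {0: (71.4, -0.34), 1: (71.4, -0.32), 2: (84.6, -0.13), 3: (76.9, -0.18)},
    "P06": {0: (100.0, -0.35), 1: (100.0, -0.41), 2: (100.0, -0.35), 3: (100.0, -0.41)},
    "P07": {0: (90.0, -0.72), 1: (90.1, -0.62), 2: (89.0, -0.21), 3: (88.5, -0.08)},
    "P08": {0: (100.0, -1.09), 1: (100.0, -0.73), 2: (100.0, -0.53), 3: (100.0, -0.56)},
    "P09": {0: (100.0, -0.83), 1: (100.0, -0.78), 2: (100.0, -1.10), 3: (100.0, -0.58)},
}
DETECTION_EPISODE_MEAN = {0: (91.3, -0.40), 1: (91.3, -0.33), 2: (93.3, -0.26), 3: (92.1, -0.19)}
DETECTION_EPISODE_SD = {0: (9.7, 0.50), 1: (9.7, 0.43), 2: (6.4, 0.45), 3: (8.2, 0.34)}

# episode-based prediction model
PREDICTION_EPISODE = {
    "P01": {0: (95.9, -0.02), 1: (95.8, 0.00), 2: (89.6, 0.04), 3: (91.7, -0.01)},
    "P02": {0: (94.3, 0.30), 1: (94.3, 0.27), 2: (97.1, 0.27), 3: (100.0, 0.30)},
    "P03": {0: (78.6, -0.33), 1: (64.3, -0.49), 2: (76.9, -0.26), 3: (92.3, -0.28)},
    "P06": {0: (100.0, -0.49), 1: (100.0, -0.49), 2: (100.0, -0.59), 3: (100.0, -0.61)},
    "P07": {0: (97.3, -1.17), 1: (97.1, -1.01), 2: (95.8, -0.83), 3: (94.3, -0.76)},
    "P08": {0: (91.7, -1.15), 1: (100.0, -0.81), 2: (100.0, -0.72), 3: (92.9, -1.08)},
    "P09": {0: (100.0, -1.10), 1: (100.0, -1.12), 2: (100.0, -0.98), 3: (100.0, -0.92)},
}
PREDICTION_EPISODE_MEAN = {0: (94.0, -0.56), 1: (93.1, -0.52), 2: (94.2, -0.44), 3: (95.9, -0.48)}
PREDICTION_EPISODE_SD = {0: (6.9, 0.55), 1: (11.9, 0.47), 2: (7.9, 0.43), 3: (3.6, 0.46)}

# MTD precision, detection model: {pid: {mt: (TP, FP, PR %)}}
DETECTION_MTD = {
    "P01": {0: (324, 231, 58.4), 1: (323, 227, 58.7), 2: (330, 245, 57.4), 3: (321, 236, 57.6)},
    "P02": {0: (436, 346, 55.8), 1: (443, 337, 56.8), 2: (434, 346, 55.6), 3: (436, 343, 56.0)},
    "P03": {0: (79, 268, 22.8), 1: (82, 276, 22.9), 2: (87, 270, 24.4), 3: (81, 271, 23.0)},
    "P06": {0: (221, 575, 27.8), 1: (233, 608, 27.7), 2: (221, 570, 27.9), 3: (232, 604, 27.8)},
    "P07": {0: (1147, 409, 73.7), 1: (1128, 437, 72.1), 2: (1131, 407, 73.5), 3: (1196, 414, 74.3)},
    "P08": {0: (211, 391, 35.0), 1: (213, 381, 35.9), 2: (206, 374, 35.5), 3: (206, 373, 35.6)},
    "P09": {0: (62, 797, 7.2), 1: (61, 844, 6.7), 2: (67, 851, 7.3), 3: (71, 836, 7.8)},
}
DETECTION_MTD_TOTAL = {0: (2480, 3017), 1: (2483, 3110), 2: (2476, 3063), 3: (2543, 3077)}
DETECTION_MTD_MEAN_PR = {0: 40.1, 1: 40.1, 2: 40.2, 3: 40.3}
DETECTION_MTD_SD_PR = {0: 21.6, 1: 21.5, 2: 21.2, 3: 21.5}

# MTD precision, prediction model
PREDICTION_MTD = {
    "P01": {0: (171, 383, 30.9), 1: (162, 377, 30.1), 2: (137, 338, 28.8), 3: (154, 429, 26.4)},
    "P02": {0: (117, 705, 14.2), 1: (123, 721, 14.6), 2: (126, 699, 15.3), 3: (132, 781, 14.5)},
    "P03": {0: (41, 205, 16.7), 1: (40, 154, 20.6), 2: (32, 157, 16.9), 3: (42, 213, 16.5)},
    "P06": {0: (73, 728, 9.1), 1: (70, 649, 9.7), 2: (63, 474, 11.7), 3: (67, 535, 11.1)},
    "P07": {0: (998, 1565, 38.9), 1: (793, 1641, 32.6), 2: (508, 1691, 23.1), 3: (365, 1863, 16.4)},
    "P08": {0: (120, 437, 21.5), 1: (78, 413, 15.9), 2: (64, 342, 15.8), 3: (66, 492, 11.8)},
    "P09": {0: (48, 1008, 4.5), 1: (46, 883, 5.0), 2: (44, 832, 5.0), 3: (32, 1010, 3.1)},
}
PREDICTION_MTD_TOTAL = {0: (1568, 5031), 1: (1312, 4838), 2: (974, 4533), 3: (858, 5323)}
PREDICTION_MTD_MEAN_PR = {0: 19.4, 1: 18.3, 2: 16.7, 3: 14.3}
PREDICTION_MTD_SD_PR = {0: 11.2, 1: 9.4, 2: 7.1, 3: 6.5}

# 2.5 s no-cue protocol, applied to the highest-precision configurations:
# detection at mt = 3 s, prediction at mt = 0 s.
# {pid: (identified %, TP, FP, PR %)}
NO_CUE_DETECTION_MT3 = {
    "P01": (93.8, 45, 40, 52.9),
    "P02": (85.7, 45, 73, 38.1),
    "P03": (76.9, 11, 67, 14.1),
    "P06": (100.0, 23, 108, 17.6),
    "P07": (88.5, 187, 98, 65.6),
    "P08": (100.0, 25, 67, 27.2),
    "P09": (100.0, 10, 132, 7.0),
}
NO_CUE_DETECTION_TOTAL = (346, 585)
NO_CUE_DETECTION_MEAN = (92.1, 31.8)  # identified %, PR %
NO_CUE_DETECTION_SD = (8.2, 19.9)

NO_CUE_PREDICTION_MT0 = {
    "P01": (95.9, 47, 51, 48.0),
    "P02": (94.3, 50, 76, 39.7),
    "P03": (78.6, 12, 54, 18.2),
    "P06": (100.0, 24, 109, 18.0),
    "P07": (96.4, 222, 164, 57.5),
    "P08": (91.7, 23, 64, 26.4),
    "P09": (100.0, 11, 165, 6.3),
}
NO_CUE_PREDICTION_TOTAL = (389, 683)
NO_CUE_PREDICTION_MEAN = (93.8, 30.6)
NO_CUE_PREDICTION_SD = (6.8, 17.0)
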