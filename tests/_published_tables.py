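"""Published reference values used as fixed inputs by the acceptance tests.

These numbers are printed results from a peer-reviewed cuffless
blood-pressure study (MIV feature rankings, per-individual agreement
statistics, and clinical-grade rows); they serve as ground truth for the
arithmetic the package implements, not as data the models are fit to.
"""

# Ranked (feature, MIV, printed cumulative contribution) for the SBP model
SBP_MIV_TABLE = [
    ("BMI", 12.5567, 0.1600),
    ("t_downr", 11.5329, 0.3069),
    ("t_bf", 7.4782, 0.4022),
    ("t_fbr", 6.9880, 0.4912),
    ("PTT_c", 4.7147, 0.5512),
    ("t_up", 3.8678, 0.6005),
    ("t_bfr", 3.7754, 0.6486),
    ("t_down", 3.2777, 0.6904),
    ("H_er", 3.1959, 0.7311),
    ("t_aer", 2.6251, 0.7645),
    ("t_upr", 2.6234, 0.7979),
    ("HR", 2.5713, 0.8307),
    ("K", 2.5514, 0.8632),
    ("PTT_a", 2.4541, 0.8945),
    ("t_ae", 2.4190, 0.9253),
    ("gender", 2.0847, 0.9518),
    ("H_fr", 2.0090, 0.9774),
    ("t_fb", 1.7716, 1.0),
]

# Ranked (feature, MIV, printed cumulative contribution) for the DBP model
DBP_MIV_TABLE = [
    ("t_downr", 10.3509, 0.1453),
    ("H_er", 7.1181, 0.2453),
    ("t_bf", 6.7586, 0.3401),
    ("t_fbr", 6.3810, 0.4298),
    ("BMI", 5.5027, 0.5070),
    ("t_bfr", 4.9504, 0.5765),
    ("t_ae", 4.4072, 0.6384),
    ("t_up", 3.5946, 0.6889),
    ("HR", 3.2784, 0.7349),
    ("t_aer", 3.1370, 0.7790),
    ("t_fb", 2.4708, 0.8136),
    ("t_down", 2.4611, 0.8482),
    ("t_upr", 2.3780, 0.8816),
    ("PTT_a", 2.0499, 0.9104),
    ("H_gr", 2.0185, 0.9387),
    ("K", 1.8294, 0.9644),
    ("H_ar", 1.3742, 0.9837),
    ("PTT_c", 1.1615, 1.0),
]

# Published 14-feature selections at the second-round threshold (0.89)
SBP_SELECTED_14 = [name for name, _, _ in SBP_MIV_TABLE[:14]]
DBP_SELECTED_14 = [name for name, _, _ in DBP_MIV_TABLE[:14]]

# Per-individual test results: individual -> (RMSE, MAD, STD), n = 6 each
SBP_PER_INDIVIDUAL = {
    "Test9": (3.3667, 2.7483, 3.6798),
    "Test10": (1.9918, 1.6463, 2.0956),
    "Test11": (6.03, 4.7696, 4.0416),
    "Test12": (2.6706, 2.3583, 2.603),
    "Test13": (2.7154, 2.2694, 2.9716),
    "Test23": (1.7656, 1.6088, 1.5235),
    "Test24": (2.1268, 1.593, 1.7522),
    "Test25": (2.7512, 2.117, 1.9318),
    "Test26": (4.7518, 4.1512, 5.1785),
    "Test27": (3.4544, 2.6524, 2.7124),
}
DBP_PER_INDIVIDUAL = {
    "Test9": (3.5002, 3.1502, 3.1158),
    "Test10": (4.2858, 4.0309, 4.0473),
    "Test11": (2.3613, 1.726, 2.5566),
    "Test12": (4.9515, 4.5651, 2.1008),
    "Test13": (4.346, 3.4716, 4.7155),
    "Test23": (1.4618, 1.3235, 1.5291),
    "Test24": (2.5727, 2.3415, 2.294),
    "Test25": (2.3513, 1.8745, 1.7989),
    "Test26": (2.7733, 2.2527, 2.5884),
    "Test27": (2.5732, 2.1541, 1.8145),
}

# Pooled published results (mmHg)
POOLED_SBP_RMSE = 3.4043
POOLED_DBP_RMSE = 3.2893
POOLED_SBP_MAD = 2.5909
POOLED_SBP_STD = 3.4148
POOLED_DBP_MAD = 2.6890
POOLED_DBP_STD = 3.3117
PLSR_SBP_MAD = 5.5768
PLSR_SBP_STD = 6.6585

# Cumulative-error percentages and published grades per model/target
BHS_CASES = [
    ((86.667, 98.3333, 100.0), "A"),   # proposed model, SBP
    ((90.0, 100.0, 100.0), "A"),       # proposed model, DBP
    ((55.0, 86.667, 95.0), "B"),       # PLSR comparison, SBP
    ((53.3333, 73.333, 100.0), "C"),   # PLSR comparison, DBP
]

# Training cohort layout: records per training subject (17 subjects)
TRAIN_RECORD_COUNTS = (44, 61, 51, 52, 52, 31, 40, 53,
                       27, 47, 41, 28, 64, 55, 20, 55, 54)
N_TRAIN_RECORDS = 775
N_TEST_RECORDS = 120
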