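"""Published aggregate results of the multinational PPH early-detection trial.

These are group-level summary numbers as printed in the trial's public report
(counts, proportions, adjusted differences, thresholds).  The patient-level
data are not public; the synthetic-trial generator is calibrated so that data
simulated at full scale reproduce these aggregates, and the validation suite
recomputes the derived quantities (risks, follow-up, ICERs) from them.

All costs are 2022 USD.
"""

# trial accounting
TOTAL_PATIENTS = 210_132
BASELINE_PATIENTS = 110_473
IMPLEMENTATION_PATIENTS = 99_659
SOURCE_VERIFIED_PATIENTS = 206_455
CLUSTERS = 78
CLUSTERS_BY_COUNTRY = {"kenya": 14, "nigeria": 38, "south_africa": 14, "tanzania": 12}

# implementation phase, complete-case analysis set
SEVERE_PPH_EVENTS = {"intervention": 786, "usual_care": 2129}
SEVERE_PPH_DENOMINATOR = {"intervention": 48_678, "usual_care": 50_043}
GROUP_N = {"intervention": 48_678, "usual_care": 50_044}

# PPH (>=500 ml) proportions, implementation phase
PPH_RATE = {"intervention": 0.085, "usual_care": 0.167}

# baseline phase severe PPH (both arms still under usual care)
BASELINE_SEVERE_PPH = {
    "intervention": (1920, 50_720),
    "usual_care": (2535, 57_010),
}

# per-patient means (s.d.) in the implementation phase
MEAN_COST = {"intervention": 45.14, "usual_care": 43.19}
SD_COST = {"intervention": 107.93, "usual_care": 126.84}
MEAN_DALYS = {"intervention": 0.00767, "usual_care": 0.01158}
SD_DALYS = {"intervention": 0.394, "usual_care": 0.454}

# baseline-phase per-patient means (s.d.)
BASELINE_MEAN_COST = {"intervention": 45.43, "usual_care": 42.05}
BASELINE_MEAN_DALYS = {"intervention": 0.01037, "usual_care": 0.01314}

# adjusted differences (intervention minus usual care) with 95% CIs
ADJUSTED_RISK_DIFFERENCE_PP = (-2.6, -3.1, -2.1)
ADJUSTED_COST_DIFFERENCE = (0.30, -2.31, 2.78)
ADJUSTED_DALY_DIFFERENCE = (-0.00266, -0.00814, 0.00287)

# printed ICERs (computed from unrounded internal estimates)
ICER_PER_SEVERE_PPH_AVERTED = 11.83
ICER_PER_DALY_AVERTED = 113.91

# weighted willingness-to-pay thresholds, USD per DALY averted
WEIGHTED_GDP_THRESHOLD = 2816.0
WEIGHTED_OPPORTUNITY_COST_THRESHOLD = 1690.0

# deterministic sensitivity analysis on the drape device price (2023 USD/unit):
# adjusted cost difference at each price; DALY difference unchanged
DSA_DRAPE = {1.00: -0.01, 0.75: -0.30, 0.50: -0.61}
DRAPE_BASE_PRICE_2023 = 1.25
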