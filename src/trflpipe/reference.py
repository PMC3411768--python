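"""Published summary statistics for the two study plants.

These are the monthly-average operational parameters (mean +/- sd over the
12-month study) and per-enzyme OTU richness reported for a high-capacity
(HC, ~41 MLD average daily flow) and a low-capacity (LC, ~1.9 MLD)
conventional activated-sludge plant.  They define the default conditions the
synthetic-data generator emulates and the worked ratios the package's
examples recompute; they are data, not computation.
"""

from __future__ import annotations

#: Operational parameter means per plant (units in comments).
OPERATIONAL_MEANS = {
    "HC": {
        "bod_in": 297.50,   # mg/L
        "bod_out": 4.13,    # mg/L
        "tss_in": 54.33,    # mg/L
        "tss_out": 1.78,    # mg/L
        "adf": 41.20,       # MLD
        "hrt": 7.21,        # hours
        "srt": 10.59,       # days
        "fm": 0.58,         # F/M ratio
        "ph": 6.63,
        "po4": 103.92,      # mg/L
        "no3": 4.90,        # mg/L
        "temperature": 29.92,  # deg C
    },
    "LC": {
        "bod_in": 173.33,
        "bod_out": 5.18,
        "tss_in": 162.83,
        "tss_out": 10.81,
        "adf": 1.88,
        "hrt": 8.73,
        "srt": 3.32,
        "fm": 0.09,
        "ph": 6.64,
        "po4": 61.29,
        "no3": 5.54,
        "temperature": 26.42,
    },
}

#: Matching standard deviations.
OPERATIONAL_SDS = {
    "HC": {
        "bod_in": 186.98,
        "bod_out": 1.60,
        "tss_in": 12.91,
        "tss_out": 1.89,
        "adf": 4.27,
        "hrt": 0.65,
        "srt": 3.69,
        "fm": 0.45,
        "ph": 0.37,
        "po4": 38.60,
        "no3": 2.09,
        "temperature": 1.00,
    },
    "LC": {
        "bod_in": 29.90,
        "bod_out": 3.27,
        "tss_in": 49.54,
        "tss_out": 11.81,
        "adf": 0.33,
        "hrt": 1.78,
        "srt": 1.63,
        "fm": 0.03,
        "ph": 0.34,
        "po4": 37.87,
        "no3": 2.02,
        "temperature": 0.67,
    },
}

#: Mean +/- sd OTU richness per restriction enzyme and plant.
RICHNESS = {
    "HC": {"HaeIII": (78, 8.6), "RsaI": (68, 11.6), "MspI": (77, 12.4)},
    "LC": {"HaeIII": (66, 10.8), "RsaI": (64, 15.3), "MspI": (77, 8.0)},
}

#: Study-average richness per plant (mean over enzymes).
AVERAGE_RICHNESS = {"HC": 74.0, "LC": 69.0}

#: Reported influent-to-effluent BOD Pearson correlations per plant.
BOD_IN_OUT_CORRELATION = {"HC": 0.4878, "LC": -0.6330}

#: Species-flow scaling exponent reported for these plants.
SPECIES_FLOW_Z = 0.359

#: The ten explanatory variables used in the constrained ordination.
CCA_VARIABLES = [
    "bod_in", "adf", "fm", "hrt", "no3",
    "ph", "po4", "srt", "temperature", "tss_in",
]
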