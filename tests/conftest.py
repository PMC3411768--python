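import numpy as np
import pandas as pd
import pytest

from trflpipe import Profile, SimulationConfig, PlantSpec
from trflpipe.synthetic import simulate_peak_tables


def make_profile(values, sizes=None, sample_id="s1", enzyme="HaeIII", normalized=True):
    values = np.asarray(values, dtype=float)
    if sizes is None:
        sizes = 50.0 + 5.0 * np.arange(len(values))
    return Profile(sample_id, enzyme,
                   pd.Series(values, index=np.asarray(sizes, float)),
                   normalized=normalized)


@pytest.fixture(scope="session")
def study_config():
    """The default study conditions under a fixed seed."""
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def study_tables(study_config):
    """(peak table, truth table) for the default study conditions."""
    return simulate_peak_tables(study_config, with_truth=True)


@pytest.fixture(scope="session")
def small_config():
    """A reduced two-plant study for fast end-to-end tests."""
    plants = [
        PlantSpec(name="HC", flow_A=41.20, c_const=6.0, z_exp=0.359,
                  evenness=0.7, turnover=0.05, bod_inf_eff_corr=0.5,
                  operational_means={"bod_in": 300.0, "bod_out": 4.0,
                                     "tss_in": 54.0, "tss_out": 2.0,
                                     "adf": 41.2, "hrt": 7.2, "srt": 10.6,
                                     "fm": 0.58, "ph": 6.6, "po4": 100.0,
                                     "no3": 5.0, "temperature": 30.0},
                  operational_sds={"bod_in": 50.0, "bod_out": 1.0,
                                   "tss_in": 10.0, "tss_out": 1.0,
                                   "adf": 4.0, "hrt": 0.6, "srt": 3.0,
                                   "fm": 0.4, "ph": 0.3, "po4": 30.0,
                                   "no3": 2.0, "temperature": 1.0}),
        PlantSpec(name="LC", flow_A=1.88, c_const=6.0, z_exp=0.359,
                  evenness=0.5, turnover=0.25, bod_inf_eff_corr=-0.6,
                  operational_means={"bod_in": 170.0, "bod_out": 5.0,
                                     "tss_in": 160.0, "tss_out": 10.0,
                                     "adf": 1.88, "hrt": 8.7, "srt": 3.3,
                                     "fm": 0.09, "ph": 6.6, "po4": 60.0,
                                     "no3": 5.5, "temperature": 26.0},
                  operational_sds={"bod_in": 25.0, "bod_out": 2.0,
                                   "tss_in": 40.0, "tss_out": 8.0,
                                   "adf": 0.3, "hrt": 1.5, "srt": 1.5,
                                   "fm": 0.03, "ph": 0.3, "po4": 30.0,
                                   "no3": 2.0, "temperature": 0.7}),
    ]
    return SimulationConfig(
        n_months=6, plants=plants, enzymes=("HaeIII",),
        noise_peaks_per_profile=120, seed=11,
    )
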