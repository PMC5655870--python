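import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from fibroenergetics import synthesize as syn
from fibroenergetics.core import Cohort


NOISE_FREE = syn.NoiseSpec(technical_cv=0.0, outlier_rate=0.0, protein_cv=0.0)


def single_line_cohort(profile, noise=NOISE_FREE, rng=None, group="sALS",
                       line_id="L1") -> Cohort:
    """Wrap one rendered line into a validated cohort."""
    rng = rng or np.random.default_rng(0)
    tables = syn.render_plate_data(profile, noise, rng, line_id=line_id)
    lines = pd.DataFrame([{
        "line_id": line_id, "group": group, "sex": "F", "age_onset": np.nan,
        "age_biopsy": np.nan, "alsfrs": np.nan, "progression_rate": np.nan,
        "fvc_pct": np.nan, "bmi": np.nan, "onset_site": np.nan, "passage": 7.0,
    }])
    return Cohort(lines=lines, flux=tables["flux"],
                  fluorescence=tables["fluorescence"], atp=tables["atp"],
                  atp_standard=tables["atp_standard"]).validate()


@pytest.fixture(scope="session")
def default_cfg():
    return syn.default_config(seed=0)


@pytest.fixture(scope="session")
def small_config():
    """A shrunken default cohort (12/12/8/4 lines) for fast end-to-end tests."""
    base = syn.default_config(seed=11)
    sizes = {"control": 12, "sALS": 12, "PLS": 8, "C9orf72": 4}
    groups = {g: replace(spec, n_lines=sizes[g]) for g, spec in base.groups.items()}
    return replace(base, groups=groups)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = syn.generate_cohort(small_config)
    return cohort, truth
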