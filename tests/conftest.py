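import datetime as dt

import numpy as np
import pandas as pd
import pytest

import betadose as bd


@pytest.fixture(scope="session")
def calibrated_model():
    """Seven-nuclide set calibrated to the published dose-surface constants."""
    return bd.calibrate_coefficients(bd.PUBLISHED_FIT)


@pytest.fixture(scope="session")
def locations():
    """The 72 bundled representative survey locations."""
    return bd.load_locations()


@pytest.fixture()
def location_records(locations):
    """The bundled locations as pipeline-ready records with pre-corrected ratios."""
    return pd.DataFrame(
        {
            "location_id": locations["location"],
            "lon": locations["lon"],
            "lat": locations["lat"],
            "i131_kbq_m2": locations["i131_kbq_m2"],
            "cs137_kbq_m2": locations["cs137_kbq_m2"],
            "te129m_kbq_m2": locations["te129m_kbq_m2"],
            "r_i": locations["r_i"],
            "r_t": locations["r_t"],
        }
    )


@pytest.fixture()
def survey_csv(tmp_path):
    """A small well-formed survey file with missing/non-detect entries."""
    path = tmp_path / "survey.csv"
    path.write_text(
        "location_id,lon,lat,sample_date,i131_kbq_m2,cs137_kbq_m2,te129m_kbq_m2\n"
        "A,140.75,37.60,2011-06-14,17,7900,920\n"
        "B,140.82,37.56,2011-06-14,ND,5700,450\n"
        "C,141.01,37.37,2011-07-02,55,5000,\n"
    )
    return path


def noise_free_config(**overrides):
    defaults = dict(
        dep_gsd=1.0,
        meas_gsd=1.0,
        r_i_noise=0.0,
        r_t_noise=0.0,
        i131_detection_limit=0.0,
        mesh_spacing_deg=0.05,
        west=140.4,
        south=37.0,
        east=141.1,
        north=37.9,
        seed=3,
    )
    defaults.update(overrides)
    return bd.PlumeConfig(**defaults)
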