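"""Loaders for the bundled published tables.

Two small fixtures ship with the package: the fitted-intercept table of
the dose surface (b vs r_t) and the 72 representative survey locations
with their printed activities, decay-corrected ratios and doses.  The
numeric columns were recovered from the published tables; see the file
headers for provenance notes.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .dose_surface import FitTable

__all__ = ["load_fit_table", "load_locations", "UNAMBIGUOUS_RT"]

#: r_t rows of the intercept table that are printed unambiguously; re-fits
#: matching the published coefficients use exactly these.
UNAMBIGUOUS_RT = (0.1, 0.5, 1.0, 5.0)


def _open(name: str):
    return resources.files("betadose").joinpath("data").joinpath(name)


def load_fit_table(only_unambiguous: bool = False) -> FitTable:
    """The b(r_t) intercept table; optionally only the four unambiguous rows.

    ``a_rt`` is filled with the published common slope 1.1165 for every
    row (the forward model's slope in r_i is independent of r_t).
    """
    with resources.as_file(_open("b_vs_rt_fit.csv")) as path:
        df = pd.read_csv(path, comment="#")
    if only_unambiguous:
        df = df[df["r_t"].isin(UNAMBIGUOUS_RT)]
    return FitTable(
        df["r_t"].to_numpy(),
        np.full(len(df), 1.1165),
        df["b"].to_numpy(),
    )


def load_locations() -> pd.DataFrame:
    """The 72 representative survey locations.

    Columns: location, lat, lon, activities (kBq/m2; ``te129m_kbq_m2``
    is NaN where not measured), decay-corrected ratios ``r_i``/``r_t``
    (referred to the 15 March 2011 deposition; ``r_t`` from the
    interpolated ratio map), the unit dose ``d_unit_msv`` (mSv per
    1000 kBq/m2) and the absolute one-year dose ``d_a_msv`` (mSv).
    """
    with resources.as_file(_open("survey_locations.csv")) as path:
        return pd.read_csv(path)
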