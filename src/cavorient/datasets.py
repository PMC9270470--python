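"""Bundled reference data.

The package ships the range-wide compilation of 11 woodpecker populations
(latitude, longitude, mean cavity orientation in degrees, and mean resultant
length r) used by the gradient analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from cavorient.geoclim import SiteSummary


def population_panel() -> pd.DataFrame:
    """The 11-population panel as a DataFrame sorted by latitude."""
    with resources.files("cavorient.data").joinpath("populations.csv").open("rb") as fh:
        return pd.read_csv(fh)


def population_summaries() -> list[SiteSummary]:
    """The panel as :class:`~cavorient.geoclim.SiteSummary` objects."""
    df = population_panel()
    return [
        SiteSummary(
            site=row.site,
            latitude_deg=float(row.latitude_deg),
            longitude_deg=float(row.longitude_deg),
            mean_dir_deg=float(row.mean_dir_deg),
            r=float(row.r),
        )
        for row in df.itertuples(index=False)
    ]
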