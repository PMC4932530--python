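"""Bundled reference tables.

`macaronesia_pixel_counts.csv` transcribes published range-size estimates
for 35 Macaronesian endemic bryophyte species: counts of climatically
suitable ~1-km^2 pixels on the islands (``n_mac_*``) and on the western
European / northwestern African continental fringe (``n_cont_*``), under
present climate and two 2070 concentration pathways.  It serves as a
worked-example input for the change-analysis arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_pixel_counts() -> pd.DataFrame:
    """Species x scenario suitable-pixel counts (35 rows)."""
    with resources.files("bryoclim.data").joinpath("macaronesia_pixel_counts.csv").open() as fh:
        return pd.read_csv(fh)


def species_row(table: pd.DataFrame, species: str) -> pd.Series:
    match = table[table.species == species]
    if len(match) != 1:
        raise KeyError(f"species '{species}' not found in reference table")
    return match.iloc[0]
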