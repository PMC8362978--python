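"""Bundled reference tables."""
from __future__ import annotations

import importlib.resources

import pandas as pd


def northeast_standardized_rates() -> pd.DataFrame:
    """Published standardized breast-cancer mortality rates, NE Brazil 1980-2019.

    Directly standardized rates (Segi world standard) per 100,000 women
    for the north-east region of Brazil and its nine states, in three
    versions: uncorrected (UMR), corrected for miscoding (CMR) and fully
    corrected including death under-registration (CMRQIUD).  Long
    format: locality, measure, period_start, rate.
    """
    ref = importlib.resources.files("apcmort.data") / "ne_brazil_standardized_rates.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")
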