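"""Shared builders for synthetic summary-statistic tables."""

import numpy as np
import pandas as pd
from scipy import stats as sps

import xdosage as xd


def stats_from_z(z, stratum, n=1000):
    """Wrap a Z-score vector as a SummaryStats table (unit positions)."""
    z = np.asarray(z, dtype=float)
    t = pd.DataFrame({
        "SNP": [f"s{i}" for i in range(len(z))],
        "A1": "A", "A2": "G", "freq": 0.3,
        "b": z * 0.01, "se": 0.01,
        "p": sps.chi2.sf(z**2, 1), "N": n,
        "chrom_class": "X_NONPAR", "bp": np.arange(1, len(z) + 1),
        "z": z, "chisq": z**2,
    })
    return xd.SummaryStats(t, stratum)
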