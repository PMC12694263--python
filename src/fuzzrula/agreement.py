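"""Multi-rater agreement on categorical risk labels (Fleiss' kappa).

Tables are subjects × raters matrices of category labels (e.g. Medium /
High / Severe).  The kappa computation itself is delegated to
statsmodels' inter-rater routines; this module adds label handling,
validation, the degenerate-table convention and the conventional
interpretation bands (poor < 0.4 ≤ moderate-to-good ≤ 0.75 < excellent).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats import inter_rater

_LABEL_ALIASES = {"M": "Medium", "H": "High", "S": "Severe"}


def _normalize(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        table = table.to_numpy()
    arr = np.asarray(table, dtype=object)
    if arr.ndim != 2:
        raise ValueError("rating table must be 2-D (subjects × raters)")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    out = np.empty_like(arr)
    for idx, v in np.ndenumerate(arr):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing rating at {idx}")
        s = str(v).strip()
        out[idx] = _LABEL_ALIASES.get(s, s)
    return out


def fleiss_kappa(table) -> float:
    """Fleiss' kappa for a subjects × raters table of category labels.

    Returns a value in [−1, 1].  When every rating in the table is the
    single same category, expected agreement is 1 and the statistic is
    0/0; by convention 1.0 is returned with a warning.
    """
    labels = _normalize(table)
    _, codes = np.unique(labels, return_inverse=True)
    codes = codes.reshape(labels.shape)
    counts, _ = inter_rater.aggregate_raters(codes)
    if counts.shape[1] == 1:
        warnings.warn(
            "all ratings are a single category; kappa is undefined "
            "(expected agreement = 1) and 1.0 is returned by convention",
            stacklevel=2,
        )
        return 1.0
    return float(inter_rater.fleiss_kappa(counts, method="fleiss"))


def interpret_kappa(k: float) -> str:
    """Conventional agreement band for a kappa value.

    Below 0.4 agreement is poor; 0.4–0.75 moderate to good; above 0.75
    excellent.
    """
    if not -1.0 <= k <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if k < 0.4:
        return "poor"
    if k <= 0.75:
        return "moderate-to-good"
    return "excellent"


def parse_rating_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a delimited rating table (subjects as rows, raters as columns)."""
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    first = df.columns[0].lower()
    if first in ("subject", "participant", "id"):
        df = df.set_index(df.columns[0])
    return df.apply(lambda s: s.str.strip())
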