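"""Crisp score timelines → risk categories and cumulative exposure times.

The final fuzzy score lives on [3, 7]; the worksheet's integer bands
(medium 3–4, high 5–6, severe 7) extend to the continuous scale with cut
points at the band midpoints 4.5 and 6.5.  Exposure is simply the sample
count per category times the sample period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("Medium", "High", "Severe")
SCORE_UNIVERSE = (3.0, 7.0)
DEFAULT_CUTS = (4.5, 6.5)


@dataclass
class RiskTimeline:
    """Per-sample categories plus cumulative seconds spent in each."""

    categories: np.ndarray  # array of category strings
    period: float  # seconds per sample
    exposure: dict[str, float]  # seconds per category

    @property
    def total_seconds(self) -> float:
        return len(self.categories) * self.period

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f"{c} Injury Risk [s]": [self.exposure[c]] for c in CATEGORIES}
        )


def categorize(score_c, cuts: tuple[float, float] = DEFAULT_CUTS):
    """Map final crisp score(s) to Medium / High / Severe.

    Scores below the first cut are Medium, below the second High, else
    Severe.  Scores outside the score universe raise ``ValueError``.
    """
    arr = np.asarray(score_c, dtype=float)
    lo, hi = SCORE_UNIVERSE
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"score outside the final universe [{lo}, {hi}]")
    idx = np.digitize(arr, cuts)
    if np.ndim(score_c) == 0:
        return CATEGORIES[int(idx)]
    return np.asarray(CATEGORIES, dtype=object)[idx]


def exposure_table(
    scores, rate: float, cuts: tuple[float, float] = DEFAULT_CUTS
) -> RiskTimeline:
    """Cumulative time per risk category for one side's score series.

    Accepts a raw score array or a :class:`~fuzzrula.rula.RulaScores`
    (its ``score_c``).  Conservation holds exactly: exposures sum to
    ``n / rate`` seconds.
    """
    if hasattr(scores, "score_c"):
        scores = scores.score_c
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score series")
    if rate <= 0:
        raise ValueError("rate must be positive")
    cats = categorize(arr, cuts)
    period = 1.0 / rate
    exposure = {c: float(np.count_nonzero(cats == c)) * period for c in CATEGORIES}
    return RiskTimeline(cats, period, exposure)


def exposure_frame(timelines: dict[str, RiskTimeline]) -> pd.DataFrame:
    """Tabulate per-side exposures like the published per-experiment tables."""
    rows = {
        side.capitalize(): [tl.exposure[c] for c in CATEGORIES]
        for side, tl in timelines.items()
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"{c} Injury Risk [s]" for c in CATEGORIES]
    ).rename_axis("Upper Limb Side")


def mean_exposure(tables: list[dict[str, RiskTimeline]]) -> pd.DataFrame:
    """Arithmetic mean of exposure tables across participants (helper only)."""
    frames = [exposure_frame(t) for t in tables]
    return sum(frames[1:], frames[0]) / len(frames)


def plot_exposure_timeline(timeline: RiskTimeline, path=None, ax=None):
    """Stacked step plot of the category sequence over time (optional export)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    levels = {c: i for i, c in enumerate(CATEGORIES)}
    y = np.vectorize(levels.get)(timeline.categories)
    t = np.arange(len(y)) * timeline.period
    ax.step(t, y, where="post", lw=0.8)
    ax.set_yticks(range(len(CATEGORIES)), CATEGORIES)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("risk level")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
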