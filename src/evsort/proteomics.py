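"""Two-group comparison of plasma-EV protein intensities.

Per protein, the fold change is the log2 ratio of arithmetic group means of
normalized intensities (metastatic over early), and significance comes from
a two-sided unpaired t-test on the intensities at raw p < alpha — no
multiple-testing correction, matching the volcano-plot convention of
colouring raw-p-significant proteins. The equal-variance (Student) test is
the default; ``welch=True`` switches to the unequal-variance form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import IntensityTable

logger = logging.getLogger(__name__)


@dataclass
class ProteinStat:
    protein_id: str
    mean_early: float
    mean_met: float
    log2fc: float
    t_stat: float
    p: float
    significant: bool
    direction: str  # up | down | none


def group_log2fc(table: IntensityTable, protein_id: str) -> float:
    """log2(mean metastatic / mean early) of normalized intensities."""
    early = table.intensities.loc[protein_id, table.group_columns("early")]
    met = table.intensities.loc[protein_id, table.group_columns("metastatic")]
    me, mm = float(np.mean(early)), float(np.mean(met))
    if me <= 0 or mm <= 0:
        raise ValueError(f"non-positive group mean for protein {protein_id!r}")
    return float(np.log2(mm / me))


def ttest_volcano(
    table: IntensityTable,
    alpha: float = 0.05,
    *,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-protein t-test and volcano classification.

    Returns a DataFrame indexed by protein id with columns mean_early,
    mean_met, log2fc, t_stat, p, significant, direction. Proteins with zero
    variance in both groups and equal means get p = 1 (logged).
    """
    early_cols = table.group_columns("early")
    met_cols = table.group_columns("metastatic")
    if len(early_cols) < 2 or len(met_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    early = table.intensities[early_cols].to_numpy(float)
    met = table.intensities[met_cols].to_numpy(float)

    t_stat, p = stats.ttest_ind(met, early, axis=1, equal_var=not welch)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("ttest_volcano: %d protein(s) with zero variance in both "
                    "groups; reporting p = 1", int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
        t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)

    mean_early = early.mean(axis=1)
    mean_met = met.mean(axis=1)
    log2fc = np.log2(mean_met / mean_early)
    significant = p < alpha
    direction = np.where(~significant, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "mean_early": mean_early,
            "mean_met": mean_met,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p": p,
            "significant": significant,
            "direction": direction,
        },
        index=table.intensities.index,
    )
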