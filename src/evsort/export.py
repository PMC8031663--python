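"""Fold-enrichment statistic and classification of selectively exported miRNAs.

A passively sampled miRNA changes equally in EVs and cells when CAVIN1 is
expressed, so its EV and cellular log2 fold changes coincide. Selective
export shows up as an EV change unexplained by the cellular change; the
statistic is

    FE = log2FC_EV - log2FC_cell

and a miRNA is called selectively exported (direction "down", the CAVIN1-
suppressed case) when both inclusive thresholds hold:

    log2FC_EV <= tau_ev   and   FE <= tau_fe

with defaults tau_ev = -1 (at least a twofold EV decrease) and
tau_fe = -0.5 (EV depleted relative to cell). Boundary rows select.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExportConfig:
    tau_ev: float = -1.0
    tau_fe: float = -0.5
    direction: str = "down"
    max_q: float | None = None  # optional significance gate, default off

    def validate(self) -> None:
        if self.direction not in ("down", "up"):
            raise ValueError("direction must be 'down' or 'up'")


def compute_fold_enrichment(log2fc_ev: float, log2fc_cell: float) -> float:
    """FE = log2FC_EV - log2FC_cell; both inputs must be finite."""
    if not (math.isfinite(log2fc_ev) and math.isfinite(log2fc_cell)):
        raise ValueError("fold enrichment requires finite log2 fold changes")
    return log2fc_ev - log2fc_cell


def classify_selective_export(
    table: pd.DataFrame,
    config: ExportConfig | None = None,
) -> pd.DataFrame:
    """Classify each miRNA row as selectively exported or not.

    ``table`` needs columns ``log2fc_ev`` and ``log2fc_cell`` indexed by
    miRNA id (one row per miRNA; duplicates raise). Rows with a missing
    value in either compartment are excluded with a logged count (FE is
    undefined there). Output preserves input order and adds ``fe`` and
    ``selected``. ``direction="up"`` mirrors the test with >= and
    sign-flipped thresholds.
    """
    config = config or ExportConfig()
    config.validate()
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate miRNA ids: {dup}")
    out = table.copy()
    complete = out["log2fc_ev"].notna() & out["log2fc_cell"].notna()
    if (~complete).any():
        logger.info("classify_selective_export: excluding %d miRNA(s) present "
                    "in only one compartment", int((~complete).sum()))
        out = out.loc[complete].copy()
    out["fe"] = [
        compute_fold_enrichment(ev, cell)
        for ev, cell in zip(out["log2fc_ev"], out["log2fc_cell"])
    ]
    if config.direction == "down":
        selected = (out["log2fc_ev"] <= config.tau_ev) & (out["fe"] <= config.tau_fe)
    else:
        selected = (out["log2fc_ev"] >= -config.tau_ev) & (out["fe"] >= -config.tau_fe)
    if config.max_q is not None and "bh_q_ev" in out.columns:
        selected &= out["bh_q_ev"] <= config.max_q
    out["selected"] = selected
    return out


def merge_contrasts(ev: pd.DataFrame, cell: pd.DataFrame) -> pd.DataFrame:
    """Join the EV and cell differential tables (from
    :func:`evsort.diffabund.nb_differential`) into the classifier's input:
    outer join on miRNA id with columns log2fc_ev / log2fc_cell (and the
    BH q-values, carried along for the optional gate)."""
    joined = pd.DataFrame({
        "log2fc_ev": ev["log2fc"],
        "log2fc_cell": cell["log2fc"],
        "bh_q_ev": ev.get("bh_q"),
        "bh_q_cell": cell.get("bh_q"),
    })
    return joined
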