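"""ADME retention filter for herb ingredient tables.

Herbal products contribute dozens of chemically characterized ingredients,
most of which are poor oral-drug candidates. The conventional
absorption/distribution/metabolism/excretion screen keeps a compound when
its predicted oral bioavailability (OB, percent scale) and drug-likeness
(DL, unitless in [0, 1]) both clear literature thresholds — by default
OB >= 30 and DL >= 0.18, inclusive. A literature whitelist rescues
compounds with experimental support that fail the numeric screen (for
indigo naturalis, tryptanthrin is the classic example).

The filter emits a per-compound audit trail stating which clause retained
or rejected each row, preserving input order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CompoundRecord", "adme_filter", "normalize_name"]


@dataclass
class CompoundRecord:
    """One herb ingredient with its ADME scores and provenance."""

    compound_id: str
    name: str
    ob: float | None  # oral bioavailability, percent scale (30 means 30%)
    dl: float | None  # drug-likeness in [0, 1]
    smiles: str | None = None
    sources: frozenset[str] = field(default_factory=frozenset)
    whitelisted: bool = False

    def __post_init__(self) -> None:
        if self.ob is not None and self.ob < 0:
            raise ValueError(f"negative OB for {self.compound_id}: {self.ob}")
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise ValueError(f"DL outside [0, 1] for {self.compound_id}: {self.dl}")


def normalize_name(name: object) -> str:
    """Trim and casefold a compound name for whitelist matching."""
    return str(name).strip().casefold()


def _score_missing(value: object) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return True


def adme_filter(
    table: pd.DataFrame,
    ob_min: float = 30.0,
    dl_min: float = 0.18,
    whitelist: Iterable[str] = (),
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the ADME retention rule with whitelist rescue.

    Parameters
    ----------
    table:
        Compound table with at least columns ``compound_id``, ``name``,
        ``ob``, ``dl``. Row order is preserved in the output.
    ob_min, dl_min:
        Inclusive retention thresholds (``ob >= ob_min and dl >= dl_min``).
    whitelist:
        Compound names to retain regardless of scores; matched
        case-insensitively after trimming.

    Returns
    -------
    retained, audit:
        ``retained`` is the sub-table of kept rows (input order).
        ``audit`` has one dict per input row with keys ``compound_id``,
        ``name``, ``retained`` and ``reason`` (one of ``"adme-pass"``,
        ``"whitelist"``, ``"below-threshold"``, ``"missing-score"``).
    """
    if not (math.isfinite(ob_min) and math.isfinite(dl_min)):
        raise ValueError("ADME thresholds must be finite")
    wl = {normalize_name(w) for w in whitelist}

    audit: list[dict] = []
    keep_idx: list = []
    for idx, row in table.iterrows():
        name_norm = normalize_name(row["name"])
        missing = _score_missing(row.get("ob")) or _score_missing(row.get("dl"))
        if not missing and float(row["ob"]) >= ob_min and float(row["dl"]) >= dl_min:
            retained, reason = True, "adme-pass"
        elif name_norm in wl:
            retained, reason = True, "whitelist"
        elif missing:
            retained, reason = False, "missing-score"
        else:
            retained, reason = False, "below-threshold"
        if retained:
            keep_idx.append(idx)
        audit.append(
            {
                "compound_id": str(row["compound_id"]),
                "name": str(row["name"]),
                "retained": retained,
                "reason": reason,
            }
        )
    n_missing = sum(1 for a in audit if a["reason"] == "missing-score")
    if n_missing:
        logger.warning("%d compound(s) rejected for missing OB/DL scores", n_missing)
    return table.loc[keep_idx], audit
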