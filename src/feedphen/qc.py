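"""Visit-level quality control for automatic-feeder records.

Eight rules screen each visit on three quantities: feed intake per visit
(FIV, g), occupation time per visit (OTV, s), and the feed intake rate per
visit (FRV, g/min, = FIV / (OTV/60)).  A visit is removed iff it violates at
least one rule; for reporting, removal is attributed to the lowest-index
violated rule.  Records with missing fields are dropped before rule
evaluation and counted separately as incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: rule index -> human-readable definition
RULE_DEFINITIONS: dict[int, str] = {
    1: "FIV < 0 g for all visits",
    2: "FIV > 2000 g for all visits",
    3: "FIV > 20 g or FIV < -20 g for visits with OTV = 0 s",
    4: "OTV < 0 s for all visits",
    5: "OTV > 3600 s for all visits",
    6: "FRV > 500 g/min for visits with 0 < FIV < 50 g",
    7: "FRV > 350 g/min for visits with FIV > 50 g",
    8: "FRV = 0 g/min for visits with OTV > 500 s",
}


def feed_rate(fiv, otv):
    """Feed intake rate per visit in g/min; a total function.

    ``fiv / (otv / 60)`` when OTV is nonzero.  At OTV = 0 the rate is the
    signed-infinity sentinel for nonzero intake (so the rate rules also
    catch zero-time intakes) and 0 for zero intake.
    """
    fiv = np.asarray(fiv, dtype=float)
    otv = np.asarray(otv, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(
            otv != 0.0,
            fiv * 60.0 / otv,
            np.where(fiv > 0.0, np.inf, np.where(fiv < 0.0, -np.inf, 0.0)),
        )
    if rate.ndim == 0:
        return float(rate)
    return rate


def rule_masks(events: pd.DataFrame) -> dict[int, np.ndarray]:
    """Boolean violation mask per rule, evaluated independently per visit.

    Rows with missing FIV/OTV/BW evaluate to False everywhere; they are the
    incomplete-record class, not a rule violation.
    """
    fiv = events["fiv_g"].to_numpy(dtype=float)
    otv = events["otv_s"].to_numpy(dtype=float)
    complete = ~(np.isnan(fiv) | np.isnan(otv)
                 | np.isnan(events["bw_kg"].to_numpy(dtype=float)))
    frv = feed_rate(fiv, otv)
    with np.errstate(invalid="ignore"):
        masks = {
            1: fiv < 0.0,
            2: fiv > 2000.0,
            3: (otv == 0.0) & ((fiv > 20.0) | (fiv < -20.0)),
            4: otv < 0.0,
            5: otv > 3600.0,
            6: (frv > 500.0) & (fiv > 0.0) & (fiv < 50.0),
            7: (frv > 350.0) & (fiv > 50.0),
            8: (frv == 0.0) & (otv > 500.0),
        }
    return {r: m & complete for r, m in masks.items()}


@dataclass
class QcReport:
    """Per-rule exclusion accounting: kept + incomplete + removals = total."""

    total: int
    kept: int
    incomplete: int
    removed_by_rule: dict[int, int]
    rule_definitions: dict[int, str] = field(
        default_factory=lambda: dict(RULE_DEFINITIONS))

    @property
    def removed(self) -> int:
        return sum(self.removed_by_rule.values())

    def to_text(self) -> str:
        lines = [
            "visit-level quality control report",
            f"total records:      {self.total}",
            f"incomplete records: {self.incomplete}",
            f"removed by rules:   {self.removed}",
            f"kept:               {self.kept}",
            "",
        ]
        for r in sorted(self.rule_definitions):
            lines.append(f"rule {r}: removed {self.removed_by_rule.get(r, 0):>7}"
                         f"  [{self.rule_definitions[r]}]")
        return "\n".join(lines) + "\n"


def removal_rule(events: pd.DataFrame) -> np.ndarray:
    """Per-row attribution: 0 = kept, 1..8 = lowest violated rule,
    -1 = incomplete record."""
    out = np.zeros(len(events), dtype=np.int64)
    masks = rule_masks(events)
    for r in sorted(masks, reverse=True):
        out[masks[r]] = r
    incomplete = events[["fiv_g", "otv_s", "bw_kg"]].isna().any(axis=1)
    out[incomplete.to_numpy()] = -1
    return out


def apply_qc(events: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Remove every visit violating >= 1 rule; order and values preserved."""
    attribution = removal_rule(events)
    keep = attribution == 0
    removed_by_rule = {r: int((attribution == r).sum())
                       for r in RULE_DEFINITIONS}
    report = QcReport(
        total=len(events),
        kept=int(keep.sum()),
        incomplete=int((attribution == -1).sum()),
        removed_by_rule=removed_by_rule,
    )
    return events.loc[keep].copy(), report
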