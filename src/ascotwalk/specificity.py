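"""Group-level PSI summaries and group-specific exon calls.

Samples are grouped (cell types, tissues, conditions); each event gets a
per-group mean PSI over its informative samples. An exon is *enriched* in
a target group when its mean PSI exceeds the best of all other groups by
at least a threshold (default 50 percentage points), and *depleted* under
the mirrored criterion. The contrast is a min-gap against the closest
other group — a single other cell type sharing the exon vetoes
specificity — and is deliberately descriptive (no hypothesis testing):
calls are threshold crossings on PSI, not p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psi import PsiMatrix

__all__ = ["GroupSummary", "SpecificityCall", "group_means", "call_specific", "summaries_frame", "calls_frame"]

THRESHOLD = 50.0
MIN_GROUP_N = 2
MIN_GROUPS_INFORMATIVE = 3


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean PSI for one event (NaN when a group has fewer than
    the required number of informative samples)."""

    event_id: str
    means: dict[str, float]
    informative_n: dict[str, int]


@dataclass(frozen=True)
class SpecificityCall:
    event_id: str
    target_group: str
    delta: float
    direction: str  # "enriched" | "depleted"


def group_means(
    psi: PsiMatrix,
    groups: dict[str, str],
    min_group_n: int = MIN_GROUP_N,
) -> list[GroupSummary]:
    """Mean PSI per group over non-missing cells only."""
    unknown = sorted(set(psi.samples) - set(groups))
    if unknown:
        raise ValueError(f"samples without a group assignment: {', '.join(unknown)}")
    labels = sorted(set(groups[s] for s in psi.samples))
    columns = {g: [i for i, s in enumerate(psi.samples) if groups[s] == g] for g in labels}
    out = []
    for i, event in enumerate(psi.events):
        means: dict[str, float] = {}
        informative_n: dict[str, int] = {}
        for g, cols in columns.items():
            values = psi.psi[i, cols]
            defined = values[~np.isnan(values)]
            informative_n[g] = int(defined.size)
            means[g] = float(defined.mean()) if defined.size >= min_group_n else float("nan")
        out.append(GroupSummary(event_id=event.event_id, means=means, informative_n=informative_n))
    return out


def call_specific(
    summaries: list[GroupSummary],
    threshold: float = THRESHOLD,
    min_groups_informative: int = MIN_GROUPS_INFORMATIVE,
) -> list[SpecificityCall]:
    """Enriched/depleted calls per event × group at a min-gap threshold.

    For each group G with a defined mean: enriched iff
    mean(G) − max(other defined means) ≥ threshold; depleted iff
    min(other defined means) − mean(G) ≥ threshold. Events with fewer than
    ``min_groups_informative`` defined group means are skipped. Output is
    sorted by |delta| descending.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must lie in (0, 100]")
    calls: list[SpecificityCall] = []
    for summary in summaries:
        defined = {g: m for g, m in summary.means.items() if not math.isnan(m)}
        if len(defined) < min_groups_informative:
            continue
        for g, mean in defined.items():
            others = [m for h, m in defined.items() if h != g]
            gap_up = mean - max(others)
            gap_down = min(others) - mean
            if gap_up >= threshold:
                calls.append(SpecificityCall(summary.event_id, g, gap_up, "enriched"))
            elif gap_down >= threshold:
                calls.append(SpecificityCall(summary.event_id, g, -gap_down, "depleted"))
    calls.sort(key=lambda c: (-abs(c.delta), c.event_id, c.target_group))
    return calls


def summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Event × group matrix of mean PSI (NaN where undefined)."""
    rows = {s.event_id: s.means for s in summaries}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("event_id")


def calls_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "target_group": c.target_group,
                "delta": round(c.delta, 1),
                "direction": c.direction,
            }
            for c in calls
        ],
        columns=["event_id", "target_group", "delta", "direction"],
    )
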