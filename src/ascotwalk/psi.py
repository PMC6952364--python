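"""Percent-spliced-in (PSI) quantification from junction counts.

For one event in one sample, let Ī be the inclusion evidence and X̄ the
exclusion evidence, each summarized from the member junction counts. Then

    PSI = 100 · Ī / (Ī + X̄)

with an informative-read total round(Ī + X̄); cells whose informative total
falls below ``min_informative`` are missing (``NaN``), not zero.

Summaries by event type (``convention="mean"``, the default):

* cassette / linked — Ī is the mean count along the single inclusion path
  (so a two-junction path is not double-counted against the one-junction
  exclusion), X̄ the exclusion-junction count;
* alt-ss group — Ī sums the per-variant path means, X̄ as above;
* mutually exclusive — Ī is the upstream exon's path mean, X̄ the partner
  path's mean; the reported PSI is for the upstream exon and the partner's
  is 100 minus it (not emitted separately).

``convention`` may be set to ``"sum"`` or ``"min"`` to aggregate path
counts by sum or minimum instead of the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .discovery import SpliceEvent
from .junctions import JunctionTable

__all__ = ["PsiMatrix", "event_psi", "psi_matrix"]

logger = logging.getLogger(__name__)

MIN_INFORMATIVE = 15

_AGG = {"mean": np.mean, "sum": np.sum, "min": np.min}


@dataclass
class PsiMatrix:
    """Events × samples PSI values (0-100 scale, NaN = missing) with the
    per-cell informative-read totals."""

    events: list[SpliceEvent]
    samples: list[str]
    psi: np.ndarray
    informative: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.informative = np.asarray(self.informative, dtype=np.int64)
        shape = (len(self.events), len(self.samples))
        if self.psi.shape != shape or self.informative.shape != shape:
            raise ValueError("psi/informative shape does not match events × samples")
        defined = ~np.isnan(self.psi)
        if defined.any():
            vals = self.psi[defined]
            if (vals < 0).any() or (vals > 100).any():
                raise ValueError("PSI values must lie in [0, 100]")

    @property
    def event_ids(self) -> list[str]:
        return [e.event_id for e in self.events]


def _path_stat(
    path: Sequence[tuple[int, int]],
    counts: Mapping[tuple[int, int], float],
    agg,
) -> float:
    values = []
    for j in path:
        c = float(counts.get(j, 0.0))
        if c < 0:
            raise ValueError(f"negative junction count at {j}")
        values.append(c)
    return float(agg(values))


def event_psi(
    event: SpliceEvent,
    counts: Mapping[tuple[int, int], float],
    min_informative: int = MIN_INFORMATIVE,
    convention: str = "mean",
) -> tuple[float, int]:
    """PSI for one event in one sample; returns (psi, informative).

    ``counts`` maps (start, end) to the sample's junction count; absent
    junctions count 0. The PSI is NaN when the informative total is below
    ``min_informative`` (or zero).
    """
    agg = _AGG[convention]
    if event.event_type == "mutually_exclusive":
        incl = _path_stat(event.inclusion_paths[0], counts, agg)
        excl = _path_stat(event.inclusion_paths[1], counts, agg)
    else:
        incl = sum(_path_stat(p, counts, agg) for p in event.inclusion_paths)
        excl = _path_stat(event.exclusion_junctions, counts, agg)
    informative = int(round(incl + excl))
    if informative < max(min_informative, 1) or incl + excl <= 0:
        return float("nan"), informative
    return 100.0 * incl / (incl + excl), informative


def psi_matrix(
    events: Sequence[SpliceEvent],
    table: JunctionTable,
    min_informative: int = MIN_INFORMATIVE,
    convention: str = "mean",
) -> PsiMatrix:
    """Apply :func:`event_psi` to every event × sample cell of a table."""
    chroms = {j.chrom for j in table.junctions}
    lookup_all = table.count_lookup()
    n_events, n_samples = len(events), table.n_samples
    psi = np.full((n_events, n_samples), np.nan)
    informative = np.zeros((n_events, n_samples), dtype=np.int64)
    for i, event in enumerate(events):
        if event.chrom not in chroms:
            logger.warning(
                "event %s references chromosome %s absent from the table; "
                "its cells are missing",
                event.event_id,
                event.chrom,
            )
            continue
        members = set(event.inclusion_junctions) | set(event.exclusion_junctions)
        vectors = {
            j: lookup_all.get((event.chrom,) + j, np.zeros(n_samples, dtype=np.int64))
            for j in members
        }
        for s in range(n_samples):
            cell_counts = {j: float(v[s]) for j, v in vectors.items()}
            psi[i, s], informative[i, s] = event_psi(
                event, cell_counts, min_informative, convention
            )
    return PsiMatrix(events=list(events), samples=list(table.samples), psi=psi, informative=informative)
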