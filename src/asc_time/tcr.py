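"""TCR-beta repertoire diversity and clonality.

Diversity is the Shannon entropy (natural log) of the clone-frequency
distribution over *productive unique* CDR3 clonotypes,

    H = -sum_i p_i ln p_i,      p_i = count_i / total templates.

Clonality normalizes entropy to the richness of the repertoire,

    C = 1 - H / ln(U),

with U the number of productive unique clonotypes: C = 0 for a perfectly
even repertoire, C -> 1 under dominance of a single expanded clone.  The
natural log is used throughout; mixing log bases would push C outside
[0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import CloneRecord, Component
from .stats import TestResult, mann_whitney_u, wilcoxon_signed_rank

__all__ = [
    "RepertoireMetrics",
    "productive_clones",
    "shannon_entropy",
    "clonality",
    "repertoire_metrics",
    "compare_repertoires",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepertoireMetrics:
    sample_id: str
    component: Component | None
    unique_clonotypes: int       # productive unique CDR3s (U)
    total_templates: int
    shannon_h: float             # nats
    clonality: float


def productive_clones(clones: Iterable[CloneRecord]) -> list[CloneRecord]:
    """Keep productive clonotypes; duplicate CDR3s violate the input
    invariant and raise."""
    kept = [c for c in clones if c.productive]
    seen: set[str] = set()
    for c in kept:
        if c.cdr3 in seen:
            raise ValueError(f"duplicate CDR3 in repertoire: {c.cdr3!r}")
        seen.add(c.cdr3)
    return kept


def _frequencies(clones: Sequence[CloneRecord]) -> np.ndarray:
    counts = np.array([c.count for c in clones], dtype=float)
    return counts / counts.sum()


def shannon_entropy(clones: Sequence[CloneRecord]) -> float:
    """Shannon entropy (nats) of the clone-frequency distribution."""
    if not clones:
        raise ValueError("empty repertoire has no entropy")
    p = _frequencies(clones)
    return float(-(p * np.log(p)).sum())


def clonality(clones: Sequence[CloneRecord]) -> float:
    """Clonality C = 1 - H / ln U for U >= 2 clonotypes.

    A singleton repertoire (U = 1) makes the formula 0/0; it is reported
    as C = 1 -- a single expanded clone is the limit of maximal clonal
    dominance -- with a logged warning.
    """
    if not clones:
        raise ValueError("empty repertoire has no clonality")
    u = len(clones)
    if u == 1:
        log.warning("singleton repertoire: clonality defined as 1")
        return 1.0
    c = 1.0 - shannon_entropy(clones) / math.log(u)
    # guard round-off just outside [0, 1] for uniform/degenerate inputs
    return min(1.0, max(0.0, c))


def repertoire_metrics(
    clones: Iterable[CloneRecord],
    sample_id: str = "",
    component: Component | None = None,
) -> RepertoireMetrics:
    """Filter to productive clones and compute all repertoire summaries."""
    prod = productive_clones(clones)
    if not prod:
        raise ValueError(f"{sample_id}: no productive clonotypes")
    return RepertoireMetrics(
        sample_id=sample_id,
        component=component,
        unique_clonotypes=len(prod),
        total_templates=sum(c.count for c in prod),
        shannon_h=shannon_entropy(prod),
        clonality=clonality(prod),
    )


def compare_repertoires(
    group_a: Sequence[RepertoireMetrics],
    group_b: Sequence[RepertoireMetrics],
    metric: str = "clonality",
    paired: bool = True,
) -> TestResult:
    """Compare a repertoire metric between two groups of samples.

    Paired comparisons (matched components of the same tumors) use the
    Wilcoxon signed-rank test and require identical sample_id sets;
    unpaired use Mann-Whitney.
    """
    if metric not in ("clonality", "shannon_h"):
        raise ValueError(f"unknown metric {metric!r}")
    get = lambda m: getattr(m, metric)
    if paired:
        a_by_id = {m.sample_id: get(m) for m in group_a}
        b_by_id = {m.sample_id: get(m) for m in group_b}
        if set(a_by_id) != set(b_by_id):
            raise ValueError("paired comparison requires matched sample_ids")
        ids = sorted(a_by_id)
        return wilcoxon_signed_rank([(a_by_id[i], b_by_id[i]) for i in ids])
    return mann_whitney_u([get(m) for m in group_a],
                          [get(m) for m in group_b])
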