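"""Multiplex-immunofluorescence phenotype gating and region proportions.

Cell phenotypes are boolean gates over the marker panel (e.g. regulatory
T cells are CD4+FOXP3+, NK cells CD57+, M2 macrophages CD68+CD163+).
Proportions are computed per region -- tumor, stroma, and *total*, where
total pools the cell counts of both regions (the sum of tumorous and
stromal areas), not the mean of the two percentages.

Also here: the PD-L1 tumor proportion score (TPS), the percent of viable
tumor cells with PD-L1 membrane staining, requiring at least 100 cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import KNOWN_MARKERS, CellRecord, Component, Region
from .stats import TestResult, wilcoxon_signed_rank

__all__ = [
    "PhenotypeGate",
    "RegionProportion",
    "builtin_gates",
    "region_proportions",
    "compare_regions_paired",
    "tumor_proportion_score",
]


@dataclass(frozen=True)
class PhenotypeGate:
    """A cell phenotype as required-positive / required-negative markers."""

    name: str
    required_positive: frozenset[str]
    required_negative: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = (self.required_positive | self.required_negative) - set(
            KNOWN_MARKERS)
        if unknown:
            raise ValueError(f"gate {self.name}: unknown markers {sorted(unknown)}")
        if self.required_positive & self.required_negative:
            raise ValueError(f"gate {self.name}: overlapping requirements")

    def member(self, cell: CellRecord) -> bool:
        """Gate membership is a pure function of the cell's marker map."""
        return all(cell.positive(m) for m in self.required_positive) and not any(
            cell.positive(m) for m in self.required_negative)


def _gate(name: str, *positive: str) -> PhenotypeGate:
    return PhenotypeGate(name, frozenset(positive))


def builtin_gates() -> list[PhenotypeGate]:
    """The study's cell phenotypes across the two staining panels.

    NK cells are gated solely as CD57+ (no negative requirement), matching
    how the panel defines them.
    """
    return [
        _gate("CD3+", "CD3"),
        _gate("CD4+", "CD4"),
        _gate("CD8+", "CD8"),
        _gate("Treg", "CD4", "FOXP3"),
        _gate("NK", "CD57"),
        _gate("M2-TAM", "CD68", "CD163"),
        _gate("PD1+", "PD1"),
        _gate("PDL1+", "PDL1"),
        _gate("TIM3+", "TIM3"),
        _gate("LAG3+", "LAG3"),
    ]


@dataclass(frozen=True)
class RegionProportion:
    """Percent of a region's cells inside one phenotype gate."""

    sample_id: str
    component: Component
    phenotype: str
    region: str  # tumor | stroma | total
    percent: float  # NaN when the region holds no cells
    n_cells_region: int
    n_positive: int


def region_proportions(
    cells: Sequence[CellRecord],
    gates: Sequence[PhenotypeGate] | None = None,
) -> list[RegionProportion]:
    """Per-gate phenotype percentages in tumor, stroma and pooled total.

    One row per (sample, component, gate, region).  A region with no
    cells yields a row with ``n_cells_region`` = 0 and NaN percent rather
    than being silently dropped.
    """
    if gates is None:
        gates = builtin_gates()
    groups: dict[tuple[str, Component], list[CellRecord]] = {}
    for cell in cells:
        groups.setdefault((cell.sample_id, cell.component), []).append(cell)
    rows: list[RegionProportion] = []
    for (sample_id, component), members in sorted(
            groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        by_region = {
            Region.TUMOR: [c for c in members if c.region is Region.TUMOR],
            Region.STROMA: [c for c in members if c.region is Region.STROMA],
        }
        for gate in gates:
            pos_counts = {
                region: sum(gate.member(c) for c in cs)
                for region, cs in by_region.items()
            }
            for region, cs in by_region.items():
                n = len(cs)
                pct = 100.0 * pos_counts[region] / n if n else math.nan
                rows.append(RegionProportion(
                    sample_id, component, gate.name, region.value,
                    pct, n, pos_counts[region]))
            n_total = len(members)
            n_pos = sum(pos_counts.values())
            rows.append(RegionProportion(
                sample_id, component, gate.name, "total",
                100.0 * n_pos / n_total if n_total else math.nan,
                n_total, n_pos))
    return rows


def compare_regions_paired(
    acc: Iterable[RegionProportion],
    sccc: Iterable[RegionProportion],
    phenotype: str,
    region: str = "total",
) -> TestResult:
    """Paired SCCC-vs-ACC comparison of one phenotype's proportion.

    Samples are matched by ``sample_id``; pairs where either component's
    proportion is missing (empty region) are dropped.  Delegates to the
    Wilcoxon signed-rank test; ``medians['a']`` is the ACC median,
    ``medians['b']`` the SCCC median.
    """
    def index(rows):
        return {
            r.sample_id: r.percent
            for r in rows
            if r.phenotype == phenotype and r.region == region
            and not math.isnan(r.percent)
        }

    acc_by_sample = index(acc)
    sccc_by_sample = index(sccc)
    shared = sorted(set(acc_by_sample) & set(sccc_by_sample))
    if not shared:
        raise ValueError(
            f"no complete sample pairs for {phenotype}/{region}")
    pairs = [(acc_by_sample[s], sccc_by_sample[s]) for s in shared]
    return wilcoxon_signed_rank(pairs)


def tumor_proportion_score(cells: Sequence[CellRecord]) -> float:
    """PD-L1 TPS: percent of viable tumor cells with PD-L1 staining.

    Callers pass the viable tumor cells only; fewer than 100 cells is a
    non-evaluable specimen and raises.
    """
    if len(cells) < 100:
        raise ValueError(
            f"insufficient viable tumor cells for TPS: {len(cells)} < 100")
    return 100.0 * sum(c.positive("PDL1") for c in cells) / len(cells)
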