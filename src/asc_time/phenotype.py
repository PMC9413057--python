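"""TIL-density immunophenotyping.

Each tumor component is scored at five random microscope fields for the
percentage of area occupied by mononuclear cells inside the tumor mass
(intratumoral) and in the stroma around the invasive border.  The mean
density over fields classifies the component into one of three
phenotypes:

* **inflamed** -- mean intratumoral density >= 10%, regardless of stroma;
* **excluded** -- intratumoral < 10% but stromal density >= 10%;
* **desert**   -- both densities negligible (< 10%).

The >= 10% threshold is inclusive and configurable (``til_cutoff``).
The three predicate regions partition [0, 100]^2 exactly.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import Component, TILFieldMeasurement

__all__ = [
    "ImmunePhenotype",
    "PhenotypeCall",
    "mean_til_density",
    "classify_phenotype",
    "call_phenotype",
    "cohort_distribution",
    "sample_phenotype",
]


class ImmunePhenotype(str, enum.Enum):
    INFLAMED = "inflamed"
    EXCLUDED = "excluded"
    DESERT = "desert"


#: ordering from least to most lymphocyte-infiltrated, used by the
#: worst-case whole-sample aggregation rule
_INFILTRATION_ORDER = {
    ImmunePhenotype.DESERT: 0,
    ImmunePhenotype.EXCLUDED: 1,
    ImmunePhenotype.INFLAMED: 2,
}


@dataclass(frozen=True)
class PhenotypeCall:
    sample_id: str
    component: Component
    mean_intratumoral: float
    mean_stromal: float
    phenotype: ImmunePhenotype


def mean_til_density(
    fields: Sequence[TILFieldMeasurement],
) -> tuple[float, float]:
    """Arithmetic mean (intratumoral %, stromal %) over a component's fields.

    All fields must belong to one (sample, component); classification
    applies to this per-sample mean, not to a per-field majority vote.
    """
    if not fields:
        raise ValueError("need at least one field measurement")
    keys = {(f.sample_id, f.component) for f in fields}
    if len(keys) > 1:
        raise ValueError(f"fields span multiple sample/components: {keys}")
    n = len(fields)
    return (
        sum(f.intratumoral_density for f in fields) / n,
        sum(f.stromal_density for f in fields) / n,
    )


def classify_phenotype(
    mean_intratumoral: float,
    mean_stromal: float,
    til_cutoff: float = 10.0,
) -> ImmunePhenotype:
    """Three-way immune phenotype from mean TIL densities (see module doc)."""
    for name, v in (("mean_intratumoral", mean_intratumoral),
                    ("mean_stromal", mean_stromal)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} = {v} outside [0, 100]")
    if mean_intratumoral >= til_cutoff:
        return ImmunePhenotype.INFLAMED
    if mean_stromal >= til_cutoff:
        return ImmunePhenotype.EXCLUDED
    return ImmunePhenotype.DESERT


def call_phenotype(
    fields: Sequence[TILFieldMeasurement],
    til_cutoff: float = 10.0,
) -> PhenotypeCall:
    """Average a component's fields and classify in one step."""
    mi, ms = mean_til_density(fields)
    return PhenotypeCall(
        sample_id=fields[0].sample_id,
        component=fields[0].component,
        mean_intratumoral=mi,
        mean_stromal=ms,
        phenotype=classify_phenotype(mi, ms, til_cutoff),
    )


def cohort_distribution(
    calls: Iterable[PhenotypeCall],
    component: Component | None = None,
) -> dict[ImmunePhenotype, tuple[int, float]]:
    """Phenotype -> (count, proportion) over calls, optionally one component.

    Proportions sum to 1 (within floating-point round-off); counts sum to
    the number of calls considered.
    """
    calls = [c for c in calls
             if component is None or c.component == component]
    if not calls:
        raise ValueError("no phenotype calls to summarize")
    counts = Counter(c.phenotype for c in calls)
    n = len(calls)
    return {ph: (cnt, cnt / n) for ph, cnt in counts.items()}


def sample_phenotype(
    calls: Sequence[PhenotypeCall],
    rule: str = "worst",
) -> ImmunePhenotype:
    """Aggregate a sample's per-component calls into one whole-sample call.

    Component-level calls are primary; this whole-sample roll-up is an
    interpretation layer.  The default ``worst`` rule returns the
    less-infiltrated phenotype (desert < excluded < inflamed), i.e. the
    sample is only as immunologically engaged as its coldest component;
    ``best`` returns the more-infiltrated one.
    """
    if not calls:
        raise ValueError("need at least one component call")
    if len({c.sample_id for c in calls}) > 1:
        raise ValueError("calls span multiple samples")
    key = lambda c: _INFILTRATION_ORDER[c.phenotype]
    if rule == "worst":
        return min(calls, key=key).phenotype
    if rule == "best":
        return max(calls, key=key).phenotype
    raise ValueError(f"unknown aggregation rule {rule!r}")
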