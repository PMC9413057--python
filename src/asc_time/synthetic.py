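"""Seeded generators for every input table the pipeline consumes.

Each generator emits records with the statistical structure its consuming
stage assumes, so every stage is testable without specimen data, and the
generating parameters are recoverable from the output (the
parameter-recovery test suite exercises exactly that).

Defaults encode the study conditions for a biphasic adenosquamous tumor:
paired components where the squamous component carries higher PD-L1,
PD-1, regulatory-T-cell fraction, mutation burden and TCR clonality, and
lower NK-cell fraction and TCR diversity, than the matched adenocarcinoma
component.

All randomness flows from one ``numpy.random.Generator`` seeded per call;
no global state.  Identical arguments and seed give identical output.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .io import (
    CellRecord,
    CloneRecord,
    Component,
    PatientOutcome,
    Region,
    TILFieldMeasurement,
    Treatment,
    TreatmentLine,
    BestResponse,
    TpsValue,
)
from .phenotype import ImmunePhenotype

__all__ = [
    "gen_til_fields",
    "gen_mif_cells",
    "gen_variants",
    "gen_repertoire",
    "gen_outcomes",
    "ACC_PHENOTYPE_PERCENTS",
    "SCCC_PHENOTYPE_PERCENTS",
]

# ---------------------------------------------------------------------------
# TIL density fields
# ---------------------------------------------------------------------------

#: per-phenotype (intratumoral, stromal) mean-density sampling boxes, percent.
#: Means drawn inside these boxes always classify correctly at the 10% cut.
_PHENOTYPE_BOXES = {
    ImmunePhenotype.INFLAMED: ((15.0, 40.0), (15.0, 40.0)),
    ImmunePhenotype.EXCLUDED: ((0.0, 5.0), (15.0, 40.0)),
    ImmunePhenotype.DESERT: ((0.0, 5.0), (0.0, 5.0)),
}


def gen_til_fields(
    target_phenotype: ImmunePhenotype | str,
    n_fields: int = 5,
    noise_sd: float = 2.0,
    seed: int = 0,
    sample_id: str = "S1",
    component: Component = Component.ACC,
) -> list[TILFieldMeasurement]:
    """Per-field TIL densities whose field means realize a target phenotype.

    A (intratumoral, stromal) mean is drawn uniformly from well inside the
    target phenotype's density region, then per-field Gaussian noise with
    SD ``noise_sd`` percentage points is added and clipped to [0, 100].
    """
    target_phenotype = ImmunePhenotype(target_phenotype)
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    (it_lo, it_hi), (st_lo, st_hi) = _PHENOTYPE_BOXES[target_phenotype]
    it_mean = rng.uniform(it_lo, it_hi)
    st_mean = rng.uniform(st_lo, st_hi)
    it = np.clip(it_mean + rng.normal(0.0, noise_sd, n_fields), 0.0, 100.0)
    st = np.clip(st_mean + rng.normal(0.0, noise_sd, n_fields), 0.0, 100.0)
    return [
        TILFieldMeasurement(sample_id, component, i + 1,
                            float(it[i]), float(st[i]))
        for i in range(n_fields)
    ]


# ---------------------------------------------------------------------------
# MIF cells
# ---------------------------------------------------------------------------

#: defining marker sets for the gated phenotypes
_PHENOTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "CD3+": ("CD3",),
    "CD4+": ("CD4",),
    "CD8+": ("CD8",),
    "Treg": ("CD4", "FOXP3"),
    "NK": ("CD57",),
    "M2-TAM": ("CD68", "CD163"),
    "PD1+": ("PD1",),
    "PDL1+": ("PDL1",),
    "TIM3+": ("TIM3",),
    "LAG3+": ("LAG3",),
}

#: study-condition total-region target percentages for each component:
#: squamous component with predominant PD-L1/PD-1, more Tregs, fewer NK.
SCCC_PHENOTYPE_PERCENTS: Mapping[str, float] = {
    "PDL1+": 8.5, "PD1+": 4.7, "Treg": 0.63, "NK": 0.27,
}
ACC_PHENOTYPE_PERCENTS: Mapping[str, float] = {
    "PDL1+": 1.2, "PD1+": 1.5, "Treg": 0.58, "NK": 0.71,
}


def gen_mif_cells(
    n_cells: int,
    tumor_fraction: float = 0.5,
    phenotype_props: Mapping[str, float] | None = None,
    seed: int = 0,
    sample_id: str = "S1",
    component: Component = Component.SCCC,
    background_fp_rate: float = 0.002,
) -> list[CellRecord]:
    """Segmented cells on a disk-plus-annulus layout with gated phenotypes.

    Tumor cells fill a unit disk, stromal cells the surrounding annulus;
    region labels are ground truth (no boundary inference).  Within each
    region every cell draws one phenotype (or none) from
    ``phenotype_props`` -- percentages of *all* cells -- and its defining
    markers are set positive.  Every other marker flips positive
    independently at ``background_fp_rate`` to emulate staining noise.

    Defaults emulate a squamous component (``SCCC_PHENOTYPE_PERCENTS``);
    pass ``ACC_PHENOTYPE_PERCENTS`` for the adenocarcinoma component.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0.0 <= tumor_fraction <= 1.0):
        raise ValueError("tumor_fraction must be in [0, 1]")
    if phenotype_props is None:
        phenotype_props = (SCCC_PHENOTYPE_PERCENTS
                           if component is Component.SCCC
                           else ACC_PHENOTYPE_PERCENTS)
    unknown = set(phenotype_props) - set(_PHENOTYPE_MARKERS)
    if unknown:
        raise ValueError(f"unknown phenotype name(s): {sorted(unknown)}")
    total_pct = sum(phenotype_props.values())
    if total_pct > 100.0 + 1e-9:
        raise ValueError(
            f"phenotype percentages sum to {total_pct} > 100")
    rng = np.random.default_rng(seed)
    n_tumor = int(round(n_cells * tumor_fraction))
    names = list(phenotype_props)
    probs = np.array([phenotype_props[n] / 100.0 for n in names])
    probs = np.append(probs, 1.0 - probs.sum())  # "no gated phenotype"
    cells: list[CellRecord] = []
    for idx in range(n_cells):
        in_tumor = idx < n_tumor
        # disk of radius 1 (tumor) or annulus radius 1..1.5 (stroma)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r = (math.sqrt(rng.uniform(0.0, 1.0)) if in_tumor
             else math.sqrt(rng.uniform(1.0, 2.25)))
        choice = rng.choice(len(probs), p=probs)
        markers = {}
        if choice < len(names):
            for m in _PHENOTYPE_MARKERS[names[choice]]:
                markers[m] = True
        if background_fp_rate > 0.0:
            from .io import KNOWN_MARKERS

            for m in KNOWN_MARKERS:
                if m not in markers and rng.uniform() < background_fp_rate:
                    markers[m] = True
        cells.append(CellRecord(
            sample_id=sample_id,
            component=component,
            cell_id=f"c{idx + 1}",
            x=r * math.cos(theta),
            y=r * math.sin(theta),
            region=Region.TUMOR if in_tumor else Region.STROMA,
            markers=markers,
        ))
    return cells


# ---------------------------------------------------------------------------
# Somatic variants
# ---------------------------------------------------------------------------

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))
_BASES = ("A", "C", "G", "T")


def gen_variants(
    n_pass_nonsyn: int = 5,
    n_pass_syn: int = 0,
    n_fail_vaf: int = 0,
    n_fail_reads: int = 0,
    n_fail_bias: int = 0,
    shared_with: Sequence | None = None,
    shared_k: int = 0,
    seed: int = 0,
) -> list:
    """Variant calls with exact per-category counts.

    Pass variants satisfy VAF >= 2%, >= 5 high-quality reads and no
    paired-end bias; each fail category violates exactly its one
    criterion.  ``shared_k`` variants are copied identically from
    ``shared_with`` (replacing that many de-novo pass-nonsynonymous
    calls) to emulate trunk mutations shared by paired components.
    """
    from .io import VariantCall

    counts = (n_pass_nonsyn, n_pass_syn, n_fail_vaf, n_fail_reads,
              n_fail_bias)
    if any(c < 0 for c in counts):
        raise ValueError("category counts must be >= 0")
    shared_with = list(shared_with or [])
    if shared_k > len(shared_with):
        raise ValueError("shared_k exceeds length of shared_with")
    if shared_k > n_pass_nonsyn:
        raise ValueError("shared_k exceeds n_pass_nonsyn")
    rng = np.random.default_rng(seed)
    used = {v.key for v in shared_with}
    variants: list[VariantCall] = list(shared_with[:shared_k])

    def fresh_locus() -> tuple[str, int, str, str]:
        while True:
            chrom = _CHROMS[rng.integers(len(_CHROMS))]
            pos = int(rng.integers(1, 250_000_000))
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            key = (chrom, pos, str(ref), str(alt))
            if key not in used:
                used.add(key)
                return key

    def make(consequence: str, vaf: float, reads: int,
             bias: bool) -> VariantCall:
        chrom, pos, ref, alt = fresh_locus()
        return VariantCall(chrom, pos, ref, alt, vaf, reads, consequence,
                           bias)

    def pass_vaf() -> float:
        return float(rng.uniform(0.05, 0.5))

    for _ in range(n_pass_nonsyn - shared_k):
        variants.append(make("nonsynonymous", pass_vaf(),
                             int(rng.integers(5, 100)), False))
    for _ in range(n_pass_syn):
        variants.append(make("synonymous", pass_vaf(),
                             int(rng.integers(5, 100)), False))
    for _ in range(n_fail_vaf):
        variants.append(make("nonsynonymous",
                             float(rng.uniform(0.001, 0.0199)),
                             int(rng.integers(5, 100)), False))
    for _ in range(n_fail_reads):
        variants.append(make("nonsynonymous", pass_vaf(),
                             int(rng.integers(0, 5)), False))
    for _ in range(n_fail_bias):
        variants.append(make("nonsynonymous", pass_vaf(),
                             int(rng.integers(5, 100)), True))
    return variants


# ---------------------------------------------------------------------------
# TCR repertoire
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _geometric_clonality(log_r: float, n: int) -> float:
    """Clonality of the geometric abundance series p_i ~ r^i, i = 0..n-1."""
    if log_r == 0.0:
        return 0.0
    i = np.arange(n, dtype=float)
    logw = i * log_r
    logw -= logw.max()
    w = np.exp(logw)
    p = w / w.sum()
    nz = p[p > 0.0]
    h = float(-(nz * np.log(nz)).sum())
    return 1.0 - h / math.log(n)


def gen_repertoire(
    n_clones: int,
    target_clonality: float = 0.1,
    seed: int = 0,
    total_templates: int = 100_000,
) -> list[CloneRecord]:
    """Productive clonotypes whose measured clonality hits a target.

    Clone frequencies follow a geometric abundance series p_i ~ r^i whose
    decay is monotone in clonality; the decay rate is solved by bisection
    (tolerance 1e-6 on clonality) and frequencies are scaled to
    ``total_templates`` integer counts (each clone >= 1).  If integer
    rounding pushes the emitted counts' clonality more than 0.01 from the
    target, a ValueError names the nearest achievable value.

    CDR3 amino-acid strings are random and unique; all clones productive.
    """
    if n_clones < 2:
        raise ValueError("need at least 2 clonotypes")
    if not (0.0 <= target_clonality <= 0.95):
        raise ValueError("target_clonality must be in [0, 0.95]")
    # bisection on log r in [-B, 0]; clonality is decreasing in log r
    lo, hi = -200.0, 0.0  # c(lo) -> ~1 (single dominant), c(hi) = 0
    if target_clonality == 0.0:
        log_r = 0.0
    else:
        while hi - lo > 1e-12:
            mid = (lo + hi) / 2.0
            if _geometric_clonality(mid, n_clones) > target_clonality:
                lo = mid
            else:
                hi = mid
            if abs(_geometric_clonality((lo + hi) / 2.0, n_clones)
                   - target_clonality) < 1e-6:
                break
        log_r = (lo + hi) / 2.0
    i = np.arange(n_clones, dtype=float)
    logw = i * log_r
    logw -= logw.max()
    w = np.exp(logw)
    p = w / w.sum()
    counts = np.maximum(1, np.round(p * total_templates).astype(int))
    # achieved clonality of the integer counts
    pc = counts / counts.sum()
    h = float(-(pc * np.log(pc)).sum())
    achieved = 1.0 - h / math.log(n_clones)
    if abs(achieved - target_clonality) > 0.01:
        raise ValueError(
            f"target clonality {target_clonality} infeasible for "
            f"{n_clones} clones at {total_templates} templates; nearest "
            f"achievable is {achieved:.4f}")
    rng = np.random.default_rng(seed)
    cdr3s: set[str] = set()
    while len(cdr3s) < n_clones:
        length = int(rng.integers(9, 18))
        cdr3s.add("C" + "".join(rng.choice(list(_AA), size=length)) + "F")
    ordered = sorted(cdr3s)
    rng.shuffle(ordered)
    return [CloneRecord(cdr3=ordered[j], count=int(counts[j]),
                        productive=True)
            for j in range(n_clones)]


# ---------------------------------------------------------------------------
# Clinical outcomes
# ---------------------------------------------------------------------------

_DEFAULT_RESPONSE_PROBS = {
    BestResponse.CR: 0.0,
    BestResponse.PR: 0.28,
    BestResponse.SD: 0.43,
    BestResponse.PD: 0.29,
}


def gen_outcomes(
    n: int,
    median_pfs: float = 6.0,
    median_os: float = 24.7,
    censor_rate: float = 0.2,
    response_probs: Mapping[BestResponse, float] | None = None,
    seed: int = 0,
) -> list[PatientOutcome]:
    """Synthetic Table-2-shaped cohort with exponential survival.

    PFS and OS marginals are exponential with the stated medians
    (rate = ln 2 / median).  The two endpoints share one uniform draw
    (comonotone coupling), which keeps both marginal medians exact while
    guaranteeing OS >= PFS whenever ``median_os >= median_pfs``.
    Censoring is an independent exponential follow-up time applied to
    both endpoints, with its rate calibrated so the expected fraction of
    censored PFS observations equals ``censor_rate``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if median_pfs <= 0 or median_os <= 0:
        raise ValueError("medians must be positive")
    if median_os < median_pfs:
        raise ValueError("median_os must be >= median_pfs")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must be in [0, 1)")
    if response_probs is None:
        response_probs = _DEFAULT_RESPONSE_PROBS
    response_probs = {BestResponse(k): float(v)
                      for k, v in response_probs.items()}
    if abs(sum(response_probs.values()) - 1.0) > 1e-9:
        raise ValueError("response_probs must sum to 1")
    rng = np.random.default_rng(seed)
    rate_pfs = math.log(2.0) / median_pfs
    rate_os = math.log(2.0) / median_os
    u = rng.uniform(size=n)
    t_pfs = -np.log(u) / rate_pfs
    t_os = -np.log(u) / rate_os
    if censor_rate > 0.0:
        # P(C < T) = rate_c / (rate_pfs + rate_c) = censor_rate
        rate_c = censor_rate / (1.0 - censor_rate) * rate_pfs
        c = rng.exponential(1.0 / rate_c, size=n)
    else:
        c = np.full(n, np.inf)
    responses = rng.choice(
        [r.value for r in response_probs],
        p=list(response_probs.values()), size=n)
    treatments = rng.choice([t.value for t in Treatment], size=n)
    lines = rng.choice([l.value for l in TreatmentLine], size=n)
    out: list[PatientOutcome] = []
    for j in range(n):
        out.append(PatientOutcome(
            patient_id=f"sim-{j + 1:04d}",
            center="synthetic",
            sex="Female" if rng.uniform() < 0.5 else "Male",
            age=float(np.round(rng.uniform(35, 80), 0)),
            driver_status="Wild type",
            pdl1_tps=TpsValue(float(np.round(rng.uniform(0, 100), 0))),
            treatment=Treatment(treatments[j]),
            line=TreatmentLine(lines[j]),
            best_response=BestResponse(responses[j]),
            pfs_months=float(min(t_pfs[j], c[j])),
            pfs_event=bool(t_pfs[j] <= c[j]),
            os_months=float(min(t_os[j], c[j])),
            os_event=bool(t_os[j] <= c[j]),
        ))
    return out
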