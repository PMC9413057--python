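"""MIF phenotype gating, region proportions, paired comparison and TPS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asc_time.io import CellRecord, Component, Region
from asc_time.mif import (
    PhenotypeGate,
    builtin_gates,
    compare_regions_paired,
    region_proportions,
    tumor_proportion_score,
)


def _cell(markers, region=Region.TUMOR, sample="S1", comp=Component.ACC,
          cid="c1"):
    return CellRecord(sample, comp, cid, 0.0, 0.0, region,
                      {m: True for m in markers})


def _cells(n_pos, n_total, marker, region, sample="S1",
           comp=Component.ACC):
    out = []
    for i in range(n_total):
        out.append(CellRecord(
            sample, comp, f"{region.value}{i}", 0.0, 0.0, region,
            {marker: True} if i < n_pos else {}))
    return out


class TestGates:
    def test_builtin_gate_names(self):
        names = {g.name for g in builtin_gates()}
        assert names == {"CD3+", "CD4+", "CD8+", "Treg", "NK", "M2-TAM",
                         "PD1+", "PDL1+", "TIM3+", "LAG3+"}

    def test_treg_requires_both_markers(self):
        treg = next(g for g in builtin_gates() if g.name == "Treg")
        assert treg.member(_cell(["CD4", "FOXP3"]))
        assert not treg.member(_cell(["CD4"]))
        assert not treg.member(_cell(["FOXP3"]))

    def test_nk_gate_has_no_negative_requirement(self):
        nk = next(g for g in builtin_gates() if g.name == "NK")
        # a CD57+ CD3+ cell is still an NK-gate member
        assert nk.member(_cell(["CD57", "CD3"]))

    def test_negative_requirement_excludes(self):
        gate = PhenotypeGate("CD4-only-T", frozenset(["CD3", "CD4"]),
                             frozenset(["CD8"]))
        assert gate.member(_cell(["CD3", "CD4"]))
        assert not gate.member(_cell(["CD3", "CD4", "CD8"]))

    def test_unknown_marker_in_gate_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeGate("bad", frozenset(["CD99"]))

    def test_membership_is_pure_function_of_markers(self):
        gate = next(g for g in builtin_gates() if g.name == "PDL1+")
        a = _cell(["PDL1"], region=Region.TUMOR, cid="x")
        b = _cell(["PDL1"], region=Region.STROMA, cid="y")
        assert gate.member(a) and gate.member(b)


class TestRegionProportions:
    def test_total_pools_counts_not_percent_mean(self):
        # 8/100 tumor and 9/100 stroma pool to 17/200 = 8.5%
        cells = (_cells(8, 100, "PDL1", Region.TUMOR)
                 + _cells(9, 100, "PDL1", Region.STROMA))
        rows = {r.region: r for r in region_proportions(cells)
                if r.phenotype == "PDL1+"}
        assert rows["tumor"].percent == pytest.approx(8.0)
        assert rows["stroma"].percent == pytest.approx(9.0)
        assert rows["total"].percent == pytest.approx(8.5)
        assert rows["total"].n_cells_region == 200

    def test_empty_region_is_missing_valued(self):
        cells = _cells(2, 10, "CD3", Region.TUMOR)
        rows = {r.region: r for r in region_proportions(cells)
                if r.phenotype == "CD3+"}
        assert math.isnan(rows["stroma"].percent)
        assert rows["stroma"].n_cells_region == 0
        assert rows["total"].percent == rows["tumor"].percent

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        cells = (_cells(5, 40, "CD8", Region.TUMOR)
                 + _cells(11, 60, "CD8", Region.STROMA))
        shuffled = list(cells)
        rng.shuffle(shuffled)
        def key(rows):
            return {(r.phenotype, r.region): (r.percent, r.n_positive)
                    for r in rows}
        assert key(region_proportions(cells)) == key(
            region_proportions(shuffled))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(1, 30),
           st.integers(0, 30), st.integers(1, 30))
    def test_total_between_region_percentages(self, pos_t, extra_t,
                                              pos_s, extra_s):
        n_t = pos_t + extra_t
        n_s = pos_s + extra_s
        cells = (_cells(pos_t, n_t, "PD1", Region.TUMOR)
                 + _cells(pos_s, n_s, "PD1", Region.STROMA))
        rows = {r.region: r.percent for r in region_proportions(cells)
                if r.phenotype == "PD1+"}
        assert (min(rows["tumor"], rows["stroma"]) - 1e-9
                <= rows["total"]
                <= max(rows["tumor"], rows["stroma"]) + 1e-9)


class TestPairedComparison:
    def _props(self, values, comp):
        cells = []
        for i, pct in enumerate(values):
            n_pos = int(round(pct))
            cells.extend(_cells(n_pos, 100, "PDL1", Region.TUMOR,
                                sample=f"S{i}", comp=comp))
        return [r for r in region_proportions(cells)
                if r.phenotype == "PDL1+"]

    def test_identical_pairs_give_p_one(self):
        acc = self._props([5, 8, 12], Component.ACC)
        sccc = self._props([5, 8, 12], Component.SCCC)
        res = compare_regions_paired(acc, sccc, "PDL1+")
        assert res.p_value == 1.0
        assert res.medians["difference"] == 0.0

    def test_shifted_pairs_detected(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        base = rng.uniform(1, 10, size=30)
        acc = self._props(base, Component.ACC)
        sccc = self._props(base + 7 + rng.normal(0, 2, size=30),
                           Component.SCCC)
        res = compare_regions_paired(acc, sccc, "PDL1+")
        assert res.p_value < 0.001
        assert res.medians["b"] > res.medians["a"]

    def test_component_swap_reverses_direction_same_p(self):
        acc = self._props([3, 4, 5, 9, 2, 7], Component.ACC)
        sccc = self._props([8, 9, 2, 14, 6, 11], Component.SCCC)
        fwd = compare_regions_paired(acc, sccc, "PDL1+")
        rev = compare_regions_paired(sccc, acc, "PDL1+")
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.medians["difference"] == -rev.medians["difference"]

    def test_no_complete_pairs_rejected(self):
        acc = self._props([5], Component.ACC)
        with pytest.raises(ValueError, match="no complete"):
            compare_regions_paired(acc, [], "PDL1+")


class TestTumorProportionScore:
    def test_simple_percentage(self):
        cells = _cells(100, 200, "PDL1", Region.TUMOR)
        assert tumor_proportion_score(cells) == pytest.approx(50.0)

    def test_fewer_than_100_cells_not_evaluable(self):
        cells = _cells(10, 99, "PDL1", Region.TUMOR)
        with pytest.raises(ValueError, match="insufficient"):
            tumor_proportion_score(cells)

    def test_all_negative_is_tps_zero(self):
        cells = _cells(0, 150, "PDL1", Region.TUMOR)
        assert tumor_proportion_score(cells) == 0.0
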