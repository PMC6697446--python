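"""Filter cascade, event clustering, load, proportions, trend and spectrum."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scgerm.io import GERM_STAGES, ReadEvidence, VariantCall
from scgerm.mutations import (
    MutationPipelineConfig,
    MutationalEvent,
    VariantWithCells,
    a_to_g_fraction,
    attach_cells,
    cluster_events,
    error_check,
    filter_known,
    filter_quality,
    filter_ref_depth,
    filter_somatic,
    mutated_cell_proportions,
    mutational_load,
    run_pipeline,
    substitution_spectrum,
    trend_test,
)

from conftest import make_annotation

CFG = MutationPipelineConfig()


def var(pos, qual=40.0, ref="A", alt="T", ref_depth=20, alt_depth=5, chrom="chr1"):
    return VariantCall(chrom, pos, ref, alt, qual, ref_depth, alt_depth)


def vwc(variant, alt_cells, types=None, ref_cells=None):
    return VariantWithCells(variant, alt_cells, set(types or ()), ref_cells or {})


class TestSimpleFilters:
    @pytest.mark.parametrize("qual,kept", [(24.9, False), (25.0, True), (25.1, True)])
    def test_quality_threshold_inclusive(self, qual, kept):
        assert bool(filter_quality([var(1, qual=qual)], CFG)) is kept

    @pytest.mark.parametrize("depth,kept", [(9, False), (10, True)])
    def test_ref_depth_threshold_inclusive(self, depth, kept):
        assert bool(filter_ref_depth([var(1, ref_depth=depth)], CFG)) is kept

    def test_known_exclusion_is_exact_key(self):
        known = {("chr1", 5, "A", "T")}
        assert filter_known([var(5, ref="A", alt="T")], known) == []
        assert len(filter_known([var(5, ref="A", alt="G")], known)) == 1  # different alt

    def test_known_union_of_lists(self):
        rng = np.random.default_rng(0)
        variants = [var(int(p)) for p in rng.choice(10_000, size=60, replace=False)]
        k1 = {v.key for v in variants[:20]}
        k2 = {v.key for v in variants[15:35]}
        kept = filter_known(variants, k1 | k2)
        assert {v.key for v in kept} == {v.key for v in variants[35:]}

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_filters_idempotent_and_commute(self, seed):
        rng = np.random.default_rng(seed)
        variants = [
            var(int(p), qual=float(rng.uniform(0, 50)), ref_depth=int(rng.integers(0, 20)))
            for p in rng.choice(100_000, size=30, replace=False)
        ]
        known = {v.key for v in variants if rng.random() < 0.3}
        orders = [
            lambda vs: filter_ref_depth(filter_known(filter_quality(vs, CFG), known), CFG),
            lambda vs: filter_quality(filter_known(filter_ref_depth(vs, CFG), known), CFG),
            lambda vs: filter_known(filter_quality(filter_ref_depth(vs, CFG), CFG), known),
        ]
        results = [{v.key for v in f(variants)} for f in orders]
        assert results[0] == results[1] == results[2]
        again = {v.key for v in orders[0](orders[0](variants))}
        assert again == results[0]


class TestAttachCells:
    def _evidence(self, rows):
        return [ReadEvidence("chr1", 10, "A", "T", bc, umi, allele) for bc, umi, allele in rows]

    def test_umi_counting_per_cell(self):
        ann = make_annotation({"b1": GERM_STAGES[0]})
        ev = self._evidence([("b1", "u1", "ALT"), ("b1", "u2", "ALT"), ("b1", "u3", "ALT")])
        out = attach_cells([var(10)], ev, ann)
        assert out[0].alt_cells == {"b1": (3, 0)}
        assert out[0].cell_types_touched == {GERM_STAGES[0]}

    def test_unannotated_barcode_dropped(self):
        ann = make_annotation({"b1": GERM_STAGES[0]})
        ev = self._evidence([("mystery", "u1", "ALT")])
        assert attach_cells([var(10)], ev, ann) == []

    def test_matches_brute_force_join(self):
        rng = np.random.default_rng(5)
        barcodes = [f"b{i}" for i in range(20)]
        ann = make_annotation({b: GERM_STAGES[rng.integers(6)] for b in barcodes})
        variants = [var(int(p)) for p in rng.choice(5000, size=10, replace=False) + 1]
        ev = []
        for i in range(400):
            v = variants[rng.integers(len(variants))]
            ev.append(
                ReadEvidence(v.chrom, v.pos, v.ref, v.alt, barcodes[rng.integers(20)],
                             f"u{i % 50}", "ALT" if rng.random() < 0.6 else "REF")
            )
        out = {x.key: x for x in attach_cells(variants, ev, ann)}
        for v in variants:
            expected = {}
            for bc in barcodes:
                alts = {e.umi for e in set(ev) if e.variant_key == v.key and e.barcode == bc and e.allele == "ALT"}
                refs = {e.umi for e in set(ev) if e.variant_key == v.key and e.barcode == bc and e.allele == "REF"}
                if alts:
                    expected[bc] = (len(alts), len(refs))
            if expected:
                assert out[v.key].alt_cells == expected
            else:
                assert v.key not in out


class TestSomaticFilter:
    def test_alt_in_somatic_cell_disqualifies(self):
        v = vwc(var(10), {"g1": (2, 0), "s1": (1, 0)}, {GERM_STAGES[0], "epithelial"})
        assert filter_somatic([v], CFG) == []

    def test_ref_reads_in_somatic_cells_do_not_disqualify(self):
        # only the ALT allele in a somatic cell removes the variant; the
        # reference allele is expected to be present in somatic cells
        v = vwc(var(10), {"g1": (2, 0)}, {GERM_STAGES[0]}, ref_cells={"s1": 5, "s2": 3})
        assert len(filter_somatic([v], CFG)) == 1

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_rule(self, seed):
        rng = np.random.default_rng(seed)
        types = list(GERM_STAGES) + ["hub", "cyst", "epithelial"]
        vwcs = []
        for i in range(20):
            touched = set(rng.choice(types, size=rng.integers(1, 4), replace=False))
            vwcs.append(vwc(var(10 + 50 * i), {"b": (1, 0)}, touched))
        kept = filter_somatic(vwcs, CFG)
        expected = [v for v in vwcs if not (v.cell_types_touched & {"hub", "cyst", "epithelial"})]
        assert kept == expected


class TestErrorCheck:
    def test_multi_cell_ref_absent_passes(self):
        v = vwc(var(10), {"g1": (2, 0), "g2": (3, 0), "g3": (2, 0)})
        ok, met = error_check(v, CFG)
        assert ok and met == {"C1", "C2"}

    def test_single_cell_single_umi_ref_excess_fails_all(self):
        v = vwc(var(10), {"g1": (1, 3)})
        ok, met = error_check(v, CFG)
        assert not ok and met == set()

    def test_single_cell_multi_umi_no_ref_passes(self):
        v = vwc(var(10), {"g1": (3, 0)})
        ok, met = error_check(v, CFG)
        assert ok and met == {"C2", "C3"}

    def test_c2_requires_every_cell(self):
        v = vwc(var(10), {"g1": (2, 0), "g2": (1, 4)})  # second cell has REF > ALT
        ok, met = error_check(v, CFG)
        assert met == {"C1"} and not ok

    def test_heterozygote_like_ref_equal_alt_counts_as_met(self):
        v = vwc(var(10), {"g1": (2, 2), "g2": (3, 1)})
        ok, met = error_check(v, CFG)
        assert ok and met == {"C1", "C2"}


def brute_force_events(positions, carriers, window):
    """Transitive closure by boolean matrix powers (independent of networkx)."""
    n = len(positions)
    adj = np.eye(n, dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        if abs(positions[i] - positions[j]) <= window and carriers[i] & carriers[j]:
            adj[i, j] = adj[j, i] = True
    closure = adj.copy()
    for _ in range(n):
        nxt = closure | (closure @ closure)
        if (nxt == closure).all():
            break
        closure = nxt
    components, seen = [], set()
    for i in range(n):
        if i not in seen:
            comp = frozenset(np.flatnonzero(closure[i]).tolist())
            seen |= comp
            components.append(comp)
    return set(components)


class TestClusterEvents:
    def _vwcs(self, positions, carrier_sets):
        return [
            vwc(var(p, alt="T" if i % 2 else "G"), {c: (2, 0) for c in cs})
            for i, (p, cs) in enumerate(zip(positions, carrier_sets))
        ]

    def test_window_and_carrier_rule(self):
        vwcs = self._vwcs([100, 105, 130], [{"c1"}, {"c1"}, {"c1"}])
        events = cluster_events(vwcs, CFG)
        assert sorted(len(e.members) for e in events) == [1, 2]

    def test_chained_transitive_closure_spans_beyond_window(self):
        vwcs = self._vwcs([100, 108, 116], [{"c1"}, {"c1"}, {"c1"}])
        events = cluster_events(vwcs, CFG)
        assert len(events) == 1 and len(events[0].members) == 3

    def test_nearby_without_shared_carrier_not_merged(self):
        vwcs = self._vwcs([100, 105], [{"c1"}, {"c2"}])
        assert len(cluster_events(vwcs, CFG)) == 2

    def test_event_carriers_are_union_of_members(self):
        vwcs = self._vwcs([100, 105], [{"c1", "c2"}, {"c1", "c3"}])
        (event,) = cluster_events(vwcs, CFG)
        assert event.carrier_cells == {"c1", "c2", "c3"}

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        positions = sorted(int(p) for p in rng.choice(200, size=n, replace=False) + 1)
        carriers = [
            frozenset(f"c{j}" for j in rng.choice(6, size=rng.integers(1, 4), replace=False))
            for _ in range(n)
        ]
        vwcs = self._vwcs(positions, carriers)
        ours = {
            frozenset(positions.index(k[1]) for k in e.members)
            for e in cluster_events(vwcs, CFG)
        }
        assert ours == brute_force_events(positions, carriers, CFG.cluster_window_bp)
        assert len(ours) <= n

    def test_event_count_equals_variant_count_iff_no_edges(self):
        vwcs = self._vwcs([100, 200, 300], [{"c1"}, {"c1"}, {"c1"}])
        assert len(cluster_events(vwcs, CFG)) == 3


class TestLoadAndProportions:
    def test_load_arithmetic(self):
        t = GERM_STAGES[0]
        load = mutational_load({t: 2}, {t: 100}, {t: 1_000_000}, [t])
        assert load["load"].iloc[0] == pytest.approx(2e-8)
        load0 = mutational_load({t: 0}, {t: 100}, {t: 1_000_000}, [t])
        assert load0["load"].iloc[0] == 0.0

    def test_zero_cell_or_zero_base_type_excluded(self):
        t1, t2 = GERM_STAGES[:2]
        load = mutational_load({t1: 1, t2: 1}, {t1: 10, t2: 0}, {t1: 100, t2: 100}, [t1, t2])
        assert load["cell_type"].tolist() == [t1]

    def test_event_counted_in_every_touched_type(self):
        from scgerm.mutations import events_per_type

        ann = make_annotation({"g1": GERM_STAGES[0], "g2": GERM_STAGES[1]})
        ev = MutationalEvent([("chr1", 1, "A", "T")], {"g1", "g2"}, set())
        counts = events_per_type([ev], ann)
        assert counts == {GERM_STAGES[0]: 1, GERM_STAGES[1]: 1}

    def test_proportion_bounds_and_wilson_oracle(self):
        ann = make_annotation(
            {f"g{i}": GERM_STAGES[0] for i in range(50)} | {f"h{i}": GERM_STAGES[1] for i in range(4)}
        )
        events = [
            MutationalEvent([("chr1", i, "A", "T")], {f"g{i}"}, set()) for i in range(5)
        ] + [MutationalEvent([("chr1", 99, "A", "T")], {f"h{i}" for i in range(4)}, set())]
        props = mutated_cell_proportions(events, ann, CFG, list(GERM_STAGES[:2]))
        row = props.iloc[0]
        assert (row["n_mutated"], row["n_cells"]) == (5, 50)
        # closed-form Wilson score interval, z = Phi^-1(0.975)
        z = stats.norm.ppf(0.975)
        p_hat, n = 0.1, 50
        centre = (p_hat + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        assert row["ci_lo"] == pytest.approx(centre - half, abs=1e-12)
        assert row["ci_hi"] == pytest.approx(centre + half, abs=1e-12)
        full = props.iloc[1]  # all 4 cells mutated
        assert full["proportion"] == 1.0 and full["ci_hi"] == 1.0

    def test_zero_mutated_ci_lower_bound_zero(self):
        ann = make_annotation({f"g{i}": GERM_STAGES[0] for i in range(10)})
        props = mutated_cell_proportions([], ann, CFG, [GERM_STAGES[0]])
        assert props.iloc[0]["proportion"] == 0.0 and props.iloc[0]["ci_lo"] == 0.0


class TestTrendTest:
    def test_equal_proportions_no_trend(self):
        res = trend_test([5, 5, 5], [50, 50, 50])
        assert res.chi2 == 0.0 and res.p_value == 1.0 and res.direction == "none"

    def test_two_groups_equal_two_proportion_chi_square(self):
        m, n = [12, 30], [80, 90]
        res = trend_test(m, n)
        table = np.array([[m[0], n[0] - m[0]], [m[1], n[1] - m[1]]])
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)

    def test_invariant_under_group_order_reversal(self):
        res = trend_test([28, 20, 18, 13, 6, 0], [200] * 6)
        rev = trend_test([0, 6, 13, 18, 20, 28], [200] * 6)
        assert res.chi2 == pytest.approx(rev.chi2, rel=1e-12)
        assert res.p_value == pytest.approx(rev.p_value, rel=1e-12)

    def test_frozen_r_prop_trend_oracle(self):
        # synthetic fixture; expected values frozen from R prop.trend.test
        res = trend_test([28, 20, 18, 13, 6, 0], [200] * 6)
        assert res.chi2 == pytest.approx(37.9510570147, abs=1e-9)
        assert res.p_value == pytest.approx(7.25417581126e-10, rel=1e-9)
        assert res.direction == "decreasing"

    def test_degenerate_all_or_none_mutated(self):
        assert trend_test([0, 0], [10, 10]).p_value == 1.0
        assert trend_test([10, 10], [10, 10]).p_value == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            trend_test([5], [10])
        with pytest.raises(ValueError):
            trend_test([11, 0], [10, 10])


class TestSpectrum:
    def test_tally_and_a_to_g_fraction(self):
        variants = [var(i, ref="A", alt="G") for i in range(1, 4)] + [var(99, ref="C", alt="T")]
        spec = substitution_spectrum(variants)
        assert spec["A>G"] == 3 and spec["C>T"] == 1 and spec.sum() == 4
        assert a_to_g_fraction(variants) == 0.75

    def test_empty_list_all_zeros(self):
        spec = substitution_spectrum([])
        assert len(spec) == 12 and spec.sum() == 0
        assert a_to_g_fraction([]) == 0.0


class TestRunPipeline:
    def test_empty_candidate_list_gives_empty_report(self, bundle):
        rep = run_pipeline([], [], bundle.annotation, set(), set(), bundle.coverage, CFG)
        assert rep.steps["n_surviving"].tolist() == [0] * len(rep.steps)
        assert rep.events == [] and rep.spectrum.sum() == 0

    def test_survivors_monotone_non_increasing(self, report):
        counts = report.steps["n_surviving"].tolist()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_variant_numerator_mode_counts_raw_substitutions(self, bundle):
        cfg = MutationPipelineConfig(load_numerator="variants")
        rep = run_pipeline(
            bundle.variants, bundle.evidence, bundle.annotation,
            bundle.known_keys, bundle.bulk_keys, bundle.coverage, cfg,
        )
        assert rep.load["n_events"].sum() >= len(rep.events)
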