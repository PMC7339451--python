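"""Split-search screen: oracle equivalence, expression filters,
gene-pair recurrence and the nearest-upstream-gene scenario."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fusionscreen.classify import DIB, UIB, TargetCandidate
from fusionscreen.genome import GenomeAnnotation
from fusionscreen.screen import (
    SplitSearchResult,
    apply_expression_filters,
    screen_nearest_gene,
    screen_recurrent_gene_gene,
    screen_uib_dib,
    split_search_best_group,
)
from fusionscreen.simulate import PlantedEvent, SimConfig, simulate
from fusionscreen.svio import LEFT, RIGHT

from conftest import make_call, make_cohort, make_gene


def dummy_candidate(sample, distance, mode=UIB, gene="T"):
    call = make_call(sample, "cX", 1_000 + distance, RIGHT, "cY", 5_000, LEFT)
    return TargetCandidate(call=call, target_gene=gene, mode=mode,
                           distance=distance, concordant=True, partner_desc="p")


def split_scenario(distances, folds, n_background=50, sigma=0.2, seed=0, base=10.0):
    """Breakpoint samples bp0..bpN with given folds plus clean background."""
    rng = np.random.default_rng(seed)
    bp = [f"bp{i}" for i in range(len(distances))]
    bg = [f"bg{i}" for i in range(n_background)]
    vals = {s: base * f * math.exp(rng.normal(0, sigma)) for s, f in zip(bp, folds)}
    vals.update({s: base * math.exp(rng.normal(0, sigma)) for s in bg})
    expr = pd.DataFrame([vals], index=["T"])
    cohort = make_cohort(expr)
    candidates = {s: [dummy_candidate(s, d)] for s, d in zip(bp, distances)}
    return cohort, candidates


def oracle_split(cohort, candidates, comparison="rest"):
    """Independently coded exhaustive search over all prefix groups."""
    pairs = sorted((min(c.distance for c in cands), s) for s, cands in candidates.items())
    ordered = [s for _, s in pairs]
    tt = list(cohort.expr.columns)
    expr = cohort.expr.loc["T"]
    best = None
    tested = 0
    for i in range(1, len(ordered) + 1):
        group = ordered[:i]
        rest = [s for s in tt if s not in group] if comparison == "rest" else ordered[i:]
        if not rest:
            continue
        x, y = expr[group].to_numpy(), expr[rest].to_numpy()
        if np.all(np.concatenate([x, y]) == x[0]):
            p = 1.0
        else:
            p = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
        tested += 1
        if best is None or p < best[1]:
            best = (i, p)
    return best[0], best[1], tested


class TestSplitSearch:
    def test_constructed_example_selects_the_three_closest(self):
        """Six breakpoint samples at 0.1-3.9 Mb, the nearest three with a
        10x planted effect: the search picks exactly that prefix."""
        distances = [100_000, 200_000, 300_000, 2_500_000, 3_000_000, 3_900_000]
        cohort, cands = split_scenario(distances, [10, 10, 10, 1, 1, 1], seed=4)
        res = split_search_best_group("T", UIB, cohort, None, candidates=cands)
        assert res.chosen_i == 3
        assert res.positive_samples == ("bp0", "bp1", "bp2")
        i, p, tested = oracle_split(cohort, cands)
        assert (res.chosen_i, res.n_splits_tested) == (i, tested)
        assert res.p_value == pytest.approx(p)

    @pytest.mark.parametrize("comparison", ["rest", "literal"])
    def test_matches_exhaustive_oracle_on_random_instances(self, comparison):
        rng = np.random.default_rng(77)
        for trial in range(30):
            n = int(rng.integers(1, 13))
            if comparison == "literal" and n < 2:
                n = 2
            distances = sorted(rng.integers(1_000, 4_000_000, n).tolist())
            folds = [float(rng.choice([1, 1, 5, 20])) for _ in range(n)]
            cohort, cands = split_scenario(distances, folds, seed=1000 + trial)
            res = split_search_best_group(
                "T", UIB, cohort, None, candidates=cands, comparison=comparison
            )
            i, p, tested = oracle_split(cohort, cands, comparison)
            assert res.chosen_i == i and res.n_splits_tested == tested
            assert res.p_value == pytest.approx(p)

    def test_single_breakpoint_sample(self):
        cohort, cands = split_scenario([50_000], [8], seed=5)
        res = split_search_best_group("T", UIB, cohort, None, candidates=cands)
        assert res.chosen_i == 1 and res.n_splits_tested == 1

    def test_full_ties_give_p_one(self):
        cohort, cands = split_scenario([1_000, 2_000], [1, 1], sigma=0.0, seed=6)
        res = split_search_best_group("T", UIB, cohort, None, candidates=cands)
        assert res.p_value == 1.0

    def test_distance_ties_broken_by_sample_id(self):
        cohort, cands = split_scenario([7_000, 7_000, 7_000], [3, 3, 3], seed=8)
        res = split_search_best_group("T", UIB, cohort, None, candidates=cands)
        assert res.ordered_samples == ("bp0", "bp1", "bp2")

    def test_permutation_empirical_p_is_calibrated_upward(self):
        cohort, cands = split_scenario([1_000, 2_000, 3_000], [30, 30, 30], seed=9)
        res = split_search_best_group(
            "T", UIB, cohort, None, candidates=cands, permutations=200, seed=3
        )
        assert res.empirical_p is not None
        # min-p selection bias: the empirical p exceeds the nominal minimum
        assert res.empirical_p >= res.p_value

    def test_absent_gene_fails(self):
        cohort, cands = split_scenario([1_000], [5])
        with pytest.raises(KeyError, match="missing"):
            split_search_best_group("missing", UIB, cohort, None, candidates=cands)


def result_for(positives, distances, tumor_type="TT"):
    order = np.argsort(distances, kind="stable")
    return SplitSearchResult(
        target_gene="T", tumor_type=tumor_type, mode=UIB,
        distances=tuple(int(distances[i]) for i in order),
        ordered_samples=tuple(positives[i] for i in order),
        chosen_i=len(positives), positive_samples=tuple(positives),
        p_value=0.01, n_splits_tested=len(positives),
    )


class TestExpressionFilters:
    def base_cohort(self, case_tpms, control_tpm=10.0, n_control=20):
        samples = [f"case{i}" for i in range(len(case_tpms))] + [
            f"ctl{i}" for i in range(n_control)
        ]
        vals = list(case_tpms) + [control_tpm] * n_control
        expr = pd.DataFrame([vals], index=["T"], columns=samples)
        return make_cohort(expr)

    def test_case_fold_threshold(self):
        cohort = self.base_cohort([50.0, 35.0, 60.0, 55.0])
        res = result_for(["case0", "case1", "case2", "case3"], [1, 2, 3, 4])
        out = apply_expression_filters(res, cohort)
        # 50/10 ~ 5x kept; 35/10 = 3.5x flagged out
        assert "case0" in out.kept_samples
        assert out.removed_low_fold == ("case1",)
        assert out.case_folds["case0"] == pytest.approx(50.1 / 10.1)
        assert out.passed

    def test_amplified_samples_excluded_before_folds(self):
        cohort = self.base_cohort([50.0, 60.0, 55.0, 52.0])
        cohort.cna.loc["T", "case3"] = 2
        cohort.cna.loc["T", "ctl0"] = 2
        res = result_for(["case0", "case1", "case2", "case3"], [1, 2, 3, 4])
        out = apply_expression_filters(res, cohort)
        assert out.removed_amplified == ("case3",)
        assert "ctl0" not in out.control_samples
        assert out.kept_samples == ("case0", "case1", "case2")

    def test_mean_fold_gate(self):
        cohort = self.base_cohort([45.0, 45.0, 45.0, 45.0])
        res = result_for(["case0", "case1", "case2", "case3"], [1, 2, 3, 4])
        out = apply_expression_filters(res, cohort, min_mean_fold=5.0)
        assert not out.passed  # 4.5x mean is below the 5x gate
        assert apply_expression_filters(res, cohort, min_mean_fold=4.0).passed

    def test_control_empty_fails(self):
        cohort = self.base_cohort([50.0, 50.0], n_control=0)
        res = result_for(["case0", "case1"], [1, 2])
        with pytest.raises(ValueError, match="control group empty"):
            apply_expression_filters(res, cohort)

    def test_removing_top_sample_never_raises_group_fold(self):
        tpms = [80.0, 50.0, 45.0, 70.0]
        cohort = self.base_cohort(tpms)
        full = result_for(["case0", "case1", "case2", "case3"], [1, 2, 3, 4])
        out_full = apply_expression_filters(cohort=cohort, result=full)
        reduced = result_for(["case1", "case2", "case3"], [2, 3, 4])  # drop max (case0)
        out_red = apply_expression_filters(cohort=cohort, result=reduced)
        assert out_red.group_mean_fold <= out_full.group_mean_fold


@pytest.fixture(scope="module")
def default_dataset():
    return simulate(SimConfig(seed=1))


class TestScreenUibDib:
    def test_recovers_planted_events_with_correct_labels(self, default_dataset):
        ds = default_dataset
        events = screen_uib_dib(ds.cohort, ds.ann, ds.bands)
        got = {(e.target_gene, e.mode, e.tumor_type): e for e in events}
        truth = {
            (t.target, t.mode, t.tumor_type): t
            for t in ds.manifest.events
            if t.mode in ("UIB", "DIB")
        }
        assert set(got) == set(truth)
        for key, ev in got.items():
            t = truth[key]
            assert set(s.sample for s in ev.samples) == set(t.positive_samples)
            assert ev.cp_label == ("CP" if t.expected_cp else "N_CP")
            assert ev.group_mean_fold > 5.0

    def test_amplification_exclusion_can_sink_an_event(self, default_dataset):
        ds = default_dataset
        truth = next(t for t in ds.manifest.events if t.mode == "DIB")
        cohort = ds.cohort
        cna = cohort.cna.copy()
        cna.loc[truth.target, truth.positive_samples[0]] = 2
        mutated = make_cohort(cohort.expr, tumor_type=cohort.tumor_type,
                              callsets=cohort.callsets, cna=cna,
                              junctions=cohort.junctions)
        events = screen_uib_dib(mutated, ds.ann, ds.bands)
        assert truth.target not in {e.target_gene for e in events}

    def test_three_sample_events_not_reported(self):
        cfg = SimConfig(seed=21, events=[
            PlantedEvent(kind="UIB_NCP", n_pos=3, fold=10.0, distance=1_000_000)
        ])
        ds = simulate(cfg)
        assert screen_uib_dib(ds.cohort, ds.ann, ds.bands) == []

    def test_subthreshold_folds_not_reported(self):
        cfg = SimConfig(seed=22, events=[
            PlantedEvent(kind="UIB_NCP", n_pos=6, fold=3.0, distance=1_000_000)
        ])
        ds = simulate(cfg)
        assert screen_uib_dib(ds.cohort, ds.ann, ds.bands) == []

    def test_partner_cytoband_recurrence_flag(self, default_dataset):
        ds = default_dataset
        events = screen_uib_dib(ds.cohort, ds.ann, ds.bands)
        cp = next(e for e in events if e.cp_label == "CP")
        # the chimera-producing event has a fixed 5' partner gene, so its
        # partner breakends recur at one cytoband
        assert cp.partner_recurrent_at_cytoband


class TestGenePairRecurrence:
    def gg_call(self, sample, toy_ann, five="GA", reverse=False):
        # GA '+' intron 1 at 20 kb; GB '-' intron 1 at 190 kb
        if not reverse:  # GA is the 5' gene
            return make_call(sample, "c1", 20_000, LEFT, "c1", 190_000, LEFT)
        return make_call(sample, "c1", 20_000, RIGHT, "c1", 190_000, RIGHT)

    def cohort_with_calls(self, toy_ann, calls_by_sample):
        samples = sorted(calls_by_sample)
        expr = pd.DataFrame(
            10.0, index=sorted(toy_ann.genes), columns=samples
        )
        return make_cohort(expr, callsets=calls_by_sample)

    def test_two_samples_recurrent_one_not(self, toy_ann):
        cohort = self.cohort_with_calls(toy_ann, {
            "S1": [self.gg_call("S1", toy_ann)],
            "S2": [self.gg_call("S2", toy_ann)],
            "S3": [],
        })
        events = screen_recurrent_gene_gene(cohort, toy_ann)
        assert len(events) == 1
        ev = events[0]
        assert (ev.five_gene, ev.three_gene, ev.oriented) == ("GA", "GB", True)
        assert ev.samples == ("S1", "S2")

    def test_opposite_orientations_are_distinct_keys(self, toy_ann):
        cohort = self.cohort_with_calls(toy_ann, {
            "S1": [self.gg_call("S1", toy_ann)],
            "S2": [self.gg_call("S2", toy_ann, reverse=True)],
        })
        assert screen_recurrent_gene_gene(cohort, toy_ann) == []

    def test_single_sample_not_recurrent(self, toy_ann):
        cohort = self.cohort_with_calls(toy_ann, {"S1": [self.gg_call("S1", toy_ann)]})
        assert screen_recurrent_gene_gene(cohort, toy_ann) == []


class TestNearestGeneScreen:
    @pytest.fixture
    def nearest_ann(self):
        upstream = make_gene("U", "c", "+", [(850_000, 900_000)])
        target = make_gene("T", "c", "+", [(1_000_000, 1_000_200), (1_010_000, 1_010_300)],
                          cds=(1_000_100, 1_010_200))
        return GenomeAnnotation([upstream, target], chrom_sizes={"c": 2_000_000})

    def make(self, nearest_ann, case_positions, case_tpms, n_controls=10):
        samples = [f"cs{i}" for i in range(len(case_positions))] + [
            f"ct{i}" for i in range(n_controls)
        ]
        expr = pd.DataFrame(
            {s: [10.0, 10.0] for s in samples}, index=["T", "U"]
        ).astype(float)
        for s, tpm in zip(samples, case_tpms):
            expr.loc["T", s] = tpm
        callsets = {
            s: [make_call(s, "c", pos, RIGHT, "c", 1_500_000, LEFT)]
            for s, pos in zip(samples, case_positions)
        }
        return make_cohort(expr, callsets=callsets)

    def test_two_upregulated_samples_reported(self, nearest_ann):
        cohort = self.make(nearest_ann, [970_000, 980_000], [60.0, 65.0])
        events = screen_nearest_gene(cohort, nearest_ann)
        assert len(events) == 1
        ev = events[0]
        assert (ev.target_gene, ev.direction) == ("T", "UP")
        assert {s.sample for s in ev.samples} == {"cs0", "cs1"}

    def test_inconsistent_direction_dropped(self, nearest_ann):
        cohort = self.make(nearest_ann, [970_000, 980_000], [60.0, 1.0])
        assert screen_nearest_gene(cohort, nearest_ann) == []

    def test_breakend_beyond_nearest_upstream_gene_not_candidate(self, nearest_ann):
        # one breakend before U's end, one past it: only one qualifies -> no event
        cohort = self.make(nearest_ann, [970_000, 700_000], [60.0, 65.0])
        assert screen_nearest_gene(cohort, nearest_ann) == []

    def test_consistent_downregulation_reported(self, nearest_ann):
        cohort = self.make(nearest_ann, [970_000, 980_000], [0.5, 0.6])
        events = screen_nearest_gene(cohort, nearest_ann)
        assert len(events) == 1 and events[0].direction == "DOWN"
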