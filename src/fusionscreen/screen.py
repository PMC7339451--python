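"""Recurrence screens: gene-gene pair recurrence, the nearest-upstream-gene
scenario, and the distance-ordered split-search screen for gene^UIB/DIB
fusions that upregulate a target gene.

The split search considers, per target gene and tumor type, the samples
carrying a concordant intergenic breakend within a window (4 Mb default)
up- or downstream of the gene. With breakpoints ordered by distance
S_1 <= ... <= S_n, every prefix group {S_1..S_i} is tested for elevated
target expression with the Wilcoxon rank-sum test, and the prefix with the
lowest p-value is selected. Expression (per-case and group-mean fold) and
copy-number (GISTIC high-level amplification) filters then decide whether
the group constitutes a recurrent functional event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chimera import predict_chimera, verify_junction_support
from .classify import (
    DIB,
    GENE_GENE,
    UIB,
    TargetCandidate,
    classify_fusion,
    enumerate_target_candidates,
    _leaves_five_gene_in_sense,
    _walks_into_target,
)
from .cohort import CohortData
from .genome import CytobandMap, GenomeAnnotation

PSEUDOCOUNT = 0.1
CP = "CP"
N_CP = "N_CP"


def _ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p; fully tied data give p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class SplitSearchResult:
    """Outcome of the distance-ordered prefix search for one target gene."""

    target_gene: str
    tumor_type: str
    mode: str
    distances: tuple[int, ...]  # ordered S_1..S_n
    ordered_samples: tuple[str, ...]
    chosen_i: int
    positive_samples: tuple[str, ...]
    p_value: float
    n_splits_tested: int
    empirical_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= self.chosen_i <= len(self.distances):
            raise ValueError("chosen_i out of range")
        if any(a > b for a, b in zip(self.distances, self.distances[1:])):
            raise ValueError("distances must be non-decreasing")


def collect_candidates(
    cohort: CohortData,
    ann: GenomeAnnotation,
    bands: Optional[CytobandMap] = None,
    window: int = 4_000_000,
    concordant_only: bool = True,
) -> dict[tuple[str, str], dict[str, list[TargetCandidate]]]:
    """Index concordant UIB/DIB candidates as (gene, mode) -> sample -> candidates."""
    out: dict[tuple[str, str], dict[str, list[TargetCandidate]]] = {}
    for sample, cs in cohort.callsets.items():
        for call in cs.calls:
            for cand in enumerate_target_candidates(call, ann, bands, window=window):
                if concordant_only and not cand.concordant:
                    continue
                out.setdefault((cand.target_gene, cand.mode), {}).setdefault(sample, []).append(cand)
    return out


def _closest_per_sample(
    per_sample: dict[str, list[TargetCandidate]], samples: Iterable[str]
) -> list[tuple[int, str]]:
    """Each sample contributes its closest qualifying breakpoint; ties on
    distance are broken by sample id for a deterministic ordering."""
    pairs = []
    for s in samples:
        cands = per_sample.get(s)
        if cands:
            pairs.append((min(c.distance for c in cands), s))
    pairs.sort()
    return pairs


def split_search_best_group(
    target_gene: str,
    mode: str,
    cohort: CohortData,
    ann: GenomeAnnotation,
    window: int = 4_000_000,
    tumor_type: Optional[str] = None,
    comparison: str = "rest",
    candidates: Optional[dict[str, list[TargetCandidate]]] = None,
    permutations: int = 0,
    seed: int = 0,
) -> SplitSearchResult:
    """Pick the breakpoint-distance prefix whose samples best separate target expression.

    ``comparison="rest"`` tests each prefix group against all remaining
    samples of the tumor type (the reading that tests upregulation against
    background); ``comparison="literal"`` tests prefix {S_1..S_i} against
    the remaining breakpoint samples {S_(i+1)..S_n} only. With
    ``permutations > 0`` a seeded label-shuffle null of the minimal p fills
    ``empirical_p``.
    """
    if target_gene not in cohort.expr.index:
        raise KeyError(f"target gene {target_gene!r} absent from the expression matrix")
    if comparison not in ("rest", "literal"):
        raise ValueError(f"comparison must be 'rest' or 'literal', got {comparison!r}")
    if tumor_type is None:
        types = cohort.tumor_types
        if len(types) != 1:
            raise ValueError("tumor_type is required for multi-type cohorts")
        tumor_type = types[0]
    tt_samples = cohort.samples_of_type(tumor_type)
    if candidates is None:
        candidates = collect_candidates(cohort, ann, window=window).get((target_gene, mode), {})
    pairs = _closest_per_sample(candidates, tt_samples)
    if not pairs:
        raise ValueError(
            f"no sample of tumor type {tumor_type} has a qualifying {mode} breakpoint "
            f"for {target_gene} within {window} bp"
        )
    distances = tuple(d for d, _ in pairs)
    ordered = tuple(s for _, s in pairs)
    expr = cohort.expr.loc[target_gene, tt_samples].astype(float)

    def min_p_for(values: pd.Series) -> tuple[int, float, int]:
        best_i, best_p, tested = 1, math.nan, 0
        n = len(ordered)
        for i in range(1, n + 1):
            group = list(ordered[:i])
            if comparison == "rest":
                rest = [s for s in tt_samples if s not in set(group)]
            else:
                rest = list(ordered[i:])
            if not rest:
                if comparison == "rest":
                    raise ValueError("control group empty: prefix covers the whole tumor type")
                continue
            p = _ranksum_p(values[group], values[rest])
            tested += 1
            if math.isnan(best_p) or p < best_p:
                best_i, best_p = i, p
        return best_i, best_p, tested

    chosen_i, p_value, tested = min_p_for(expr)

    empirical_p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        vals = expr.to_numpy(copy=True)
        for _ in range(permutations):
            rng.shuffle(vals)
            perm = pd.Series(vals, index=tt_samples)
            _, p_perm, _ = min_p_for(perm)
            if not math.isnan(p_perm) and (math.isnan(p_value) or p_perm <= p_value):
                hits += 1
        empirical_p = (hits + 1) / (permutations + 1)

    return SplitSearchResult(
        target_gene=target_gene,
        tumor_type=tumor_type,
        mode=mode,
        distances=distances,
        ordered_samples=ordered,
        chosen_i=chosen_i,
        positive_samples=ordered[:chosen_i],
        p_value=p_value,
        n_splits_tested=tested,
        empirical_p=empirical_p,
    )


@dataclass(frozen=True)
class FilterOutcome:
    """Expression/copy-number filtering of a split-search positive group."""

    kept_samples: tuple[str, ...]
    case_folds: dict
    removed_amplified: tuple[str, ...]
    removed_low_fold: tuple[str, ...]
    group_mean_fold: float
    control_samples: tuple[str, ...]
    passed: bool


def apply_expression_filters(
    result: SplitSearchResult,
    cohort: CohortData,
    min_case_fold: float = 4.0,
    min_mean_fold: float = 5.0,
    pseudocount: float = PSEUDOCOUNT,
) -> FilterOutcome:
    """Per-case and group-mean fold filters with GISTIC-amplification exclusion.

    Samples whose target-gene copy-number score is 2 (high-level
    amplification) are excluded before any fold computation — from the
    positive group and from the control background alike. Per-case fold is
    TPM over the control median; cases below ``min_case_fold`` are flagged
    out; the event passes when the surviving group's mean is more than
    ``min_mean_fold`` times the control mean. A pseudocount guards zeros.
    """
    gene = result.target_gene
    tt_samples = cohort.samples_of_type(result.tumor_type)
    if gene in cohort.cna.index:
        cna_row = cohort.cna.loc[gene, tt_samples]
        amplified = {s for s in tt_samples if cna_row[s] == 2}
    else:
        amplified = set()
    positives = [s for s in result.positive_samples if s not in amplified]
    removed_amp = tuple(s for s in result.positive_samples if s in amplified)
    control = [s for s in tt_samples if s not in set(result.positive_samples) and s not in amplified]
    if not control:
        raise ValueError(f"control group empty for {gene} in {result.tumor_type}")
    expr = cohort.expr.loc[gene].astype(float)
    control_median = float(expr[control].median())
    case_folds = {
        s: (expr[s] + pseudocount) / (control_median + pseudocount) for s in positives
    }
    kept = [s for s in positives if case_folds[s] > min_case_fold]
    removed_low = tuple(s for s in positives if s not in set(kept))
    if kept:
        group_mean_fold = float(
            (expr[kept].mean() + pseudocount) / (expr[control].mean() + pseudocount)
        )
    else:
        group_mean_fold = math.nan
    passed = bool(kept) and group_mean_fold > min_mean_fold
    return FilterOutcome(
        kept_samples=tuple(kept),
        case_folds=case_folds,
        removed_amplified=removed_amp,
        removed_low_fold=removed_low,
        group_mean_fold=group_mean_fold,
        control_samples=tuple(control),
        passed=passed,
    )


@dataclass(frozen=True)
class SampleEvidence:
    sample: str
    distance: int
    partner_desc: str
    partner_band: Optional[str]
    fold: float
    chimera_verified: bool


@dataclass(frozen=True)
class RecurrentEvent:
    """A recurrent gene^UIB/DIB event passing all screen criteria."""

    target_gene: str
    tumor_type: str
    mode: str
    samples: tuple[SampleEvidence, ...]
    group_mean_fold: float
    p_value: float
    cp_label: str
    partner_recurrent_at_cytoband: bool
    dist_mean: float
    dist_max: int
    frac_gt_1mb: float
    frac_gt_2mb: float
    n_splits_tested: int
    empirical_p: Optional[float] = None
    direction: str = "UP"

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _partner_breakend(cand: TargetCandidate, ann: GenomeAnnotation):
    """The breakend of the candidate's call on the partner (non-target) side."""
    g = ann[cand.target_gene]
    for bnd, other in ((cand.call.bnd1, cand.call.bnd2), (cand.call.bnd2, cand.call.bnd1)):
        if bnd.chrom != g.chrom:
            continue
        d = g.upstream_distance(bnd.pos) if cand.mode == UIB else g.downstream_distance(bnd.pos)
        if d == cand.distance:
            return other
    return cand.call.bnd2


def screen_uib_dib(
    cohort: CohortData,
    ann: GenomeAnnotation,
    bands: Optional[CytobandMap] = None,
    min_samples: int = 4,
    window: int = 4_000_000,
    modes: Sequence[str] = (UIB, DIB),
    min_case_fold: float = 4.0,
    min_mean_fold: float = 5.0,
    min_junction_reads: int = 3,
    chimera_window: int = 100_000,
    comparison: str = "rest",
    permutations: int = 0,
    seed: int = 0,
    p_threshold: Optional[float] = None,
) -> list[RecurrentEvent]:
    """The 4-Mb split-search screen for recurrent target-upregulating fusions.

    For every gene, tumor type and mode, the split search selects the best
    breakpoint prefix group, the expression/copy-number filters prune it,
    and groups retaining at least ``min_samples`` samples are emitted as
    events. An event is labelled CP when at least one positive sample's
    fusion yields a chimera prediction for the target that is verified by
    RNA junction reads, N_CP otherwise. Events are sorted by p-value; an
    optional ``p_threshold`` restricts the output (by default all events
    passing the fold filters are reported).
    """
    cand_index = collect_candidates(cohort, ann, bands, window=window)
    events: list[RecurrentEvent] = []
    for (gene, mode) in sorted(cand_index):
        if mode not in modes:
            continue
        per_sample = cand_index[(gene, mode)]
        for tumor_type in cohort.tumor_types:
            tt_samples = cohort.samples_of_type(tumor_type)
            n_cand = sum(1 for s in tt_samples if s in per_sample)
            if n_cand < min_samples:
                continue
            result = split_search_best_group(
                gene, mode, cohort, ann,
                window=window, tumor_type=tumor_type, comparison=comparison,
                candidates=per_sample, permutations=permutations, seed=seed,
            )
            outcome = apply_expression_filters(
                result, cohort, min_case_fold=min_case_fold, min_mean_fold=min_mean_fold
            )
            if not outcome.passed or len(outcome.kept_samples) < min_samples:
                continue
            if p_threshold is not None and not (result.p_value < p_threshold):
                continue
            evidence = []
            partner_bands = []
            any_verified = False
            for s in outcome.kept_samples:
                cand = min(per_sample[s], key=lambda c: c.distance)
                verified = False
                if mode == UIB and s in cohort.junctions:
                    pred = predict_chimera(cand.call, ann, chimera_window=chimera_window)
                    if pred is not None and pred.three_gene == gene:
                        verified, _ = verify_junction_support(
                            pred, cohort.junctions[s], min_reads=min_junction_reads
                        )
                band = None
                if bands is not None:
                    p_bnd = _partner_breakend(cand, ann)
                    band = f"{p_bnd.chrom}:{bands.cytoband_of(p_bnd.chrom, p_bnd.pos)}"
                    partner_bands.append(band)
                evidence.append(
                    SampleEvidence(
                        sample=s,
                        distance=cand.distance,
                        partner_desc=cand.partner_desc,
                        partner_band=band,
                        fold=float(outcome.case_folds[s]),
                        chimera_verified=verified,
                    )
                )
                any_verified = any_verified or verified
            dists = np.array([e.distance for e in evidence], dtype=float)
            band_counts = pd.Series(partner_bands).value_counts() if partner_bands else pd.Series(dtype=int)
            events.append(
                RecurrentEvent(
                    target_gene=gene,
                    tumor_type=tumor_type,
                    mode=mode,
                    samples=tuple(evidence),
                    group_mean_fold=outcome.group_mean_fold,
                    p_value=result.p_value,
                    cp_label=CP if any_verified else N_CP,
                    partner_recurrent_at_cytoband=bool((band_counts >= 2).any()),
                    dist_mean=float(dists.mean()),
                    dist_max=int(dists.max()),
                    frac_gt_1mb=float((dists > 1_000_000).mean()),
                    frac_gt_2mb=float((dists > 2_000_000).mean()),
                    n_splits_tested=result.n_splits_tested,
                    empirical_p=result.empirical_p,
                )
            )
    events.sort(key=lambda e: (math.isnan(e.p_value), e.p_value, e.target_gene, e.mode))
    return events


@dataclass(frozen=True)
class GenePairEvent:
    """A recurrent gene-gene fusion pair."""

    five_gene: str
    three_gene: str
    oriented: bool  # orientation-aware key when concordance was determinable
    samples: tuple[str, ...]


def screen_recurrent_gene_gene(cohort: CohortData, ann: GenomeAnnotation) -> list[GenePairEvent]:
    """Gene pairs fused in at least two distinct samples.

    Pairs are keyed by (5' gene, 3' gene) when the junction orientation
    determines which gene donates its promoter; otherwise by the unordered
    pair.
    """
    groups: dict[tuple, set[str]] = {}
    for sample, cs in cohort.callsets.items():
        for call in cs.calls:
            if classify_fusion(call, ann) != GENE_GENE:
                continue
            hits = []
            for bnd in call.breakends:
                anno = ann.annotate_position(bnd.chrom, bnd.pos, flank_window=1)
                hits.append((ann[anno.hit_genes[0][0]], bnd))
            (g1, b1), (g2, b2) = hits
            if g1.gene_id == g2.gene_id:
                continue
            key = None
            for (ga, ba), (gb, bb) in (((g1, b1), (g2, b2)), ((g2, b2), (g1, b1))):
                if _leaves_five_gene_in_sense(ba, ga) and _walks_into_target(bb, gb):
                    key = (ga.gene_id, gb.gene_id, True)
                    break
            if key is None:
                key = (*sorted([g1.gene_id, g2.gene_id]), False)
            groups.setdefault(key, set()).add(sample)
    events = [
        GenePairEvent(five_gene=a, three_gene=b, oriented=oriented, samples=tuple(sorted(samples)))
        for (a, b, oriented), samples in groups.items()
        if len(samples) >= 2
    ]
    events.sort(key=lambda e: (-len(e.samples), e.five_gene, e.three_gene))
    return events


def screen_nearest_gene(
    cohort: CohortData,
    ann: GenomeAnnotation,
    bands: Optional[CytobandMap] = None,
    min_samples: int = 2,
    p_threshold: float = 0.05,
    pseudocount: float = PSEUDOCOUNT,
) -> list[RecurrentEvent]:
    """Initial-scenario screen: breakpoints before the nearest upstream gene.

    Candidate breakends are restricted to the interval between a target's
    transcription start and its nearest upstream neighbour gene. Groups of
    at least ``min_samples`` samples whose target expression lies
    consistently on one side of the control median are reported as up- or
    downregulating when the two-sided rank-sum test against the remaining
    tumor-type samples reaches ``p_threshold``.
    """
    max_window = max(ann.chrom_sizes.values())
    cand_index = collect_candidates(cohort, ann, bands, window=max_window)
    events: list[RecurrentEvent] = []
    for (gene, mode), per_sample in sorted(cand_index.items()):
        if mode != UIB:
            continue
        gap = ann.nearest_upstream_gene_gap(gene)
        if gene not in cohort.expr.index:
            continue
        for tumor_type in cohort.tumor_types:
            tt_samples = cohort.samples_of_type(tumor_type)
            qualified = {}
            for s in tt_samples:
                cands = [
                    c for c in per_sample.get(s, [])
                    if gap is None or c.distance < gap
                ]
                if cands:
                    qualified[s] = min(cands, key=lambda c: c.distance)
            if len(qualified) < min_samples:
                continue
            pos = sorted(qualified)
            rest = [s for s in tt_samples if s not in qualified]
            if not rest:
                continue
            expr = cohort.expr.loc[gene].astype(float)
            ctrl_median = float(expr[rest].median())
            case_vals = expr[pos]
            if (case_vals > ctrl_median).all():
                direction = "UP"
            elif (case_vals < ctrl_median).all():
                direction = "DOWN"
            else:
                continue
            p = _ranksum_p(case_vals, expr[rest])
            if not p < p_threshold:
                continue
            dists = np.array([qualified[s].distance for s in pos], dtype=float)
            evidence = tuple(
                SampleEvidence(
                    sample=s,
                    distance=qualified[s].distance,
                    partner_desc=qualified[s].partner_desc,
                    partner_band=None,
                    fold=float((expr[s] + pseudocount) / (ctrl_median + pseudocount)),
                    chimera_verified=False,
                )
                for s in pos
            )
            events.append(
                RecurrentEvent(
                    target_gene=gene,
                    tumor_type=tumor_type,
                    mode=UIB,
                    samples=evidence,
                    group_mean_fold=float(
                        (expr[pos].mean() + pseudocount) / (expr[rest].mean() + pseudocount)
                    ),
                    p_value=p,
                    cp_label=N_CP,
                    partner_recurrent_at_cytoband=False,
                    dist_mean=float(dists.mean()),
                    dist_max=int(dists.max()),
                    frac_gt_1mb=float((dists > 1_000_000).mean()),
                    frac_gt_2mb=float((dists > 2_000_000).mean()),
                    n_splits_tested=0,
                    direction=direction,
                )
            )
    events.sort(key=lambda e: (e.p_value, e.target_gene))
    return events


def events_to_frame(events: Sequence[RecurrentEvent]) -> pd.DataFrame:
    """One row per event, sample details joined for TSV output."""
    rows = []
    for e in events:
        rows.append(
            {
                "target_gene": e.target_gene,
                "tumor_type": e.tumor_type,
                "mode": e.mode,
                "direction": e.direction,
                "n_samples": e.n_samples,
                "samples": ",".join(s.sample for s in e.samples),
                "distances_bp": ",".join(str(s.distance) for s in e.samples),
                "case_folds": ",".join(f"{s.fold:.3g}" for s in e.samples),
                "group_mean_fold": e.group_mean_fold,
                "p_value": e.p_value,
                "empirical_p": e.empirical_p if e.empirical_p is not None else "",
                "cp_label": e.cp_label,
                "partner_recurrent_at_cytoband": e.partner_recurrent_at_cytoband,
                "dist_mean_bp": e.dist_mean,
                "dist_max_bp": e.dist_max,
                "frac_gt_1mb": e.frac_gt_1mb,
                "frac_gt_2mb": e.frac_gt_2mb,
                "n_splits_tested": e.n_splits_tested,
            }
        )
    return pd.DataFrame(rows)


def sample_evidence_frame(events: Sequence[RecurrentEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        for s in e.samples:
            rows.append(
                {
                    "target_gene": e.target_gene,
                    "tumor_type": e.tumor_type,
                    "mode": e.mode,
                    "sample": s.sample,
                    "distance_bp": s.distance,
                    "partner": s.partner_desc,
                    "partner_band": s.partner_band or "",
                    "fold_vs_control_median": s.fold,
                    "chimera_verified": s.chimera_verified,
                }
            )
    return pd.DataFrame(rows)
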