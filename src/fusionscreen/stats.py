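"""Supporting statistics: proportion test, Fisher enrichment, pairwise
mutual exclusivity, group differential expression and the correlation
screen with Benjamini-Hochberg adjustment."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

PSEUDOCOUNT = 0.1


def proportion_test(k: int, n: int, p0: float, method: str = "exact") -> float:
    """Two-sided test of an observed count ``k`` out of ``n`` against proportion ``p0``.

    ``method="exact"`` is the exact binomial test; ``method="normal"`` the
    normal approximation z-test. Both are deterministic.
    """
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if method == "exact":
        return sps.binomtest(k, n, p0, alternative="two-sided").pvalue
    if method == "normal":
        z = (k - n * p0) / np.sqrt(n * p0 * (1.0 - p0))
        return float(2.0 * sps.norm.sf(abs(z)))
    raise ValueError(f"method must be 'exact' or 'normal', got {method!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    overlap: int
    set_a_size: int
    set_b_size: int
    universe_size: int
    odds_ratio: float
    p_value: float


def fisher_enrichment(targets: set, reference: set, universe: set) -> EnrichmentResult:
    """One-sided Fisher exact test for enrichment of ``targets`` in ``reference``."""
    targets, reference, universe = set(targets), set(reference), set(universe)
    if not targets <= universe or not reference <= universe:
        raise ValueError("targets and reference must be subsets of the universe")
    a = len(targets & reference)
    b = len(targets - reference)
    c = len(reference - targets)
    d = len(universe) - a - b - c
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(
        overlap=a,
        set_a_size=len(targets),
        set_b_size=len(reference),
        universe_size=len(universe),
        odds_ratio=float(odds),
        p_value=float(p),
    )


def mutual_exclusivity(events: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Fisher exact tests for exclusivity and co-occurrence.

    ``events`` is a binary sample x alteration matrix. For each alteration
    pair the 2x2 co-occurrence table is tested in both one-sided
    directions. Alterations that are constant across samples yield NA.
    This is a deliberately simple pairwise substitute for dedicated
    exclusivity machinery, and output columns say so.
    """
    if events.shape[1] < 2 or events.shape[0] < 2:
        raise ValueError("mutual_exclusivity needs >=2 alterations and >=2 samples")
    mat = events.astype(bool)
    rows = []
    for a, b in combinations(mat.columns, 2):
        va, vb = mat[a].to_numpy(), mat[b].to_numpy()
        if va.all() or (~va).all() or vb.all() or (~vb).all():
            rows.append((a, b, np.nan, np.nan, np.nan, True))
            continue
        both = int((va & vb).sum())
        only_a = int((va & ~vb).sum())
        only_b = int((~va & vb).sum())
        neither = int((~va & ~vb).sum())
        table = [[both, only_a], [only_b, neither]]
        _, p_co = sps.fisher_exact(table, alternative="greater")
        _, p_ex = sps.fisher_exact(table, alternative="less")
        rows.append((a, b, both, float(p_ex), float(p_co), False))
    return pd.DataFrame(
        rows,
        columns=["alt_a", "alt_b", "n_cooccur", "p_exclusive_fisher", "p_cooccur_fisher", "constant_na"],
    )


def group_de_test(
    expr: pd.DataFrame,
    positive: Iterable[str],
    negative: Iterable[str],
    method: str = "t",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene two-sided group comparison plus group-mean fold change.

    ``expr`` is a gene x sample matrix; ``method`` is ``"t"`` (two-sample t
    test, Welch) or ``"ranksum"`` (Wilcoxon rank-sum). Fold is
    (mean_pos + pc) / (mean_neg + pc).
    """
    positive, negative = list(positive), list(negative)
    if method not in ("t", "ranksum"):
        raise ValueError(f"method must be 't' or 'ranksum', got {method!r}")
    min_n = 2 if method == "t" else 1
    if len(positive) < min_n or len(negative) < min_n:
        raise ValueError(
            f"method {method!r} needs >= {min_n} samples per group for all "
            f"{expr.shape[0]} genes (got {len(positive)} vs {len(negative)})"
        )
    xs = expr[positive].to_numpy(dtype=float)
    ys = expr[negative].to_numpy(dtype=float)
    if method == "t":
        stat, p = sps.ttest_ind(xs, ys, axis=1, equal_var=False)
    else:
        stat, p = sps.mannwhitneyu(xs, ys, axis=1, alternative="two-sided")
    fold = (xs.mean(axis=1) + pseudocount) / (ys.mean(axis=1) + pseudocount)
    return pd.DataFrame(
        {"statistic": stat, "p_value": p, "fold": fold}, index=expr.index
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


@dataclass(frozen=True)
class CorrelationHit:
    gene_id: str
    r: float
    p_value: float
    q_value: float


def correlation_screen(
    expr: pd.DataFrame,
    target_gene: str,
    q_threshold: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Genes whose expression correlates with ``target_gene`` across samples.

    Pearson r per gene against the target profile; the p-value comes from
    the t-transform of r with n-2 degrees of freedom; q-values are BH over
    all tested genes. The target itself is excluded; zero-variance genes
    are skipped (logged). Returns hits with q < ``q_threshold`` unless
    ``return_all``.
    """
    if target_gene not in expr.index:
        raise KeyError(f"target gene {target_gene!r} absent from the expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("correlation_screen needs >= 3 samples")
    y = expr.loc[target_gene].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError(f"target gene {target_gene!r} has zero variance")
    others = expr.drop(index=target_gene)
    x = others.to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    n_skipped = int((~keep).sum())
    if n_skipped:
        log.info("correlation_screen: skipped %d zero-variance genes", n_skipped)
    x = x[keep]
    genes = others.index[keep]
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    r = (xc @ yc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(yc))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    q = bh_adjust(p)
    out = pd.DataFrame({"r": r, "p_value": p, "q_value": q}, index=genes)
    out = out.sort_values(["q_value", "p_value"])
    return out if return_all else out[out["q_value"] < q_threshold]
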