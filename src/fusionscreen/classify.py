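"""Breakpoint-level fusion classification and UIB/DIB target-candidate enumeration.

A DNA fusion junction is classified by whether its two breakends fall in
gene bodies (GENE_GENE), exactly one does (GENE_INTERGENIC), or neither
does (INTERGENIC_INTERGENIC). For each intergenic breakend, genes whose
strand-aware upstream (UIB) or downstream (DIB) region contains the
breakend within a window — 4 Mb by default — are candidate targets for
regulatory dysregulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from . import stats as _stats
from .genome import (
    DOWNSTREAM,
    GENIC,
    UPSTREAM,
    CytobandMap,
    GeneModel,
    GenomeAnnotation,
)
from .svio import LEFT, RIGHT, Breakend, CallSet, SvCall

GENE_GENE = "GENE_GENE"
GENE_INTERGENIC = "GENE_INTERGENIC"
INTERGENIC_INTERGENIC = "INTERGENIC_INTERGENIC"
FUSION_CLASSES = (GENE_GENE, GENE_INTERGENIC, INTERGENIC_INTERGENIC)

UIB = "UIB"
DIB = "DIB"


@dataclass(frozen=True)
class TargetCandidate:
    """A gene that an intergenic breakend may dysregulate.

    ``mode`` is UIB when the breakend lies strand-aware upstream of the
    target, DIB when downstream; ``concordant`` records whether the
    junction retains the intact target gene joined to the partner segment.
    ``partner_desc`` summarizes the other breakend (genic element or
    cytoband).
    """

    call: SvCall
    target_gene: str
    mode: str
    distance: int
    concordant: bool
    partner_desc: str

    def __post_init__(self) -> None:
        if self.mode not in (UIB, DIB):
            raise ValueError(f"mode must be UIB or DIB, got {self.mode!r}")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def classify_fusion(call: SvCall, ann: GenomeAnnotation) -> str:
    """GENE_GENE / GENE_INTERGENIC / INTERGENIC_INTERGENIC by breakend annotation."""
    n_genic = sum(
        ann.annotate_position(b.chrom, b.pos, flank_window=1).is_genic for b in call.breakends
    )
    return {2: GENE_GENE, 1: GENE_INTERGENIC, 0: INTERGENIC_INTERGENIC}[n_genic]


def _retains_gene(bnd: Breakend, gene: GeneModel) -> bool:
    """True when the retained segment at an intergenic breakend contains the gene."""
    if bnd.chrom != gene.chrom:
        return False
    if bnd.pos < gene.tx_start:  # gene at higher coordinates
        return bnd.side == RIGHT
    if bnd.pos >= gene.tx_end:  # gene at lower coordinates
        return bnd.side == LEFT
    raise ValueError(f"breakend {bnd.chrom}:{bnd.pos} lies inside gene {gene.gene_id}")


def _walks_into_target(bnd: Breakend, target: GeneModel) -> bool:
    """True when walking across the junction into the retained target-side segment
    proceeds in the target's transcriptional direction (side RIGHT walks toward
    higher coordinates)."""
    return (bnd.side == RIGHT) == (target.strand == "+")


def _leaves_five_gene_in_sense(bnd: Breakend, five_gene: GeneModel) -> bool:
    """True when walking from inside the retained 5'-gene segment toward the
    junction runs in the 5' gene's sense direction (side LEFT approaches the
    junction walking toward higher coordinates)."""
    return (bnd.side == LEFT) == (five_gene.strand == "+")


def _target_side_breakend(call: SvCall, target: GeneModel) -> Breakend:
    """The breakend adjacent to ``target``: inside it, or in its strand-aware
    upstream region; with two qualifying breakends the closer one wins."""
    candidates = []
    for b in call.breakends:
        if b.chrom != target.chrom:
            continue
        if target.contains(b.pos):
            candidates.append((0, b))
        else:
            d = target.upstream_distance(b.pos)
            if d is not None:
                candidates.append((d, b))
    if not candidates:
        raise ValueError(
            f"target {target.gene_id} is not adjacent to either breakend of the call"
        )
    return min(candidates, key=lambda t: t[0])[1]


def is_transcription_concordant(
    call: SvCall, five_gene: Optional[GeneModel], target: GeneModel
) -> bool:
    """Whether transcription initiated on the partner side runs into the target.

    The derived junction is walked from the retained segment at the partner
    breakend into the retained segment at the target-side breakend; the
    fusion is concordant when that walk direction equals the target's
    transcriptional direction and, when ``five_gene`` is given, the walk
    additionally leaves the 5' gene in its sense direction — i.e. the two
    genes are juxtaposed on one transcriptional strand.
    """
    t_bnd = _target_side_breakend(call, target)
    if not _walks_into_target(t_bnd, target):
        return False
    if five_gene is not None:
        p_bnd = call.bnd2 if t_bnd is call.bnd1 else call.bnd1
        if not _leaves_five_gene_in_sense(p_bnd, five_gene):
            return False
    return True


def describe_breakend(
    bnd: Breakend, ann: GenomeAnnotation, bands: Optional[CytobandMap] = None
) -> str:
    """Compact partner description: genic element or cytoband/position."""
    a = ann.annotate_position(bnd.chrom, bnd.pos, flank_window=1)
    if a.is_genic:
        gid, elem, idx = a.hit_genes[0]
        return f"GENIC:{gid}:{elem.lower()}{idx}"
    if bands is not None:
        return f"INTERGENIC:{bnd.chrom}:{bands.cytoband_of(bnd.chrom, bnd.pos)}"
    return f"INTERGENIC:{bnd.chrom}:{bnd.pos}"


def enumerate_target_candidates(
    call: SvCall,
    ann: GenomeAnnotation,
    bands: Optional[CytobandMap] = None,
    window: int = 4_000_000,
) -> list[TargetCandidate]:
    """All UIB/DIB target candidates of a call's intergenic breakends.

    One candidate per (intergenic breakend, gene within ``window`` in the
    UIB or DIB relation), flagged for orientation concordance and sorted by
    distance. Discordant candidates are emitted too, so that they remain
    inspectable; the recurrence screen consumes concordant ones only.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out: list[TargetCandidate] = []
    for bnd, other in ((call.bnd1, call.bnd2), (call.bnd2, call.bnd1)):
        if ann.annotate_position(bnd.chrom, bnd.pos, flank_window=1).is_genic:
            continue
        partner = describe_breakend(other, ann, bands)
        for relation, mode in ((UPSTREAM, UIB), (DOWNSTREAM, DIB)):
            for gid, dist in ann.genes_within_window(bnd.chrom, bnd.pos, window, relation):
                out.append(
                    TargetCandidate(
                        call=call,
                        target_gene=gid,
                        mode=mode,
                        distance=dist,
                        concordant=_retains_gene(bnd, ann[gid]),
                        partner_desc=partner,
                    )
                )
    out.sort(key=lambda c: (c.distance, c.target_gene, c.mode))
    return out


@dataclass(frozen=True)
class ClassProportions:
    counts: dict
    fractions: dict
    n_total: int
    genic_fraction: float
    expected_gene_gene: float
    p_value: float


def class_proportions(
    callsets: Iterable[CallSet], ann: GenomeAnnotation, test_method: str = "normal"
) -> ClassProportions:
    """Observed class counts versus a uniform-breakpoint null.

    Under breakpoints falling uniformly over the genome, both ends land in
    gene bodies with probability f^2 where f is the genic fraction, so the
    expected GENE_GENE count is N*f^2; a one-proportion test of the observed
    count against f^2 quantifies over-representation.
    """
    counts = {k: 0 for k in FUSION_CLASSES}
    for cs in callsets:
        for call in cs.calls:
            counts[classify_fusion(call, ann)] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("class_proportions needs at least one call")
    f = ann.genic_fraction()
    p0 = f * f
    if 0.0 < p0 < 1.0:
        p_value = _stats.proportion_test(counts[GENE_GENE], n, p0, method=test_method)
    else:  # degenerate fully-genic / gene-free genome: the null is a point mass
        p_value = float("nan")
    return ClassProportions(
        counts=counts,
        fractions={k: v / n for k, v in counts.items()},
        n_total=n,
        genic_fraction=f,
        expected_gene_gene=n * p0,
        p_value=p_value,
    )
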