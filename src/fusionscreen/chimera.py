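"""Chimeric-mRNA prediction for gene-gene and gene-intergenic fusions.

The splicing model: when an SV juxtaposes two genes on one transcriptional
strand, with the 5' gene (A) broken in an intron and the 3' gene (B)
either broken in an intron (gene-gene) or intact downstream of an
intergenic breakend in its upstream region (gene-intergenic), the
transcript runs from A's promoter across the junction into B. The whole
segment between A's last retained exon and the first usable B exon is
spliced out as one intron. In the intergenic (UIB) mode B's first exon is
skipped — lacking an upstream splice acceptor signal, it cannot terminate
the hybrid intron — so the junction joins A's last retained exon to B's
exon 2.

Donor/acceptor coordinates are the 0-based genomic positions of the
terminal exonic bases (the last base of the donor exon, the first base of
the acceptor exon, in transcript orientation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .classify import (
    _leaves_five_gene_in_sense,
    _retains_gene,
    _walks_into_target,
)
from .genome import EXON, INTRON, GeneModel, GenomeAnnotation
from .svio import Breakend, SvCall

log = logging.getLogger(__name__)

FIVE_UTR_ONLY = "FIVE_UTR_ONLY"
THREE_EXON1_UTR_ORF_INTACT = "THREE_EXON1_UTR_ORF_INTACT"
IN_FRAME = "IN_FRAME"
OUT_OF_FRAME = "OUT_OF_FRAME"
NON_CODING = "NON_CODING"
FRAME_STATUSES = (
    FIVE_UTR_ONLY,
    THREE_EXON1_UTR_ORF_INTACT,
    IN_FRAME,
    OUT_OF_FRAME,
    NON_CODING,
)


@dataclass(frozen=True)
class ChimeraPrediction:
    """A predicted spliced fusion junction.

    ``five_last_exon`` is the last retained exon of the 5' gene (1-based,
    transcription order); ``three_first_exon`` the first joined exon of the
    3' gene (always 2 in UIB mode). ``uib_distance`` is 0 for the gene-gene
    mode.
    """

    five_gene: str
    five_last_exon: int
    three_gene: str
    three_first_exon: int
    donor_chrom: str
    donor_pos: int
    acceptor_chrom: str
    acceptor_pos: int
    uib_distance: int = 0
    frame_status: Optional[str] = None

    def __post_init__(self) -> None:
        if self.five_last_exon < 1:
            raise ValueError("five_last_exon must be >= 1")
        if self.three_first_exon < 2:
            raise ValueError("three_first_exon must be >= 2 (exon 1 is never the acceptor)")


@dataclass
class JunctionEvidence:
    """Per-sample spliced-junction read support from RNA-seq."""

    sample_id: str
    records: list[tuple[str, int, str, int, int]] = field(default_factory=list)
    # (chrom_donor, donor_pos, chrom_acceptor, acceptor_pos, read_count)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec[4] < 1:
                raise ValueError("junction read_count must be >= 1")


def _donor_pos(gene: GeneModel, exon_index: int) -> int:
    """Genomic position of the 3'-most base of the given exon."""
    s, e = gene.exons[exon_index - 1]
    return e - 1 if gene.strand == "+" else s


def _acceptor_pos(gene: GeneModel, exon_index: int) -> int:
    """Genomic position of the 5'-most base of the given exon."""
    s, e = gene.exons[exon_index - 1]
    return s if gene.strand == "+" else e - 1


def predict_chimera(
    call: SvCall,
    ann: GenomeAnnotation,
    chimera_window: int = 100_000,
) -> Optional[ChimeraPrediction]:
    """Predict the chimeric junction produced by a fusion call, or None.

    Gene-intergenic (UIB) mode: one breakend in an intron of the 5' gene,
    the other intergenic within ``chimera_window`` upstream of the 3' gene,
    with concordant orientation; the junction joins the 5' gene's last exon
    before its breakpoint to the 3' gene's second exon. Gene-gene mode:
    both breakends intronic and concordant; the acceptor is the 3' gene's
    first exon after its breakpoint. Exonic breakpoints and discordant
    orientations return None (the model is undefined there; logged).
    """
    annos = [ann.annotate_position(b.chrom, b.pos) for b in call.breakends]
    genic = [a.is_genic for a in annos]

    if all(genic):
        return _predict_gene_gene(call, ann, annos)
    if not any(genic):
        return None
    g_idx = 0 if genic[0] else 1
    return _predict_uib(call, ann, annos, g_idx, chimera_window)


def _intron_hit(anno, ann: GenomeAnnotation, bnd: Breakend):
    """(gene, intron_index) when the breakend lies in an intron of exactly one gene."""
    intronic = [(g, i) for g, e, i in anno.hit_genes if e == INTRON]
    exonic = [g for g, e, _ in anno.hit_genes if e == EXON]
    if exonic:
        log.info("no chimera: breakend %s:%d is exonic in %s", bnd.chrom, bnd.pos, exonic)
        return None
    if len(intronic) != 1:
        return None
    gid, idx = intronic[0]
    return ann[gid], idx


def _predict_gene_gene(call, ann, annos) -> Optional[ChimeraPrediction]:
    hit1 = _intron_hit(annos[0], ann, call.bnd1)
    hit2 = _intron_hit(annos[1], ann, call.bnd2)
    if hit1 is None or hit2 is None:
        return None
    # the 5' gene is the one whose breakend retains its 5' portion in sense
    # orientation; the 3' gene's breakend must walk into its retained 3' part
    for (a_gene, a_intron, a_bnd), (b_gene, b_intron, b_bnd) in (
        ((*hit1, call.bnd1), (*hit2, call.bnd2)),
        ((*hit2, call.bnd2), (*hit1, call.bnd1)),
    ):
        if _leaves_five_gene_in_sense(a_bnd, a_gene) and _walks_into_target(b_bnd, b_gene):
            if b_intron + 1 > b_gene.n_exons:
                return None
            return ChimeraPrediction(
                five_gene=a_gene.gene_id,
                five_last_exon=a_intron,
                three_gene=b_gene.gene_id,
                three_first_exon=b_intron + 1,
                donor_chrom=a_gene.chrom,
                donor_pos=_donor_pos(a_gene, a_intron),
                acceptor_chrom=b_gene.chrom,
                acceptor_pos=_acceptor_pos(b_gene, b_intron + 1),
                uib_distance=0,
            )
    log.info("no chimera: gene-gene call orientation is discordant")
    return None


def _predict_uib(call, ann, annos, g_idx, chimera_window) -> Optional[ChimeraPrediction]:
    a_bnd = call.breakends[g_idx]
    i_bnd = call.breakends[1 - g_idx]
    hit = _intron_hit(annos[g_idx], ann, a_bnd)
    if hit is None:
        return None
    a_gene, a_intron = hit
    if not _leaves_five_gene_in_sense(a_bnd, a_gene):
        log.info("no chimera: 5' gene %s oriented antisense to the junction", a_gene.gene_id)
        return None
    # candidate 3' genes: breakend upstream within the chimera window, gene
    # retained on the junction side, transcription running into it
    best = None
    for gid, dist in ann.genes_within_window(i_bnd.chrom, i_bnd.pos, chimera_window, "UPSTREAM"):
        b_gene = ann[gid]
        if b_gene.n_exons < 2:
            continue
        if not (_retains_gene(i_bnd, b_gene) and _walks_into_target(i_bnd, b_gene)):
            continue
        if best is None or dist < best[1]:
            best = (b_gene, dist)
    if best is None:
        return None
    b_gene, dist = best
    return ChimeraPrediction(
        five_gene=a_gene.gene_id,
        five_last_exon=a_intron,
        three_gene=b_gene.gene_id,
        three_first_exon=2,
        donor_chrom=a_gene.chrom,
        donor_pos=_donor_pos(a_gene, a_intron),
        acceptor_chrom=b_gene.chrom,
        acceptor_pos=_acceptor_pos(b_gene, 2),
        uib_distance=dist,
    )


def frame_status(pred: ChimeraPrediction, ann: GenomeAnnotation) -> str:
    """Coding consequence of a predicted junction.

    NON_CODING when either gene lacks a CDS. FIVE_UTR_ONLY when the 5'
    gene's retained exons end before its CDS start — the transcript borrows
    only the 5' partner's promoter and UTR, and the protein is the 3'
    gene's, not chimeric. THREE_EXON1_UTR_ORF_INTACT when the 3' gene's
    skipped prefix is entirely untranslated, leaving its ORF intact from
    the joined exon on. Otherwise the join is IN_FRAME iff the 5' retained
    coding length and the 3' skipped coding prefix agree mod 3.
    """
    a = ann[pred.five_gene]
    b = ann[pred.three_gene]
    if pred.five_last_exon > a.n_exons or pred.three_first_exon > b.n_exons:
        raise ValueError("prediction does not match the annotation's exon counts")
    if not a.is_coding or not b.is_coding:
        return NON_CODING
    a_coding = a.coding_prefix_len(pred.five_last_exon)
    if a_coding == 0:
        return FIVE_UTR_ONLY
    b_skipped = b.coding_prefix_len(pred.three_first_exon - 1)
    if b_skipped == 0 and b.coding_prefix_len(b.n_exons) > 0:
        return THREE_EXON1_UTR_ORF_INTACT
    return IN_FRAME if a_coding % 3 == b_skipped % 3 else OUT_OF_FRAME


def verify_junction_support(
    pred: ChimeraPrediction,
    evidence: JunctionEvidence,
    min_reads: int = 3,
    tol: int = 0,
) -> tuple[bool, int]:
    """Sum RNA junction reads matching the predicted donor/acceptor.

    Records match when chromosomes agree and positions are within ``tol``
    bp; the prediction is verified when the summed read count reaches
    ``min_reads``.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    reads = 0
    for dch, dpos, ach, apos, count in evidence.records:
        if (
            dch == pred.donor_chrom
            and ach == pred.acceptor_chrom
            and abs(dpos - pred.donor_pos) <= tol
            and abs(apos - pred.acceptor_pos) <= tol
        ):
            reads += count
    return (reads >= min_reads, reads)
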