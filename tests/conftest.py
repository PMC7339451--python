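"""Shared toy fixtures: a small hand-built annotation, cohort builders and
a sequence-backed fusion geometry used by the chimera tests."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from fusionscreen.cohort import CohortData
from fusionscreen.genome import GeneModel, GenomeAnnotation
from fusionscreen.svio import LEFT, RIGHT, Breakend, CallSet, SvCall


def make_gene(gid, chrom, strand, exons_genomic, cds=None, name=None) -> GeneModel:
    ex = sorted(exons_genomic)
    tx_start, tx_end = ex[0][0], ex[-1][1]
    if strand == "-":
        ex = ex[::-1]
    cds_start, cds_end = cds if cds else (None, None)
    return GeneModel(
        gene_id=gid, name=name or gid, chrom=chrom, strand=strand,
        tx_start=tx_start, tx_end=tx_end, exons=tuple(ex),
        cds_start=cds_start, cds_end=cds_end,
    )


def make_call(sample, chrom1, pos1, side1, chrom2, pos2, side2, sv_type="TRA", **kw) -> SvCall:
    b1, b2 = Breakend(chrom1, pos1, side1), Breakend(chrom2, pos2, side2)
    if b1.chrom == b2.chrom and b1.pos > b2.pos:
        b1, b2 = b2, b1
    kw.setdefault("n_discordant", 10)
    kw.setdefault("n_split", 5)
    return SvCall(sample_id=sample, bnd1=b1, bnd2=b2, sv_type=sv_type, **kw)


def make_cohort(expr: pd.DataFrame, tumor_type=None, callsets=None, cna=None, junctions=None) -> CohortData:
    if tumor_type is None:
        tumor_type = pd.Series("TT", index=expr.columns, name="tumor_type")
    if cna is None:
        cna = pd.DataFrame(0, index=expr.index, columns=expr.columns, dtype=int)
    callsets = callsets or {}
    wrapped = {
        s: cs if isinstance(cs, CallSet) else CallSet(sample_id=s, calls=list(cs))
        for s, cs in callsets.items()
    }
    return CohortData(
        callsets=wrapped, expr=expr, cna=cna, tumor_type=tumor_type,
        junctions=junctions or {},
    )


@pytest.fixture
def toy_ann() -> GenomeAnnotation:
    """Two chromosomes, four genes covering both strands and a non-coding gene."""
    genes = [
        make_gene("GA", "c1", "+",
                  [(10_000, 10_200), (30_000, 30_200), (40_000, 40_300)],
                  cds=(10_100, 40_200)),
        make_gene("GB", "c1", "-",
                  [(160_000, 160_400), (180_000, 180_200), (200_000, 200_300)],
                  cds=(160_100, 200_100)),
        make_gene("GC", "c2", "+",
                  [(500_000, 500_150), (520_000, 520_200), (540_000, 540_250)],
                  cds=(520_050, 540_100)),
        make_gene("GD", "c2", "-", [(800_000, 800_100), (820_000, 820_200)]),
    ]
    return GenomeAnnotation(genes, chrom_sizes={"c1": 1_000_000, "c2": 1_000_000})


# ---------------------------------------------------------------------------
# sequence-backed fusion geometry for the splicing-model archetypes

GCT32 = "GCT" * 32


@dataclass
class SeqGene:
    model: GeneModel
    exon_seqs: list  # transcription order

    @property
    def transcript(self) -> str:
        return "".join(self.exon_seqs)


@dataclass
class ChimeraToy:
    """Plus-strand fusion geometry with explicit exon sequences.

    Gene A (5', coding from mid exon 1, 100 coding bp retained, phase 1),
    gene A2 (5', untranslated first exon), gene B (3', untranslated first
    exon, ORF from exon 2), gene B2 (3', CDS start in exon 1, skipped
    coding prefix 4 bp ≡ 1 mod 3: in-frame with A), gene B3 (same but
    skipped prefix 3 bp ≡ 0: out of frame with A).
    """

    ann: GenomeAnnotation
    genes: dict

    def seq(self, gid) -> SeqGene:
        return self.genes[gid]

    def fusion_transcript(self, five_gid, five_last_exon, three_gid, three_first_exon) -> str:
        a, b = self.genes[five_gid], self.genes[three_gid]
        return "".join(a.exon_seqs[:five_last_exon]) + "".join(
            b.exon_seqs[three_first_exon - 1 :]
        )


@pytest.fixture
def chimera_toy() -> ChimeraToy:
    genes = {}

    def add(gid, chrom, exons, seqs, cds):
        g = make_gene(gid, chrom, "+", exons, cds=cds)
        assert [e - s for s, e in g.exons] == [len(x) for x in seqs]
        genes[gid] = SeqGene(model=g, exon_seqs=list(seqs))

    # A: exon1 = 10 bp UTR + ATG + 32 codons + 1 dangling base (100 coding bp)
    add(
        "A", "cA",
        [(1_000, 1_110), (61_000, 61_100), (70_000, 70_100)],
        ["T" * 10 + "ATG" + GCT32 + "G", "CT" + "CAT" * 32 + "AG", "CAT" * 16 + "TAA" + "C" * 49],
        cds=(1_010, 70_051),
    )
    # A2: entirely untranslated first exon
    add(
        "A2", "cA",
        [(200_000, 200_100), (261_000, 261_100), (270_000, 270_100)],
        ["T" * 100, "C" * 10 + "ATG" + "GCT" * 29, "CAT" * 16 + "TGA" + "G" * 49],
        cds=(261_010, 270_051),
    )
    # B: untranslated exon 1; ORF (MAHHH*) entirely within exons 2-3
    add(
        "B", "cB",
        [(500_000, 500_060), (520_000, 520_017), (540_000, 540_008)],
        ["T" * 60, "CCCCC" + "ATGGCTCATCAT", "CATTAA" + "GG"],
        cds=(520_005, 540_006),
    )
    # B2: CDS starts in exon 1, 4 coding bp before the first intron
    add(
        "B2", "cB",
        [(600_000, 600_009), (620_000, 620_014)],
        ["CCCCC" + "ATGG", "CTCATCATCATTAA"],
        cds=(600_005, 620_014),
    )
    # B3: CDS starts in exon 1, 3 coding bp before the first intron
    add(
        "B3", "cB",
        [(700_000, 700_008), (720_000, 720_015)],
        ["CCCCC" + "ATG", "GCTCATCATCATTAA"],
        cds=(700_005, 720_015),
    )
    ann = GenomeAnnotation(
        [g.model for g in genes.values()],
        chrom_sizes={"cA": 1_000_000, "cB": 1_000_000},
    )
    return ChimeraToy(ann=ann, genes=genes)
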