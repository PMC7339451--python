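"""Gene models, cytobands and genome-level breakend annotation.

All internal coordinates are 0-based half-open; GTF is read and written in
its native 1-based inclusive dialect, BED/BEDPE in 0-based half-open.
Exons of a gene model are ordered by transcription (exon 1 first), so for a
minus-strand gene exon 1 occupies the highest genomic coordinates.
"Upstream" and "downstream" are always relative to a gene's own
transcriptional strand: upstream of a minus-strand gene means a higher
genomic coordinate.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from typing import Iterable, Optional

from intervaltree import IntervalTree

UPSTREAM = "UPSTREAM"
DOWNSTREAM = "DOWNSTREAM"
GENIC = "GENIC"
INTERGENIC = "INTERGENIC"
EXON = "EXON"
INTRON = "INTRON"


@dataclass(frozen=True)
class GeneModel:
    """One gene with a single canonical transcript.

    ``exons`` is a tuple of (start, end) half-open intervals ordered by
    transcription; ``cds_start``/``cds_end`` bound the genomic CDS interval
    and are both ``None`` for a non-coding gene.
    """

    gene_id: str
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs at least one exon")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons {(s1, e1)} and {(s2, e2)}")
        if genomic[0][0] < self.tx_start or genomic[-1][1] > self.tx_end:
            raise ValueError(f"{self.gene_id}: exons extend beyond [tx_start, tx_end)")
        expect = tuple(genomic if self.strand == "+" else genomic[::-1])
        if tuple(self.exons) != expect:
            raise ValueError(f"{self.gene_id}: exons not in transcription order for strand {self.strand}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: cds_start/cds_end must both be set or both absent")
        if self.cds_start is not None:
            cov = sum(max(0, min(e, self.cds_end) - max(s, self.cds_start)) for s, e in self.exons)
            if cov <= 0:
                raise ValueError(f"{self.gene_id}: CDS interval does not intersect the exon union")

    # -- basic geometry -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos < self.tx_end

    def element_at(self, pos: int) -> Optional[tuple[str, int]]:
        """(EXON|INTRON, 1-based index in transcription order) at ``pos``."""
        if not self.contains(pos):
            return None
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos < e:
                return (EXON, i)
        for i in range(1, self.n_exons):
            a, b = self.exons[i - 1], self.exons[i]
            lo, hi = (a[1], b[0]) if self.strand == "+" else (b[1], a[0])
            if lo <= pos < hi:
                return (INTRON, i)
        return None  # pragma: no cover - tx bounds tighter than exon hull

    def upstream_distance(self, pos: int) -> Optional[int]:
        """bp from ``pos`` to the 5' gene boundary when pos is upstream, else None."""
        if self.strand == "+":
            return self.tx_start - pos if pos < self.tx_start else None
        return pos - self.tx_end + 1 if pos >= self.tx_end else None

    def downstream_distance(self, pos: int) -> Optional[int]:
        if self.strand == "+":
            return pos - self.tx_end + 1 if pos >= self.tx_end else None
        return self.tx_start - pos if pos < self.tx_start else None

    def coding_prefix_len(self, n_exons: int) -> int:
        """Coding bp contained in the first ``n_exons`` exons (transcription order)."""
        if not self.is_coding:
            return 0
        return sum(
            max(0, min(e, self.cds_end) - max(s, self.cds_start))
            for s, e in self.exons[:n_exons]
        )

    def intron_interval(self, index: int) -> tuple[int, int]:
        """Genomic half-open interval of intron ``index`` (1-based, after exon ``index``)."""
        if not 1 <= index < self.n_exons:
            raise ValueError(f"{self.gene_id}: intron index {index} out of range")
        a, b = self.exons[index - 1], self.exons[index]
        return (a[1], b[0]) if self.strand == "+" else (b[1], a[0])


@dataclass(frozen=True)
class BreakendAnnotation:
    """Annotation of one genomic position relative to the gene set.

    ``hit_genes`` holds (gene_id, EXON|INTRON, index) for genes whose body
    contains the position; ``flanking`` holds, for intergenic positions,
    (gene_id, UPSTREAM|DOWNSTREAM, distance) for genes within the flank
    window, relations computed on each gene's own strand.
    """

    status: str
    hit_genes: tuple[tuple[str, str, int], ...] = ()
    flanking: tuple[tuple[str, str, int], ...] = ()

    @property
    def is_genic(self) -> bool:
        return self.status == GENIC


class GenomeAnnotation:
    """A collection of gene models with an interval index over gene bodies."""

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: Optional[dict[str, int]] = None):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        if chrom_sizes is None:
            chrom_sizes = {}
            for g in self.genes.values():
                chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.tx_end)
        self.chrom_sizes = dict(chrom_sizes)
        for g in self.genes.values():
            size = self.chrom_sizes.get(g.chrom)
            if size is None or g.tx_end > size:
                raise ValueError(f"gene {g.gene_id} does not fit within chrom_sizes[{g.chrom}]")
        self._trees: dict[str, IntervalTree] = {}
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.tx_start, g.tx_end, g.gene_id)
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self._by_chrom.values():
            glist.sort(key=lambda g: (g.tx_start, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self.chrom_sizes:
            raise ValueError(
                f"unknown chromosome {chrom!r}; annotation uses "
                f"{sorted(self.chrom_sizes)} (chromosome names are passed through "
                "verbatim, no 'chr' normalization is attempted)"
            )

    def genes_on(self, chrom: str) -> list[GeneModel]:
        self._check_chrom(chrom)
        return self._by_chrom.get(chrom, [])

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        self._check_chrom(chrom)
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((self.genes[iv.data] for iv in tree.at(pos)), key=lambda g: g.gene_id)

    def annotate_position(self, chrom: str, pos: int, flank_window: int = 4_000_000) -> BreakendAnnotation:
        """Annotate ``pos`` as GENIC (with exon/intron indices) or INTERGENIC.

        Intergenic positions carry strand-aware flanking relations for every
        gene within ``flank_window``.
        """
        self._check_chrom(chrom)
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome (size {self.chrom_sizes[chrom]})")
        hits = []
        for g in self.genes_at(chrom, pos):
            elem = g.element_at(pos)
            if elem is not None:
                hits.append((g.gene_id, elem[0], elem[1]))
        if hits:
            return BreakendAnnotation(GENIC, hit_genes=tuple(hits))
        flanking = []
        for rel in (UPSTREAM, DOWNSTREAM):
            for gid, d in self.genes_within_window(chrom, pos, flank_window, rel):
                flanking.append((gid, rel, d))
        flanking.sort(key=lambda t: (t[2], t[0]))
        return BreakendAnnotation(INTERGENIC, flanking=tuple(flanking))

    def genes_within_window(
        self, chrom: str, pos: int, window: int, relation: str
    ) -> list[tuple[str, int]]:
        """Genes for which ``pos`` lies in ``relation`` to them within ``window`` bp.

        Sorted ascending by distance (ties by gene_id). Relations are
        strand-aware: ``pos`` UPSTREAM of a minus-strand gene means a higher
        coordinate than its transcription end.
        """
        if window <= 0:
            raise ValueError("window must be positive")
        if relation not in (UPSTREAM, DOWNSTREAM):
            raise ValueError(f"relation must be UPSTREAM or DOWNSTREAM, got {relation!r}")
        self._check_chrom(chrom)
        out = []
        for g in self._by_chrom.get(chrom, []):
            d = g.upstream_distance(pos) if relation == UPSTREAM else g.downstream_distance(pos)
            if d is not None and d <= window:
                out.append((g.gene_id, d))
        out.sort(key=lambda t: (t[1], t[0]))
        return out

    def nearest_upstream_gene_gap(self, gene_id: str) -> Optional[int]:
        """Distance from ``gene_id``'s 5' boundary to the nearest other gene upstream.

        Measured to the closest boundary of the nearest gene body lying
        (strand-aware) upstream of the target on the same chromosome; None
        when no such gene exists.
        """
        g = self.genes[gene_id]
        best = None
        for other in self._by_chrom[g.chrom]:
            if other.gene_id == gene_id:
                continue
            if g.strand == "+":
                if other.tx_end <= g.tx_start:
                    d = g.tx_start - other.tx_end + 1
                elif other.tx_start < g.tx_start:
                    d = 1  # overlapping upstream neighbor
                else:
                    continue
            else:
                if other.tx_start >= g.tx_end:
                    d = other.tx_start - g.tx_end + 1
                elif other.tx_end > g.tx_end:
                    d = 1
                else:
                    continue
            if best is None or d < best:
                best = d
        return best

    def genic_fraction(self) -> float:
        """Fraction of the genome covered by the union of gene bodies."""
        total = sum(self.chrom_sizes.values())
        if total == 0:
            raise ValueError("empty chrom_sizes")
        covered = 0
        for chrom, glist in self._by_chrom.items():
            last_end = -1
            for g in glist:
                s, e = max(g.tx_start, last_end), g.tx_end
                if e > s:
                    covered += e - s
                    last_end = e
                else:
                    last_end = max(last_end, g.tx_end)
        return covered / total


class CytobandMap:
    """Ordered cytogenetic bands per chromosome (UCSC cytoBand dialect)."""

    def __init__(self, bands: dict[str, list[tuple[int, int, str]]]):
        self.bands = {}
        for chrom, blist in bands.items():
            blist = sorted(blist)
            for (s1, e1, _), (s2, e2, _) in zip(blist, blist[1:]):
                if e1 != s2:
                    raise ValueError(f"{chrom}: bands do not tile contiguously at {e1}/{s2}")
            self.bands[chrom] = blist

    def cytoband_of(self, chrom: str, pos: int) -> str:
        if chrom not in self.bands:
            raise ValueError(f"no cytobands for chromosome {chrom!r} (have {sorted(self.bands)})")
        blist = self.bands[chrom]
        starts = [b[0] for b in blist]
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0 or pos >= blist[i][1]:
            raise ValueError(f"position {chrom}:{pos} outside the tiled cytoband range")
        return blist[i][2]


def read_cytobands(path: str) -> CytobandMap:
    """Read a UCSC cytoBand file (chrom, start, end, band, gieStain)."""
    bands: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated columns")
            chrom, start, end, band = parts[:4]
            bands.setdefault(chrom, []).append((int(start), int(end), band))
    return CytobandMap(bands)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gene_models(path: str, chrom_sizes: Optional[dict[str, int]] = None) -> GenomeAnnotation:
    """Parse a GTF into a :class:`GenomeAnnotation` with one canonical transcript per gene.

    The canonical transcript is the one with the longest CDS; ties go to the
    longest transcript (summed exon length) and then to the lexicographically
    smallest transcript id. GTF 1-based inclusive coordinates are converted
    to the internal 0-based half-open convention. ``#!chrom_size`` header
    comments, when present, supply chromosome sizes; otherwise sizes are
    inferred from the furthest gene end.
    """
    # transcript_id -> accumulated features
    tx: dict[str, dict] = {}
    header_sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#!chrom_size"):
                _, chrom, size = line.split()
                header_sizes[chrom] = int(size)
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("exon", "CDS"):
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            try:
                s, e = int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable coordinates") from exc
            attr = _parse_attributes(attrs)
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            tid = attr.get("transcript_id", gene_id)
            rec = tx.setdefault(
                tid,
                {"gene_id": gene_id, "name": attr.get("gene_name", gene_id),
                 "chrom": chrom, "strand": strand, "exons": [], "cds": []},
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ValueError(f"{path}:{lineno}: transcript {tid} spans chromosomes/strands")
            rec[{"exon": "exons", "CDS": "cds"}[feature]].append((s, e))

    by_gene: dict[str, list[tuple[str, dict]]] = {}
    for tid, rec in tx.items():
        by_gene.setdefault(rec["gene_id"], []).append((tid, rec))

    genes = []
    for gene_id, txs in by_gene.items():
        def rank(item):
            tid, rec = item
            cds_len = sum(e - s for s, e in rec["cds"])
            tx_len = sum(e - s for s, e in rec["exons"])
            return (-cds_len, -tx_len, tid)

        tid, rec = min(txs, key=rank)
        exons = sorted(rec["exons"])
        if rec["strand"] == "-":
            exons = exons[::-1]
        cds_start = cds_end = None
        if rec["cds"]:
            cds_start = min(s for s, _ in rec["cds"])
            cds_end = max(e for _, e in rec["cds"])
        genes.append(
            GeneModel(
                gene_id=gene_id, name=rec["name"], chrom=rec["chrom"], strand=rec["strand"],
                tx_start=min(s for s, _ in exons), tx_end=max(e for _, e in exons),
                exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    if chrom_sizes is None and header_sizes:
        chrom_sizes = header_sizes
    return GenomeAnnotation(genes, chrom_sizes=chrom_sizes)


def write_gene_models(ann: GenomeAnnotation, path: str) -> None:
    """Write the annotation back to GTF (1-based inclusive), one transcript per gene.

    Chromosome sizes are preserved in ``#!chrom_size`` header comments so a
    round-trip through :func:`read_gene_models` reproduces the annotation.
    """
    with open(path, "w") as fh:
        for chrom in sorted(ann.chrom_sizes):
            fh.write(f"#!chrom_size {chrom} {ann.chrom_sizes[chrom]}\n")
        for g in sorted(ann.genes.values(), key=lambda g: (g.chrom, g.tx_start, g.gene_id)):
            tid = f"{g.gene_id}.t1"
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}"; gene_name "{g.name}";'
            for s, e in sorted(g.exons):
                fh.write(f"{g.chrom}\tfusionscreen\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
                if g.is_coding:
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if ce > cs:
                        fh.write(
                            f"{g.chrom}\tfusionscreen\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t.\t{attrs}\n"
                        )


def write_cytobands(bands: CytobandMap, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(bands.bands):
            for s, e, name in bands.bands[chrom]:
                stain = "gneg"
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{stain}\n")
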