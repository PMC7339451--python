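"""Seeded synthetic cohorts with planted fusion events and a ground-truth manifest.

The generator emulates the study conditions the pipeline is built for: a
multi-chromosome annotation whose first introns are several-fold larger
than later ones, per-sample SV call sets containing planted UIB/DIB and
gene-gene events realized with orientation-concordant breakends, log-normal
expression noise with planted fold effects in fusion-positive samples,
GISTIC-amplified confounder samples with elevated expression but no SV,
germline events shared with a panel of normals, repeat regions, and random
background SVs. Every random draw flows from one named seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .chimera import predict_chimera
from .chimera import JunctionEvidence
from .cohort import CohortData, write_cohort, load_cohort
from .genome import (
    CytobandMap,
    GeneModel,
    GenomeAnnotation,
    read_cytobands,
    read_gene_models,
    write_cytobands,
    write_gene_models,
)
from .svio import (
    LEFT,
    RIGHT,
    Breakend,
    CallSet,
    SvCall,
    read_bed,
    read_bedpe,
    write_bedpe,
)

KINDS = ("GENE_GENE", "UIB_CP", "UIB_NCP", "DIB_NCP")


@dataclass(frozen=True)
class PlantedEvent:
    """Specification of one event to plant into the cohort.

    ``distance`` is the maximal breakpoint distance from the target's 5'
    (UIB) or 3' (DIB) boundary; per-sample distances are drawn between 30%
    and 100% of it. ``fold`` multiplies the target's TPM in positive
    samples. ``target`` and ``tumor_type`` default to an automatic choice.
    """

    kind: str
    n_pos: int = 4
    fold: float = 10.0
    distance: int = 30_000
    sv_type: str = "TRA"
    target: Optional[str] = None
    tumor_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.n_pos < 1 or self.fold <= 0:
            raise ValueError("n_pos must be >= 1 and fold > 0")
        if self.kind != "GENE_GENE" and not 0 < self.distance <= 4_000_000:
            raise ValueError("UIB/DIB distances must be in (0, 4 Mb]")


def default_events() -> list[PlantedEvent]:
    """One event per regime: a chimera-producing short-range UIB fusion, a
    megabase-range UIB enhancer repositioning, a downstream (DIB) event and
    a recurrent gene-gene fusion, with planted folds spanning the moderate
    to extreme upregulation seen in real cohorts."""
    return [
        PlantedEvent(kind="UIB_CP", n_pos=4, fold=25.0, distance=30_000),
        PlantedEvent(kind="UIB_NCP", n_pos=6, fold=110.0, distance=2_000_000),
        PlantedEvent(kind="DIB_NCP", n_pos=4, fold=9.0, distance=1_000_000),
        PlantedEvent(kind="GENE_GENE", n_pos=3, fold=25.0),
    ]


@dataclass
class SimConfig:
    """Cohort-generator parameters; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 4
    chrom_len: int = 40_000_000
    n_genes: int = 160
    exon_len_range: tuple[int, int] = (80, 300)
    intron_log_mean: float = math.log(3_000)
    intron_log_sigma: float = 1.0
    first_intron_scale: float = 4.0
    noncoding_frac: float = 0.1
    utr_first_exon_frac: float = 0.4
    samples: dict = field(default_factory=lambda: {"THCA": 60})
    events: list = field(default_factory=default_events)
    noise_sigma: float = 0.25
    baseline_log_mean: float = math.log(20.0)
    baseline_log_sigma: float = 1.0
    n_amplified_confounders: int = 2
    amplified_fold: float = 8.0
    n_germline_events: int = 3
    germline_carrier_frac: float = 0.4
    background_sv_rate: float = 1.5
    low_support_rate: float = 0.5
    repeat_trapped_rate: float = 0.3
    repeat_fraction: float = 0.03
    chimera_window: int = 100_000
    n_cytobands_per_chrom: int = 8

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_len", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.samples.values()):
            raise ValueError("sample counts must be positive")


@dataclass
class PlantedTruth:
    """Ground truth for one planted event, as realized in the cohort."""

    kind: str
    mode: str  # UIB | DIB | GENE_GENE
    target: str
    tumor_type: str
    positive_samples: list
    distances: dict
    fold: float
    expected_cp: bool
    five_gene: Optional[str] = None


@dataclass
class TruthManifest:
    seed: int
    events: list

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "events": [asdict(e) for e in self.events]}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        obj = json.loads(text)
        return cls(seed=obj["seed"], events=[PlantedTruth(**e) for e in obj["events"]])


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(cfg: SimConfig) -> GenomeAnnotation:
    """Draw a non-overlapping gene annotation, deterministic under the seed.

    Genes carry 3-10 exons; intron lengths are log-normal with the first
    intron scaled up by ``first_intron_scale``, mirroring the large first
    introns of real genes; a configurable fraction of coding genes has a
    purely untranslated first exon so that every frame outcome is
    exercised.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: cfg.chrom_len for c in chrom_names}
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gene_no = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        structures = []
        for _ in range(n_here):
            n_exons = int(rng.integers(3, 11))
            exon_lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, n_exons)
            intron_lens = np.exp(
                rng.normal(cfg.intron_log_mean, cfg.intron_log_sigma, n_exons - 1)
            ).astype(int)
            intron_lens = np.clip(intron_lens, 200, 500_000)
            intron_lens[0] = int(intron_lens[0] * cfg.first_intron_scale)
            structures.append((exon_lens, intron_lens))
        spans = [int(e.sum() + i.sum()) for e, i in structures]
        leftover = cfg.chrom_len - sum(spans) - 1000 * (n_here + 1)
        if leftover <= 0:
            raise ValueError(
                f"genes do not fit on {chrom}: increase chrom_len or reduce n_genes"
            )
        gaps = (rng.dirichlet(np.ones(n_here + 1)) * leftover).astype(int) + 1000
        cursor = 0
        for (exon_lens, intron_lens), gap in zip(structures, gaps[:-1]):
            cursor += int(gap)
            start = cursor
            exons_genomic = []
            pos = start
            for i, elen in enumerate(exon_lens):
                exons_genomic.append((pos, pos + int(elen)))
                pos += int(elen)
                if i < len(intron_lens):
                    pos += int(intron_lens[i])
            cursor = pos
            gene_no += 1
            gid = f"G{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            tx_exons = tuple(exons_genomic if strand == "+" else exons_genomic[::-1])
            cds_start = cds_end = None
            if rng.random() >= cfg.noncoding_frac:
                cds_start, cds_end = _draw_cds(rng, tx_exons, strand, cfg.utr_first_exon_frac)
            genes.append(
                GeneModel(
                    gene_id=gid, name=gid, chrom=chrom, strand=strand,
                    tx_start=start, tx_end=cursor, exons=tx_exons,
                    cds_start=cds_start, cds_end=cds_end,
                )
            )
    return GenomeAnnotation(genes, chrom_sizes=chrom_sizes)


def _tx_base(exons: tuple, strand: str, tx_pos: int) -> int:
    """Genomic coordinate of transcript position ``tx_pos`` (0-based)."""
    off = tx_pos
    for s, e in exons:
        ln = e - s
        if off < ln:
            return s + off if strand == "+" else e - 1 - off
        off -= ln
    raise ValueError("transcript position beyond the exon union")


def _draw_cds(rng, exons: tuple, strand: str, utr_first_exon_frac: float):
    lens = [e - s for s, e in exons]
    total = sum(lens)
    if rng.random() < utr_first_exon_frac and len(exons) >= 2:
        cds_tx_start = lens[0] + int(rng.integers(3, max(4, lens[1] // 2)))
    else:
        cds_tx_start = int(rng.integers(3, max(4, lens[0] - 3)))
    # leave a 3' UTR of at least 10 bp and trim to a whole number of codons
    max_len = total - cds_tx_start - 10
    n_codons = max(2, (max_len // 3) - int(rng.integers(0, 4)))
    cds_tx_end = cds_tx_start + 3 * n_codons  # exclusive transcript coord
    if cds_tx_end > total:
        cds_tx_end = cds_tx_start + 3 * ((total - cds_tx_start - 1) // 3)
    first = _tx_base(exons, strand, cds_tx_start)
    last = _tx_base(exons, strand, cds_tx_end - 1)
    lo, hi = min(first, last), max(first, last)
    return lo, hi + 1


def simulate_cytobands(ann: GenomeAnnotation, n_bands: int = 8) -> CytobandMap:
    """Equal-width synthetic bands tiling each chromosome, p then q arm."""
    bands = {}
    for chrom, size in ann.chrom_sizes.items():
        edges = np.linspace(0, size, n_bands + 1).astype(int)
        half = n_bands // 2
        names = [f"p{half - i}" for i in range(half)] + [
            f"q{i + 1}" for i in range(n_bands - half)
        ]
        bands[chrom] = [
            (int(edges[i]), int(edges[i + 1]), names[i]) for i in range(n_bands)
        ]
    return CytobandMap(bands)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SyntheticDataset:
    """Everything one simulation run produces."""

    config: SimConfig
    ann: GenomeAnnotation
    cohort: CohortData
    manifest: TruthManifest
    pon: CallSet
    repeats: dict
    bands: CytobandMap


def _five_boundary(g: GeneModel) -> int:
    return g.tx_start if g.strand == "+" else g.tx_end - 1


def _uib_breakend(g: GeneModel, d: int) -> Breakend:
    if g.strand == "+":
        return Breakend(g.chrom, g.tx_start - d, RIGHT)
    return Breakend(g.chrom, g.tx_end + d - 1, LEFT)


def _dib_breakend(g: GeneModel, d: int) -> Breakend:
    if g.strand == "+":
        return Breakend(g.chrom, g.tx_end + d - 1, LEFT)
    return Breakend(g.chrom, g.tx_start - d, RIGHT)


def _five_side_breakend(g: GeneModel, pos: int) -> Breakend:
    return Breakend(g.chrom, pos, LEFT if g.strand == "+" else RIGHT)


def _three_side_breakend(g: GeneModel, pos: int) -> Breakend:
    return Breakend(g.chrom, pos, RIGHT if g.strand == "+" else LEFT)


def _in_repeat(repeats: dict, chrom: str, pos: int) -> bool:
    tree = repeats.get(chrom)
    return bool(tree is not None and tree.overlaps_point(pos))


class _CohortBuilder:
    def __init__(self, cfg: SimConfig, ann: GenomeAnnotation):
        self.cfg = cfg
        self.ann = ann
        self.rng = np.random.default_rng([cfg.seed, 1])
        self.samples = [
            f"{tt}_{i:03d}" for tt, n in cfg.samples.items() for i in range(n)
        ]
        self.tumor_type = pd.Series(
            {s: s.rsplit("_", 1)[0] for s in self.samples}, name="tumor_type"
        )
        self.genes = sorted(ann.genes)
        self.calls: dict[str, list[SvCall]] = {s: [] for s in self.samples}
        self.junctions: dict[str, JunctionEvidence] = {}
        self.used_targets: set[str] = set()
        self.truth: list[PlantedTruth] = []
        self.repeats = self._draw_repeats()
        baseline = np.exp(
            self.rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sigma, len(self.genes))
        )
        noise = np.exp(
            self.rng.normal(0.0, cfg.noise_sigma, (len(self.genes), len(self.samples)))
        )
        self.expr = pd.DataFrame(
            baseline[:, None] * noise, index=self.genes, columns=self.samples
        )
        self.cna = pd.DataFrame(
            0, index=self.genes, columns=self.samples, dtype=int
        )
        # sparse benign copy-number calls
        mask = self.rng.random(self.cna.shape) < 0.02
        signs = self.rng.choice([-1, 1], size=self.cna.shape)
        self.cna = self.cna.mask(pd.DataFrame(mask, index=self.genes, columns=self.samples),
                                 pd.DataFrame(signs, index=self.genes, columns=self.samples))

    # -- geometry helpers ----------------------------------------------

    def _draw_repeats(self) -> dict:
        trees: dict[str, IntervalTree] = {}
        for chrom, size in self.ann.chrom_sizes.items():
            covered = 0
            target_bp = int(size * self.cfg.repeat_fraction)
            tree = IntervalTree()
            while covered < target_bp:
                length = int(self.rng.integers(2_000, 10_000))
                start = int(self.rng.integers(0, size - length))
                tree.addi(start, start + length)
                covered += length
            trees[chrom] = tree
        return trees

    def _random_intergenic_pos(self, chrom: str) -> int:
        for _ in range(200):
            pos = int(self.rng.integers(0, self.ann.chrom_sizes[chrom]))
            if not self.ann.annotate_position(chrom, pos, flank_window=1).is_genic:
                return pos
        raise RuntimeError(f"could not find an intergenic position on {chrom}")

    def _intergenic_breakend_at(self, gene: GeneModel, mode: str, d_max: int) -> tuple[Breakend, int]:
        """A clean intergenic, non-repeat breakend up/downstream of ``gene``."""
        make = _uib_breakend if mode == "UIB" else _dib_breakend
        for _ in range(100):
            d = max(1, int(d_max * self.rng.uniform(0.3, 1.0)))
            bnd = make(gene, d)
            if not 0 <= bnd.pos < self.ann.chrom_sizes[gene.chrom]:
                continue
            if self.ann.annotate_position(gene.chrom, bnd.pos, flank_window=1).is_genic:
                continue
            if _in_repeat(self.repeats, gene.chrom, bnd.pos):
                continue
            return bnd, d
        raise ValueError(
            f"planted event impossible in geometry: no clean breakend within "
            f"{d_max} bp {mode}-ward of {gene.gene_id}"
        )

    def _eligible_targets(self, mode: str, d_max: int, exclude: set[str]) -> list[GeneModel]:
        out = []
        for gid in self.genes:
            g = self.ann[gid]
            if gid in exclude or not g.is_coding or g.n_exons < 2:
                continue
            if mode == "UIB":
                ok = (g.tx_start - d_max >= 0) if g.strand == "+" else (
                    g.tx_end + d_max < self.ann.chrom_sizes[g.chrom]
                )
            else:
                ok = (g.tx_end + d_max < self.ann.chrom_sizes[g.chrom]) if g.strand == "+" else (
                    g.tx_start - d_max >= 0
                )
            if ok:
                out.append(g)
        return out

    def _pick(self, pool: list, why: str):
        if not pool:
            raise ValueError(f"planted event impossible in geometry: no gene for {why}")
        return pool[int(self.rng.integers(0, len(pool)))]

    def _support(self) -> dict:
        return {
            "n_discordant": int(self.rng.integers(6, 31)),
            "n_split": int(self.rng.integers(2, 13)),
        }

    def _make_call(self, sample: str, b1: Breakend, b2: Breakend, sv_type: str) -> SvCall:
        if b1.chrom == b2.chrom and b1.pos > b2.pos:
            b1, b2 = b2, b1
        return SvCall(sample_id=sample, bnd1=b1, bnd2=b2, sv_type=sv_type, **self._support())

    # -- planting -------------------------------------------------------

    def plant(self, ev: PlantedEvent) -> None:
        tt = ev.tumor_type or next(iter(self.cfg.samples))
        tt_samples = [s for s in self.samples if self.tumor_type[s] == tt]
        if ev.n_pos > len(tt_samples):
            raise ValueError(f"planted event needs {ev.n_pos} samples but {tt} has {len(tt_samples)}")
        positives = sorted(
            self.rng.choice(tt_samples, size=ev.n_pos, replace=False).tolist()
        )
        if ev.kind == "GENE_GENE":
            self._plant_gene_gene(ev, tt, positives)
        else:
            self._plant_intergenic(ev, tt, positives)

    def _plant_intergenic(self, ev: PlantedEvent, tt: str, positives: list) -> None:
        mode = "UIB" if ev.kind.startswith("UIB") else "DIB"
        if ev.target is not None:
            target = self.ann[ev.target]
        else:
            target = self._pick(
                self._eligible_targets(mode, ev.distance, self.used_targets),
                f"{ev.kind} target",
            )
        self.used_targets.add(target.gene_id)
        five_gene = None
        if ev.kind == "UIB_CP":
            pool = [
                self.ann[g] for g in self.genes
                if g != target.gene_id and self.ann[g].is_coding and self.ann[g].n_exons >= 2
                and (self.ann[g].chrom != target.chrom if ev.sv_type == "TRA" else True)
            ]
            five_gene = self._pick(pool, "UIB_CP 5' partner")
        distances = {}
        for s in positives:
            call = pred = None
            for _ in range(20):
                t_bnd, d = self._intergenic_breakend_at(target, mode, ev.distance)
                if ev.kind == "UIB_CP":
                    lo, hi = five_gene.intron_interval(1)
                    p_bnd = _five_side_breakend(five_gene, int(self.rng.integers(lo, hi)))
                else:
                    p_chrom = self._partner_chrom(target.chrom, ev.sv_type)
                    p_bnd = Breakend(
                        p_chrom,
                        self._random_intergenic_pos(p_chrom),
                        LEFT if self.rng.random() < 0.5 else RIGHT,
                    )
                call = self._make_call(s, t_bnd, p_bnd, ev.sv_type)
                if ev.kind != "UIB_CP":
                    break
                # another gene between the breakend and the target would
                # capture the splice — redraw until the target is the acceptor
                pred = predict_chimera(call, self.ann, chimera_window=self.cfg.chimera_window)
                if pred is not None and pred.three_gene == target.gene_id:
                    break
                call = None
            if call is None:
                raise ValueError(
                    f"planted event impossible in geometry: UIB_CP call for "
                    f"{target.gene_id} in {s} does not yield the expected chimera"
                )
            distances[s] = d
            self.calls[s].append(call)
            self.expr.loc[target.gene_id, s] *= ev.fold
            if ev.kind == "UIB_CP":
                self._add_junction_reads(s, pred)
        self._add_confounders(target.gene_id, tt, set(positives))
        self.truth.append(
            PlantedTruth(
                kind=ev.kind, mode=mode, target=target.gene_id, tumor_type=tt,
                positive_samples=positives, distances=distances, fold=ev.fold,
                expected_cp=(ev.kind == "UIB_CP"),
                five_gene=five_gene.gene_id if five_gene else None,
            )
        )

    def _plant_gene_gene(self, ev: PlantedEvent, tt: str, positives: list) -> None:
        pool3 = [
            self.ann[g] for g in self.genes
            if g not in self.used_targets and self.ann[g].is_coding and self.ann[g].n_exons >= 3
        ]
        three = self._pick(pool3, "gene-gene 3' gene")
        self.used_targets.add(three.gene_id)
        pool5 = [
            g for g in pool3
            if g.gene_id != three.gene_id
            and (g.chrom != three.chrom if ev.sv_type == "TRA" else True)
        ]
        five = self._pick(pool5, "gene-gene 5' gene")
        for s in positives:
            lo5, hi5 = five.intron_interval(1)
            lo3, hi3 = three.intron_interval(1)
            call = self._make_call(
                s,
                _five_side_breakend(five, int(self.rng.integers(lo5, hi5))),
                _three_side_breakend(three, int(self.rng.integers(lo3, hi3))),
                ev.sv_type,
            )
            self.calls[s].append(call)
            self.expr.loc[three.gene_id, s] *= ev.fold
            pred = predict_chimera(call, self.ann)
            if pred is None or pred.three_gene != three.gene_id:
                raise ValueError(
                    "planted event impossible in geometry: gene-gene call does not "
                    f"yield the expected chimera for {three.gene_id} in {s}"
                )
            self._add_junction_reads(s, pred)
        self.truth.append(
            PlantedTruth(
                kind=ev.kind, mode="GENE_GENE", target=three.gene_id, tumor_type=tt,
                positive_samples=positives, distances={s: 0 for s in positives},
                fold=ev.fold, expected_cp=True, five_gene=five.gene_id,
            )
        )

    def _partner_chrom(self, chrom: str, sv_type: str) -> str:
        if sv_type == "TRA":
            others = [c for c in self.ann.chrom_sizes if c != chrom]
            return others[int(self.rng.integers(0, len(others)))]
        return chrom

    def _add_junction_reads(self, sample: str, pred) -> None:
        ev = self.junctions.setdefault(sample, JunctionEvidence(sample_id=sample))
        ev.records.append(
            (
                pred.donor_chrom, pred.donor_pos,
                pred.acceptor_chrom, pred.acceptor_pos,
                int(self.rng.integers(4, 16)),
            )
        )

    def _add_confounders(self, gene_id: str, tt: str, positives: set) -> None:
        pool = [s for s in self.samples if self.tumor_type[s] == tt and s not in positives]
        n = min(self.cfg.n_amplified_confounders, len(pool))
        for s in self.rng.choice(pool, size=n, replace=False):
            self.cna.loc[gene_id, s] = 2
            self.expr.loc[gene_id, s] *= self.cfg.amplified_fold

    # -- background -----------------------------------------------------

    def _random_breakend(self, chrom: Optional[str] = None) -> Breakend:
        if chrom is None:
            chroms = list(self.ann.chrom_sizes)
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
        pos = int(self.rng.integers(0, self.ann.chrom_sizes[chrom]))
        return Breakend(chrom, pos, LEFT if self.rng.random() < 0.5 else RIGHT)

    def add_background(self) -> None:
        sv_types = ["DEL", "INV", "TDUP", "TRA"]
        for s in self.samples:
            for _ in range(int(self.rng.poisson(self.cfg.background_sv_rate))):
                b1 = self._random_breakend()
                interchrom = self.rng.random() < 0.5
                b2 = self._random_breakend(None if interchrom else b1.chrom)
                svt = "TRA" if b1.chrom != b2.chrom else sv_types[int(self.rng.integers(0, 3))]
                self.calls[s].append(self._make_call(s, b1, b2, svt))
            for _ in range(int(self.rng.poisson(self.cfg.low_support_rate))):
                b1, b2 = self._random_breakend(), self._random_breakend()
                call = self._make_call(s, b1, b2, "OTHER")
                self.calls[s].append(
                    replace(call, n_discordant=int(self.rng.integers(0, 4)), n_split=0)
                )
            for _ in range(int(self.rng.poisson(self.cfg.repeat_trapped_rate))):
                b1 = self._repeat_breakend()
                b2 = self._repeat_breakend()
                self.calls[s].append(self._make_call(s, b1, b2, "OTHER"))

    def _repeat_breakend(self) -> Breakend:
        chroms = [c for c, t in self.repeats.items() if len(t)]
        chrom = chroms[int(self.rng.integers(0, len(chroms)))]
        ivs = sorted(self.repeats[chrom])
        iv = ivs[int(self.rng.integers(0, len(ivs)))]
        pos = int(self.rng.integers(iv.begin, iv.end))
        return Breakend(chrom, pos, LEFT if self.rng.random() < 0.5 else RIGHT)

    def add_germline(self) -> CallSet:
        pon_calls = []
        for _ in range(self.cfg.n_germline_events):
            b1, b2 = self._random_breakend(), self._random_breakend()
            proto = self._make_call("PON", b1, b2, "OTHER")
            pon_calls.append(proto)
            carriers = [
                s for s in self.samples
                if self.rng.random() < self.cfg.germline_carrier_frac
            ]
            for s in carriers:
                j1 = int(self.rng.integers(-40, 41))
                j2 = int(self.rng.integers(-40, 41))
                self.calls[s].append(
                    self._make_call(
                        s,
                        Breakend(b1.chrom, max(0, b1.pos + j1), b1.side),
                        Breakend(b2.chrom, max(0, b2.pos + j2), b2.side),
                        "OTHER",
                    )
                )
        return CallSet(sample_id="PON", calls=pon_calls, provenance={"synthetic": True})

    def build(self) -> SyntheticDataset:
        for ev in self.cfg.events:
            self.plant(ev)
        self.add_background()
        pon = self.add_germline()
        callsets = {
            s: CallSet(sample_id=s, calls=list(cl), provenance={"synthetic": True})
            for s, cl in self.calls.items()
        }
        cohort = CohortData(
            callsets=callsets,
            expr=self.expr,
            cna=self.cna,
            tumor_type=self.tumor_type,
            junctions=self.junctions,
        )
        manifest = TruthManifest(seed=self.cfg.seed, events=self.truth)
        return SyntheticDataset(
            config=self.cfg,
            ann=self.ann,
            cohort=cohort,
            manifest=manifest,
            pon=pon,
            repeats=self.repeats,
            bands=simulate_cytobands(self.ann, self.cfg.n_cytobands_per_chrom),
        )


def simulate(cfg: SimConfig) -> SyntheticDataset:
    """Full simulation: annotation plus cohort plus ancillary fixtures."""
    ann = simulate_annotation(cfg)
    return _CohortBuilder(cfg, ann).build()


def simulate_cohort(cfg: SimConfig, ann: GenomeAnnotation) -> tuple[CohortData, TruthManifest]:
    """Cohort-only entry point against a pre-built annotation."""
    ds = _CohortBuilder(cfg, ann).build()
    return ds.cohort, ds.manifest


# ---------------------------------------------------------------------------
# fixture files


def write_fixture_files(ds: SyntheticDataset, outdir: str) -> None:
    """Emit the complete plain-text fixture set for a simulated dataset."""
    os.makedirs(outdir, exist_ok=True)
    write_gene_models(ds.ann, os.path.join(outdir, "genes.gtf"))
    write_cytobands(ds.bands, os.path.join(outdir, "cytobands.tsv"))
    write_cohort(ds.cohort, outdir)
    write_bedpe(ds.pon, os.path.join(outdir, "pon.bedpe"))
    with open(os.path.join(outdir, "repeats.bed"), "w") as fh:
        for chrom in sorted(ds.repeats):
            for iv in sorted(ds.repeats[chrom]):
                fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\trepeat\n")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(ds.manifest.to_json())
    with open(os.path.join(outdir, "simconfig.json"), "w") as fh:
        cfg = asdict(ds.config)
        cfg["exon_len_range"] = list(cfg["exon_len_range"])
        json.dump(cfg, fh, indent=2)


def load_dataset(outdir: str) -> SyntheticDataset:
    """Read a fixture directory back into in-memory structures."""
    ann = read_gene_models(os.path.join(outdir, "genes.gtf"))
    cohort = load_cohort(outdir)
    with open(os.path.join(outdir, "manifest.json")) as fh:
        manifest = TruthManifest.from_json(fh.read())
    with open(os.path.join(outdir, "simconfig.json")) as fh:
        raw = json.load(fh)
    raw["exon_len_range"] = tuple(raw["exon_len_range"])
    raw["events"] = [PlantedEvent(**e) if isinstance(e, dict) else e for e in raw["events"]]
    cfg = SimConfig(**raw)
    return SyntheticDataset(
        config=cfg,
        ann=ann,
        cohort=cohort,
        manifest=manifest,
        pon=read_bedpe(os.path.join(outdir, "pon.bedpe"), sample_id="PON"),
        repeats=read_bed(os.path.join(outdir, "repeats.bed")),
        bands=read_cytobands(os.path.join(outdir, "cytobands.tsv")),
    )
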