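"""Reading SV call sets (BEDPE) and the support / germline / repeat filters.

A breakend's ``side`` records where the retained, joined segment lies
relative to the breakpoint: LEFT means the retained DNA occupies lower
coordinates (BEDPE strand "+"), RIGHT means higher coordinates (strand "-").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from intervaltree import IntervalTree

LEFT = "LEFT"
RIGHT = "RIGHT"
SV_TYPES = ("DEL", "INV", "TDUP", "TRA", "OTHER")
HIGH = "HIGH"
LOW = "LOW"


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int  # 0-based
    side: str  # LEFT | RIGHT

    def __post_init__(self) -> None:
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"breakend side must be LEFT or RIGHT, got {self.side!r}")
        if self.pos < 0:
            raise ValueError("breakend position must be >= 0")


@dataclass(frozen=True)
class SvCall:
    """One SV junction: a pair of oriented breakends with read support."""

    sample_id: str
    bnd1: Breakend
    bnd2: Breakend
    sv_type: str = "OTHER"
    n_discordant: int = 0
    n_split: int = 0
    coverage_tier: str = HIGH

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"sv_type must be one of {SV_TYPES}, got {self.sv_type!r}")
        if self.n_discordant < 0 or self.n_split < 0:
            raise ValueError("support counts must be >= 0")
        if self.coverage_tier not in (HIGH, LOW):
            raise ValueError("coverage_tier must be HIGH or LOW")
        if self.bnd1.chrom == self.bnd2.chrom and self.bnd1.pos > self.bnd2.pos:
            raise ValueError("intra-chromosomal calls must have bnd1.pos <= bnd2.pos")

    @property
    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.bnd1, self.bnd2)

    def swapped(self) -> "SvCall":
        """The same junction with bnd1/bnd2 labels exchanged (inter-chromosomal only)."""
        return replace(self, bnd1=self.bnd2, bnd2=self.bnd1) if self.bnd1.chrom != self.bnd2.chrom else self


@dataclass
class CallSet:
    sample_id: str
    calls: list[SvCall] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.sample_id != self.sample_id:
                raise ValueError(f"call sample {c.sample_id} != call set sample {self.sample_id}")

    def __len__(self) -> int:
        return len(self.calls)


def _ordered(sample_id, bnd1, bnd2, **kw) -> SvCall:
    if bnd1.chrom == bnd2.chrom and bnd1.pos > bnd2.pos:
        bnd1, bnd2 = bnd2, bnd1
    return SvCall(sample_id=sample_id, bnd1=bnd1, bnd2=bnd2, **kw)


def strand_to_side(strand: str) -> str:
    """BEDPE strand "+" retains the leftward segment (side LEFT), "-" the rightward."""
    if strand == "+":
        return LEFT
    if strand == "-":
        return RIGHT
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def side_to_strand(side: str) -> str:
    return "+" if side == LEFT else "-"


def _parse_info(text: str) -> dict[str, str]:
    out = {}
    for item in text.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_bedpe(path: str, sample_id: str, coverage_tier: str = HIGH) -> CallSet:
    """Read a >=10 column BEDPE into a :class:`CallSet`.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1
    strand2 [info]. The optional 11th column carries ``key=value`` pairs;
    SVTYPE, DP (discordant pairs) and SR (split reads) are recognized.
    Breakend positions are the interval starts (0-based).
    """
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"{path}:{lineno}: BEDPE needs >=10 columns, got {len(parts)}")
            try:
                c1, s1 = parts[0], int(parts[1])
                c2, s2 = parts[3], int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable coordinates") from exc
            try:
                side1, side2 = strand_to_side(parts[8]), strand_to_side(parts[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            info = _parse_info(parts[10]) if len(parts) > 10 else {}
            sv_type = info.get("SVTYPE", "OTHER")
            if sv_type not in SV_TYPES:
                sv_type = "OTHER"
            calls.append(
                _ordered(
                    sample_id,
                    Breakend(c1, s1, side1),
                    Breakend(c2, s2, side2),
                    sv_type=sv_type,
                    n_discordant=int(info.get("DP", 0)),
                    n_split=int(info.get("SR", 0)),
                    coverage_tier=coverage_tier,
                )
            )
    return CallSet(sample_id=sample_id, calls=calls, provenance={"path": path, "coverage_tier": coverage_tier})


def write_bedpe(cs: CallSet, path: str, filter_reasons: Optional[dict[int, str]] = None) -> None:
    """Write a call set as BEDPE; dropped calls may carry a FILTER_REASON tag."""
    with open(path, "w") as fh:
        for i, c in enumerate(cs.calls):
            info = f"SVTYPE={c.sv_type};DP={c.n_discordant};SR={c.n_split}"
            if filter_reasons and i in filter_reasons:
                info += f";FILTER_REASON={filter_reasons[i]}"
            fh.write(
                "\t".join(
                    [
                        c.bnd1.chrom, str(c.bnd1.pos), str(c.bnd1.pos + 1),
                        c.bnd2.chrom, str(c.bnd2.pos), str(c.bnd2.pos + 1),
                        f"{cs.sample_id}_{i}", ".",
                        side_to_strand(c.bnd1.side), side_to_strand(c.bnd2.side),
                        info,
                    ]
                )
                + "\n"
            )


def filter_support(
    cs: CallSet,
    high_min_total: int = 6,
    low_min_discordant: int = 2,
    low_min_split: int = 1,
) -> CallSet:
    """Keep calls meeting the coverage-tier read-support thresholds.

    HIGH-tier calls need combined discordant + split support of at least
    ``high_min_total``; LOW-tier calls need at least ``low_min_discordant``
    discordant pairs and ``low_min_split`` split reads.
    """
    kept = []
    for c in cs.calls:
        if c.coverage_tier == HIGH:
            ok = c.n_discordant + c.n_split >= high_min_total
        else:
            ok = c.n_discordant >= low_min_discordant and c.n_split >= low_min_split
        if ok:
            kept.append(c)
    prov = dict(cs.provenance)
    prov["removed_support"] = prov.get("removed_support", 0) + len(cs.calls) - len(kept)
    return CallSet(sample_id=cs.sample_id, calls=kept, provenance=prov)


def read_bed(path: str) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _pon_match(call: SvCall, pon_call: SvCall, slop: int) -> bool:
    for a, b in ((call.bnd1, call.bnd2), (call.bnd2, call.bnd1)):
        if (
            a.chrom == pon_call.bnd1.chrom
            and abs(a.pos - pon_call.bnd1.pos) <= slop
            and b.chrom == pon_call.bnd2.chrom
            and abs(b.pos - pon_call.bnd2.pos) <= slop
        ):
            return True
    return False


def _in_repeat(bnd: Breakend, repeats: dict[str, IntervalTree]) -> bool:
    tree = repeats.get(bnd.chrom)
    return bool(tree is not None and tree.overlaps_point(bnd.pos))


def filter_germline_and_repeats(
    cs: CallSet,
    pon: Iterable[CallSet] = (),
    repeats: Optional[dict[str, IntervalTree]] = None,
    slop: int = 100,
    require_both_pon_ends: bool = True,
) -> CallSet:
    """Drop panel-of-normals (germline) matches and repeat-trapped calls.

    A call is germline when a PON call matches both breakends within
    ``slop`` bp on the same chromosomes (either-end matching is available
    via ``require_both_pon_ends=False``); a call is repeat-trapped when
    BOTH breakends fall inside repeat intervals. Counts removed per reason
    are recorded in the returned call set's provenance.
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    pon_calls = [c for p in pon for c in p.calls]
    kept, n_germ, n_rep = [], 0, 0
    for c in cs.calls:
        if require_both_pon_ends:
            is_germ = any(_pon_match(c, p, slop) for p in pon_calls)
        else:
            is_germ = any(
                a.chrom == pb.chrom and abs(a.pos - pb.pos) <= slop
                for p in pon_calls
                for a in c.breakends
                for pb in p.breakends
            )
        if is_germ:
            n_germ += 1
            continue
        if repeats and _in_repeat(c.bnd1, repeats) and _in_repeat(c.bnd2, repeats):
            n_rep += 1
            continue
        kept.append(c)
    prov = dict(cs.provenance)
    prov["removed_germline"] = prov.get("removed_germline", 0) + n_germ
    prov["removed_repeat"] = prov.get("removed_repeat", 0) + n_rep
    return CallSet(sample_id=cs.sample_id, calls=kept, provenance=prov)


def union_callsets(callsets: Iterable[CallSet], slop: int = 100) -> CallSet:
    """Positional union of call sets from multiple callers for one sample (plumbing).

    Calls whose breakend pairs agree within ``slop`` bp are merged, keeping
    the maximal support counts.
    """
    callsets = list(callsets)
    if not callsets:
        raise ValueError("no call sets to union")
    sample = callsets[0].sample_id
    merged: list[SvCall] = []
    for cs in callsets:
        if cs.sample_id != sample:
            raise ValueError("union_callsets expects call sets from a single sample")
        for c in cs.calls:
            for i, m in enumerate(merged):
                if c.sv_type == m.sv_type and _pon_match(c, m, slop):
                    merged[i] = replace(
                        m,
                        n_discordant=max(m.n_discordant, c.n_discordant),
                        n_split=max(m.n_split, c.n_split),
                    )
                    break
            else:
                merged.append(c)
    return CallSet(sample_id=sample, calls=merged, provenance={"union_of": len(callsets)})
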