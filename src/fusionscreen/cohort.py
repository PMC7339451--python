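"""Cohort container aligning SV call sets, expression, copy number and
RNA junction evidence, with plain-TSV readers and writers."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .chimera import JunctionEvidence
from .svio import CallSet, read_bedpe, write_bedpe


@dataclass
class CohortData:
    """Aligned per-sample data for one cohort.

    ``expr`` and ``cna`` are gene x sample matrices (TPM and GISTIC-style
    integer scores, where 2 marks high-level amplification); ``tumor_type``
    maps each sample to its label. ``junctions`` carries optional per-sample
    RNA spliced-junction evidence.
    """

    callsets: dict[str, CallSet]
    expr: pd.DataFrame
    cna: pd.DataFrame
    tumor_type: pd.Series
    junctions: dict[str, JunctionEvidence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = set(self.tumor_type.index)
        for name, df in (("expr", self.expr), ("cna", self.cna)):
            missing = samples - set(df.columns)
            if missing:
                raise ValueError(f"{name} matrix lacks samples {sorted(missing)[:5]}")
        unknown = set(self.callsets) - samples
        if unknown:
            raise ValueError(f"call sets for samples without labels: {sorted(unknown)[:5]}")
        if (self.expr.to_numpy() < 0).any():
            raise ValueError("TPM values must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.tumor_type.index)

    def samples_of_type(self, tumor_type: str) -> list[str]:
        return [s for s, t in self.tumor_type.items() if t == tumor_type]

    @property
    def tumor_types(self) -> list[str]:
        return sorted(self.tumor_type.unique())


def read_matrix(path: str) -> pd.DataFrame:
    """Gene x sample TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_matrix(df: pd.DataFrame, path: str, float_format: Optional[str] = None) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_junctions(path: str) -> dict[str, JunctionEvidence]:
    """Junction TSV: sample, chrom_donor, donor_pos, chrom_acceptor, acceptor_pos, reads."""
    out: dict[str, JunctionEvidence] = {}
    df = pd.read_csv(path, sep="\t", dtype={"chrom_donor": str, "chrom_acceptor": str})
    for row in df.itertuples(index=False):
        ev = out.setdefault(row.sample, JunctionEvidence(sample_id=row.sample))
        ev.records.append(
            (row.chrom_donor, int(row.donor_pos), row.chrom_acceptor, int(row.acceptor_pos), int(row.reads))
        )
    return out


def write_junctions(junctions: dict[str, JunctionEvidence], path: str) -> None:
    rows = [
        (s, *rec)
        for s, ev in sorted(junctions.items())
        for rec in ev.records
    ]
    pd.DataFrame(
        rows,
        columns=["sample", "chrom_donor", "donor_pos", "chrom_acceptor", "acceptor_pos", "reads"],
    ).to_csv(path, sep="\t", index=False)


def read_tumor_types(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("tumor_type")


def write_tumor_types(tumor_type: pd.Series, path: str) -> None:
    tumor_type.rename("tumor_type").to_csv(path, sep="\t", index_label="sample")


def load_cohort(directory: str) -> CohortData:
    """Assemble a :class:`CohortData` from a fixture directory.

    Expects ``expression.tsv``, ``cna.tsv``, ``tumor_types.tsv``,
    ``sv/<sample>.bedpe`` per sample, and optionally ``junctions.tsv``.
    """
    def need(name: str) -> str:
        p = os.path.join(directory, name)
        if not os.path.exists(p):
            raise FileNotFoundError(f"required cohort input missing: {p}")
        return p

    expr = read_matrix(need("expression.tsv"))
    cna = read_matrix(need("cna.tsv"))
    tumor_type = read_tumor_types(need("tumor_types.tsv"))
    svdir = need("sv")
    callsets = {}
    for sample in tumor_type.index:
        p = os.path.join(svdir, f"{sample}.bedpe")
        if os.path.exists(p):
            callsets[sample] = read_bedpe(p, sample_id=sample)
    jpath = os.path.join(directory, "junctions.tsv")
    junctions = read_junctions(jpath) if os.path.exists(jpath) else {}
    return CohortData(
        callsets=callsets, expr=expr, cna=cna, tumor_type=tumor_type, junctions=junctions
    )


def write_cohort(cohort: CohortData, directory: str) -> None:
    os.makedirs(os.path.join(directory, "sv"), exist_ok=True)
    write_matrix(cohort.expr, os.path.join(directory, "expression.tsv"))
    write_matrix(cohort.cna, os.path.join(directory, "cna.tsv"))
    write_tumor_types(cohort.tumor_type, os.path.join(directory, "tumor_types.tsv"))
    for sample, cs in cohort.callsets.items():
        write_bedpe(cs, os.path.join(directory, "sv", f"{sample}.bedpe"))
    write_junctions(cohort.junctions, os.path.join(directory, "junctions.tsv"))
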