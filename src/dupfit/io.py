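"""Readers and writers for the package's tabular and sequence formats.

All tabular interchange is TSV with a header line and stable column order.
Schemas:

* count tables: well_id, green_genotype, red_genotype, generation,
  red_count, green_count, total_count (one row per well x timepoint)
* estimates: well_id, green_genotype, red_genotype, s, R0_hat, status, se
* genotype tables: label, locus, promoter, provenance, elements
  (comma-separated; one row per occupied locus)
* landscape edge lists: parent, child, event, s_rep1, s_rep2, call

Alignments are FASTA (via Biopython) with '-' gaps; trees are newick with
post-duplication clades marked by an internal node label starting with
``DUP``. Flat configuration files are ``key = value`` lines with ``#``
comments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fitness import CompetitionCounts, SelectionEstimate
from .landscape import AlleleSpec, FitnessLandscape, GenotypeSpec

COUNT_COLUMNS = [
    "well_id",
    "green_genotype",
    "red_genotype",
    "generation",
    "red_count",
    "green_count",
    "total_count",
]
ESTIMATE_COLUMNS = ["well_id", "green_genotype", "red_genotype", "s", "R0_hat", "status", "se"]


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table lacks columns: {sorted(missing)}")
    return df[COUNT_COLUMNS]


def counts_to_wells(df: pd.DataFrame) -> list[CompetitionCounts]:
    """Group a long count table into one CompetitionCounts per well."""
    wells = []
    for well_id, grp in df.groupby("well_id", sort=True):
        grp = grp.sort_values("generation")
        wells.append(
            CompetitionCounts(
                well_id=str(well_id),
                timepoints=tuple(float(t) for t in grp["generation"]),
                red=tuple(int(r) for r in grp["red_count"]),
                green=tuple(int(g) for g in grp["green_count"]),
            )
        )
    return wells


def write_estimates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ESTIMATE_COLUMNS)


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def estimates_to_objects(df: pd.DataFrame) -> list[SelectionEstimate]:
    return [
        SelectionEstimate(
            well_id=str(row.well_id),
            s=float(row.s),
            R0_hat=None if pd.isna(row.R0_hat) else float(row.R0_hat),
            status=str(row.status),
            se=None if pd.isna(row.se) else float(row.se),
        )
        for row in df.itertuples()
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(alignment: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genotypes(path: str | Path) -> list[GenotypeSpec]:
    """Read a genotype table (one row per occupied locus) into specs."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"label", "locus", "promoter", "provenance", "elements"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype table needs columns {sorted(required)}")
    out = []
    for label, grp in df.groupby("label", sort=True):
        loci: dict[str, AlleleSpec] = {}
        for row in grp.itertuples():
            locus = row.locus.lower()
            if locus not in ("bub1", "mad3"):
                raise ValueError(f"unknown locus {row.locus!r}")
            elements = frozenset(
                e.strip() for e in row.elements.split(",") if e.strip()
            )
            loci[locus] = AlleleSpec(elements, row.promoter, row.provenance)
        out.append(
            GenotypeSpec(
                str(label),
                locus_bub1=loci.get("bub1"),
                locus_mad3=loci.get("mad3"),
            )
        )
    return out


def write_genotypes(genotypes: Sequence[GenotypeSpec], path: str | Path) -> None:
    rows = []
    for g in genotypes:
        for locus, allele in g.loci.items():
            if allele is None:
                continue
            rows.append(
                {
                    "label": g.label,
                    "locus": locus,
                    "promoter": allele.promoter,
                    "provenance": allele.provenance,
                    "elements": ",".join(sorted(allele.elements)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_landscape(landscape: FitnessLandscape, path: str | Path) -> None:
    landscape.edges_frame().to_csv(path, sep="\t", index=False)


def write_dot(landscape: FitnessLandscape, path: str | Path) -> None:
    Path(path).write_text(landscape.to_dot() + "\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` configuration with ``#`` comments."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out
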