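"""File I/O for the pipeline's standard formats.

FASTA goes through Biopython, Newick through dendropy (via
:class:`~nifsip.placement.ReferenceTree`), tabular data through pandas TSV
with a header row; '#'-prefixed lines are comments.  All writers produce
deterministic, diff-stable output.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refdb import RANKS, RawRecord
from .sip import FractionTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_raw_records",
    "read_lineage_table",
    "write_lineage_table",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_fraction_metadata",
    "load_fraction_tables",
    "write_fraction_tables",
    "write_tsv",
]

_FLOAT_FMT = "%.6g"


def read_fasta(path: str, with_descriptions: bool = False):
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Duplicate record ids are an error.  With ``with_descriptions=True`` a
    second return value maps id -> free-text description (id stripped).
    """
    records = []
    descriptions = {}
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        descriptions[rec.id] = desc
    if with_descriptions:
        return records, descriptions
    return records


def write_fasta(
    path: str,
    records: Iterable[tuple[str, str]],
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    seqs = [
        SeqRecord(Seq(seq), id=rid, description=descriptions.get(rid, ""))
        for rid, seq in records
    ]
    SeqIO.write(seqs, path, "fasta")


def read_lineage_table(path: str) -> dict[str, tuple]:
    """Lineage TSV (columns: id + the seven ranks; empty cell = rank absent)
    into a map id -> ordered (rank, name) tuple."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if "id" not in df.columns:
        raise ValueError(f"{path}: lineage table lacks an 'id' column")
    out: dict[str, tuple] = {}
    for _, row in df.iterrows():
        rid = row["id"]
        if rid in out:
            raise ValueError(f"{path}: duplicate lineage id {rid!r}")
        lin = tuple(
            (rank, row[rank])
            for rank in RANKS
            if rank in df.columns and row[rank] != ""
        )
        out[rid] = lin
    return out


def write_lineage_table(path: str, lineages: Mapping[str, tuple]) -> None:
    rows = []
    for rid in lineages:
        row = {"id": rid}
        row.update({rank: name for rank, name in lineages[rid]})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", *RANKS])
    df.to_csv(path, sep="\t", index=False)


def read_raw_records(fasta_path: str, lineage_path: str) -> list[RawRecord]:
    """Assemble curation inputs: sequences from FASTA (description used as
    the organism name) plus ranked lineages from the companion TSV."""
    records, descriptions = read_fasta(fasta_path, with_descriptions=True)
    lineages = read_lineage_table(lineage_path)
    out = []
    for rid, seq in records:
        out.append(
            RawRecord(
                id=rid,
                sequence=seq,
                organism_name=descriptions.get(rid, ""),
                lineage=lineages.get(rid, ()),
            )
        )
    return out


def read_counts_tsv(path: str) -> pd.DataFrame:
    """Taxa x samples integer count table (first column = taxon id)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty and df.columns.empty:
        return df
    bad = df.columns[df.dtypes == object]
    if len(bad):
        raise ValueError(f"{path}: non-numeric count column(s) {list(bad)}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_counts_tsv(path: str, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="taxon")


def read_fraction_metadata(path: str) -> pd.DataFrame:
    """Fraction metadata TSV: sample_id, condition, density.

    A blank density marks the unfractionated extract for that condition.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in ("sample_id", "condition", "density"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata lacks column {col!r}")
    return df


def load_fraction_tables(
    counts_path: str, meta_path: str
) -> dict[str, FractionTable]:
    """Assemble one :class:`FractionTable` per condition from a counts TSV
    and a fraction-metadata TSV."""
    counts = read_counts_tsv(counts_path)
    meta = read_fraction_metadata(meta_path)
    missing = set(meta["sample_id"]) - set(counts.columns)
    if missing:
        raise ValueError(
            f"{counts_path}: samples in metadata but not in counts: "
            f"{sorted(missing)[:5]}"
        )
    tables: dict[str, FractionTable] = {}
    for cond, grp in meta.groupby("condition", sort=True):
        frac = grp[grp["density"].notna()]
        unfrac = grp[grp["density"].isna()]
        unfrac_counts = None
        if len(unfrac):
            unfrac_counts = counts[list(unfrac["sample_id"])].sum(axis=1)
        tables[cond] = FractionTable(
            counts=counts[list(frac["sample_id"])],
            densities=pd.Series(
                frac["density"].to_numpy(dtype=float),
                index=list(frac["sample_id"]),
            ),
            condition=str(cond),
            unfractionated=unfrac_counts,
        )
    return tables


def write_fraction_tables(
    counts_path: str,
    meta_path: str,
    control: FractionTable,
    treatment: FractionTable,
) -> None:
    """Write a paired experiment as one counts TSV plus fraction metadata,
    appending one unfractionated sample per condition when present."""
    frames = []
    meta_rows = []
    for ft in (control, treatment):
        frames.append(ft.counts)
        for col in ft.counts.columns:
            meta_rows.append(
                {
                    "sample_id": col,
                    "condition": ft.condition,
                    "density": round(float(ft.densities[col]), 6),
                }
            )
        if ft.unfractionated is not None:
            col = f"{ft.condition}_unfractionated"
            frames.append(ft.unfractionated.rename(col).to_frame())
            meta_rows.append(
                {"sample_id": col, "condition": ft.condition, "density": None}
            )
    counts = pd.concat(frames, axis=1).fillna(0).astype(int)
    write_counts_tsv(counts_path, counts)
    pd.DataFrame(meta_rows, columns=["sample_id", "condition", "density"]).to_csv(
        meta_path, sep="\t", index=False
    )


def write_tsv(path: str, df: pd.DataFrame, comments: Iterable[str] = ()) -> None:
    """TSV with optional '#'-prefixed comment lines above the header."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
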