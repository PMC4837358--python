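"""Readers and writers for the formats the pipeline touches.

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive on
disk) is converted at the boundary in both directions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class IqdfamError(ValueError):
    """Base error for contract violations."""


@dataclass
class SequenceRecord:
    """A named sequence (protein or nucleotide), residues upper-cased."""

    id: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """One mRNA's exon/CDS structure in 0-based half-open contig coordinates."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_segments)

    @property
    def tss(self) -> int:
        """Transcription start: 5'-most coordinate on +, 3'-most on -."""
        starts = self.exons or [(s, e) for s, e, _ in self.cds_segments]
        if self.strand == "+":
            return min(s for s, _ in starts)
        return max(e for _, e in starts)


@dataclass
class FamilyTableRow:
    gene_name: str
    sequence_id: str
    orf_length_bp: int
    pi: float
    mw_da: float
    size_aa: int
    exons: int


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Residues are whitespace-stripped and upper-cased. Duplicate ids and
    empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise IqdfamError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = "".join(str(rec.seq).split()).upper()
        if not residues:
            raise IqdfamError(f"record {rec.id!r} in {path} has no residues")
        records.append(SequenceRecord(rec.id, rec.description, residues))
    if not records:
        raise IqdfamError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description if r.description != r.id else "")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")
    # Biopython wraps at 60 by default; width kept for signature clarity.


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into GeneModels (one per mRNA).

    File coordinates (1-based inclusive) become 0-based half-open; exons are
    sorted; CDS phases are carried through. A CDS whose total length is not a
    multiple of 3 is retained with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
            for f in db.children(mrna, featuretype="CDS")
        )
        model = GeneModel(
            gene_id=mrna.id, contig=mrna.seqid, strand=mrna.strand,
            exons=exons or [(s, e) for s, e, _ in cds], cds_segments=cds,
        )
        if model.cds_segments and model.cds_length % 3 != 0:
            warnings.warn(
                f"CDS length of {model.gene_id} ({model.cds_length}) is not a multiple of 3"
            )
        models.append(model)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels back out as canonical gene/mRNA/exon/CDS GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            gid = f"gene:{m.gene_id}"
            fh.write(
                f"{m.contig}\tiqdfam\tgene\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.contig}\tiqdfam\tmRNA\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent={gid}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.contig}\tiqdfam\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )
            for i, (s, e, phase) in enumerate(m.cds_segments, 1):
                fh.write(
                    f"{m.contig}\tiqdfam\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id}\n"
                )


_TABLE_COLUMNS = [
    "gene_name", "sequence_id", "orf_length_bp", "pi", "mw_da", "size_aa", "exons",
]


def load_family_table(path: str | Path | None = None) -> list[FamilyTableRow]:
    """Load the family summary table (TSV); defaults to the packaged fixture.

    Each row records one family member's ORF length (bp), isoelectric point,
    molecular weight (Da), protein length (aa) and exon count. Non-numeric
    cells raise a row-labelled error; the structural relation
    orf_length_bp == 3 * (size_aa + 1) is verified per row and reported via
    :func:`family_table_invariant`.
    """
    try:
        if path is None:
            with resources.as_file(
                resources.files("iqdfam.data") / "family_table.tsv"
            ) as p:
                df = pd.read_csv(p, sep="\t")
        else:
            df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise IqdfamError("family table file is empty") from exc
    if df.empty:
        raise IqdfamError("family table is empty")
    rows: list[FamilyTableRow] = []
    for _, rec in df.iterrows():
        label = str(rec.get("gene_name", "<unnamed>"))
        try:
            rows.append(
                FamilyTableRow(
                    gene_name=label,
                    sequence_id=str(rec["sequence_id"]),
                    orf_length_bp=int(rec["orf_length_bp"]),
                    pi=float(rec["pi"]),
                    mw_da=float(rec["mw_da"]),
                    size_aa=int(rec["size_aa"]),
                    exons=int(rec["exons"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise IqdfamError(f"row {label}: cannot parse numeric cell ({exc})") from exc
    for row in rows:
        for fld in ("orf_length_bp", "pi", "mw_da", "size_aa", "exons"):
            if getattr(row, fld) <= 0:
                raise IqdfamError(f"row {row.gene_name}: non-positive {fld}")
    return rows


def family_table_invariant(rows: list[FamilyTableRow]) -> dict[str, bool]:
    """Per-row check of ORF length = 3 x (protein length + 1)."""
    return {r.gene_name: r.orf_length_bp == 3 * (r.size_aa + 1) for r in rows}


def family_table_stats(rows: list[FamilyTableRow]) -> dict[str, float]:
    """Summary statistics over the family table (lengths, ORF range, pI range)."""
    aa = [r.size_aa for r in rows]
    orf = [r.orf_length_bp for r in rows]
    pi = [r.pi for r in rows]
    return {
        "n_genes": len(rows),
        "mean_length_aa": sum(aa) / len(aa),
        "min_length_aa": min(aa),
        "max_length_aa": max(aa),
        "min_orf_bp": min(orf),
        "max_orf_bp": max(orf),
        "min_pi": min(pi),
        "max_pi": max(pi),
    }


def load_cam_binding_peptides(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged predicted calmodulin-binding peptide strings (scanner fixtures)."""
    if path is None:
        with resources.as_file(
            resources.files("iqdfam.data") / "cam_binding_peptides.tsv"
        ) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def load_cis_element_library(path: str | Path | None = None) -> list[dict]:
    """Load a cis-element library (JSON list of element_id/consensus/description)."""
    if path is None:
        text = (resources.files("iqdfam.data") / "cis_element_library.json").read_text()
    else:
        text = Path(path).read_text()
    return json.loads(text)


#: Published per-species counts of full-length family proteins entering the
#: cross-species tree (rice, Brachypodium, Arabidopsis, poplar, soybean,
#: tomato), plus the moso bamboo family size kept separately.
TREE_SPECIES_COUNTS = {
    "Oryza sativa": 28,
    "Brachypodium distachyon": 23,
    "Arabidopsis thaliana": 34,
    "Populus trichocarpa": 40,
    "Glycine max": 67,
    "Solanum lycopersicum": 34,
}
MOSO_BAMBOO_FAMILY_SIZE = 29
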