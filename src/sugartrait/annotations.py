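"""Genome annotation input: feature tables with free-text product strings.

Annotations arrive as GenBank flat files, GFF3 (with ``product=``
attributes on CDS features), or a minimal 3-column TSV
(``genome_id``, ``protein_id``, ``product``).  All three are reduced to
the same in-memory :class:`GenomeAnnotation` so the downstream keyword
census never sees format differences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd


class AnnotationFormatError(ValueError):
    """Raised when an annotation file cannot be parsed in the declared dialect."""


@dataclass(frozen=True)
class FeatureRecord:
    """One protein-coding feature with its annotation product string."""

    genome_id: str
    feature_id: str
    product: str
    gene_name: Optional[str] = None
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if self.product is None:
            raise ValueError("product may be empty but not None")


@dataclass
class GenomeAnnotation:
    """A genome's protein-coding features plus its taxonomic labels."""

    genome_id: str
    features: list[FeatureRecord] = field(default_factory=list)
    species: str = ""
    genus: str = ""
    phylum: str = ""

    def __post_init__(self) -> None:
        for f in self.features:
            if f.genome_id != self.genome_id:
                raise ValueError(
                    f"feature {f.feature_id} carries genome_id {f.genome_id!r}, "
                    f"annotation is {self.genome_id!r}"
                )

    def __len__(self) -> int:
        return len(self.features)


def _dedup_key(rec: FeatureRecord) -> tuple:
    # duplicate proteins (e.g. identical proteins listed on two replicons)
    # collapse on protein_id; features without one are kept per feature_id
    if rec.protein_id:
        return ("pid", rec.protein_id)
    return ("fid", rec.genome_id, rec.feature_id)


def deduplicate(features: Iterable[FeatureRecord]) -> list[FeatureRecord]:
    """Collapse features sharing a protein_id, keeping first occurrence."""
    seen: set[tuple] = set()
    out: list[FeatureRecord] = []
    for rec in features:
        key = _dedup_key(rec)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def _genome_id_from_path(path: str) -> str:
    base = os.path.basename(path)
    for ext in (".gz", ".gbff", ".gbk", ".gb", ".gff3", ".gff", ".tsv", ".txt"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    return base


def _parse_genbank(path: str, genome_id: str) -> list[FeatureRecord]:
    from Bio import SeqIO

    records: list[FeatureRecord] = []
    try:
        parsed = list(SeqIO.parse(path, "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise AnnotationFormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    n = 0
    for seqrec in parsed:
        for feat in seqrec.features:
            if feat.type != "CDS":
                continue
            n += 1
            quals = feat.qualifiers
            records.append(
                FeatureRecord(
                    genome_id=genome_id,
                    feature_id=quals.get("locus_tag", [f"cds_{n}"])[0],
                    product=quals.get("product", [""])[0],
                    gene_name=quals.get("gene", [None])[0],
                    protein_id=quals.get("protein_id", [None])[0],
                )
            )
    return records


def _parse_gff3(path: str, genome_id: str) -> list[FeatureRecord]:
    from gffutils.iterators import DataIterator

    records: list[FeatureRecord] = []
    try:
        for n, feat in enumerate(DataIterator(path), start=1):
            if feat.featuretype != "CDS":
                continue
            attrs = feat.attributes
            records.append(
                FeatureRecord(
                    genome_id=genome_id,
                    feature_id=(attrs.get("ID") or [f"cds_{n}"])[0],
                    product=(attrs.get("product") or [""])[0],
                    gene_name=(attrs.get("gene") or [None])[0],
                    protein_id=(attrs.get("protein_id") or [None])[0],
                )
            )
    except AnnotationFormatError:
        raise
    except Exception as exc:
        raise AnnotationFormatError(f"{path}: not parseable as GFF3: {exc}") from exc
    return records


def _parse_tsv(path: str, genome_id: str) -> tuple[str, list[FeatureRecord]]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise AnnotationFormatError(f"{path}: not parseable as TSV: {exc}") from exc
    required = {"genome_id", "protein_id", "product"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationFormatError(
            f"{path}: TSV annotation missing columns {sorted(missing)}"
        )
    if len(df):
        genome_id = df["genome_id"].iloc[0]
    records = [
        FeatureRecord(
            genome_id=row.genome_id,
            feature_id=row.protein_id or f"row_{i}",
            product=row.product,
            protein_id=row.protein_id or None,
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
    return genome_id, records


def parse_annotation(
    path: str,
    format: str = "gff3",
    genome_id: Optional[str] = None,
    species: str = "",
    genus: str = "",
    phylum: str = "",
) -> GenomeAnnotation:
    """Parse an annotation file into a :class:`GenomeAnnotation`.

    Parameters
    ----------
    path:
        Annotation file. Must exist.
    format:
        One of ``genbank``, ``gff3``, ``tsv``.
    genome_id:
        Identifier for the genome; defaults to the file stem (TSV files
        may override it from their genome_id column).

    Features sharing a ``protein_id`` are collapsed to a single record
    before any counting, mirroring deduplicated protein files.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    gid = genome_id or _genome_id_from_path(path)
    if format == "genbank":
        feats = _parse_genbank(path, gid)
    elif format == "gff3":
        feats = _parse_gff3(path, gid)
    elif format == "tsv":
        gid2, feats = _parse_tsv(path, gid)
        gid = genome_id or gid2
        feats = [
            FeatureRecord(gid, f.feature_id, f.product, f.gene_name, f.protein_id)
            for f in feats
        ]
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GenomeAnnotation(
        genome_id=gid,
        features=deduplicate(feats),
        species=species,
        genus=genus,
        phylum=phylum,
    )
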