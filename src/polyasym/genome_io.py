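"""FASTA/GFF3 input, gene-model assembly, and gene-level filters.

One gene model is kept per gene (a uniform random isoform when several are
annotated), genes nested inside — or hosting — another gene are removed, and
genes are required to contain a minimum number of introns (default 2, so the
first/internal/last position classes are distinct).  All sequence delivery is
strand-normalized: minus-strand features are returned as the reverse
complement, i.e. as read by the transcription machinery.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
import numpy as np
from Bio import SeqIO

from .dsa_core import revcomp

logger = logging.getLogger("polyasym")

IUPAC = frozenset("ACGTRYSWKMBDHVN")


class FastaFormatError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """One selected transcript of one gene.

    ``exons`` are (start, end) pairs in genomic 1-based inclusive
    coordinates, ordered 5'->3' along the mRNA — i.e. ascending genomic
    position on the plus strand and descending on the minus strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    def introns_genomic(self) -> tuple[tuple[int, int], ...]:
        """Intron (start, end) pairs in transcription order, genomic coordinates."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return tuple(out)


def read_fasta(source) -> dict[str, str]:
    """Read FASTA into {chrom_id: uppercase sequence}.

    ``source`` may be a path, a text stream, or raw FASTA text.  Ids are the
    first whitespace-delimited header token.  Duplicate ids and non-IUPAC
    letters are format errors.
    """
    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle = io.StringIO(source)
    elif isinstance(source, (str, os.PathLike)):
        handle = open(source)
    else:
        handle = source
    genome: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in genome:
                raise FastaFormatError(f"duplicate sequence id {rec.id!r}")
            seq = str(rec.seq).upper()
            bad = sorted(set(seq) - IUPAC)
            if bad:
                raise FastaFormatError(
                    f"non-IUPAC characters in {rec.id!r}: {bad}")
            genome[rec.id] = seq
    finally:
        if handle is not source:
            handle.close()
    return genome


def _assemble_models(db: gffutils.FeatureDB) -> dict[str, list[GeneModel]]:
    candidates: dict[str, list[GeneModel]] = {}
    # warn about exons whose Parent cannot be resolved
    for exon in db.features_of_type("exon"):
        for pid in exon.attributes.get("Parent", []):
            try:
                db[pid]
            except gffutils.FeatureNotFoundError:
                logger.warning("exon at %s:%d-%d has unresolvable parent %r; skipped",
                               exon.seqid, exon.start, exon.end, pid)
    for gene in db.features_of_type("gene"):
        gid = gene.id
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(e.start, e.end) for e in db.children(mrna, featuretype="exon")]
            if not exons:
                logger.warning("mRNA %s has no exons; skipped", mrna.id)
                continue
            exons.sort(key=lambda x: x[0], reverse=(gene.strand == "-"))
            candidates.setdefault(gid, []).append(
                GeneModel(gene_id=gid, transcript_id=mrna.id, chrom=gene.seqid,
                          strand=gene.strand, exons=tuple(exons)))
    return candidates


def read_gff(source) -> dict[str, list[GeneModel]]:
    """Parse GFF3 into {gene_id: [isoform GeneModel, ...]}.

    Requires gene/mRNA/exon rows linked by Parent attributes.  Minus-strand
    exon lists come out in transcription order (descending genomic start).
    """
    try:
        if isinstance(source, (str, os.PathLike)) and not str(source).lstrip().startswith("##"):
            db = gffutils.create_db(str(source), dbfn=":memory:",
                                    merge_strategy="create_unique", keep_order=False)
        else:
            text = source if isinstance(source, str) else source.read()
            db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                                    merge_strategy="create_unique", keep_order=False)
    except gffutils.exceptions.EmptyInputError:
        return {}
    return _assemble_models(db)


def select_isoform(candidates: list[GeneModel], rng: np.random.Generator) -> GeneModel:
    """Uniform random choice of one isoform; reproducible under a seeded rng."""
    if not candidates:
        raise ValueError("no isoform candidates")
    if len(candidates) == 1:
        return candidates[0]
    return candidates[int(rng.integers(0, len(candidates)))]


def select_isoforms(candidates: Mapping[str, list[GeneModel]],
                    rng: np.random.Generator) -> list[GeneModel]:
    """One isoform per gene, in sorted gene-id order for determinism."""
    return [select_isoform(candidates[g], rng) for g in sorted(candidates)]


def filter_genes(models: Iterable[GeneModel], min_introns: int = 2,
                 remove_nested: bool = True) -> list[GeneModel]:
    """Apply the gene-level filters.

    When ``remove_nested`` is set, any gene whose genomic span lies within
    another gene's span is removed together with the hosting gene (strand is
    ignored; partial overlaps are retained).  Genes with fewer than
    ``min_introns`` introns are removed.  The retained set is independent of
    input order.
    """
    models = list(models)
    drop: set[str] = set()
    if remove_nested:
        by_chrom: dict[str, list[GeneModel]] = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append(m)
        for chrom_models in by_chrom.values():
            chrom_models.sort(key=lambda m: (m.span[0], -m.span[1], m.gene_id))
            for i, a in enumerate(chrom_models):
                sa, ea = a.span
                for b in chrom_models[i + 1:]:
                    sb, eb = b.span
                    if sb > ea:
                        break
                    if sa <= sb and eb <= ea and a.gene_id != b.gene_id:
                        drop.add(a.gene_id)
                        drop.add(b.gene_id)
    kept = [m for m in models if m.gene_id not in drop and m.n_introns >= min_introns]
    n_nested = len({m.gene_id for m in models} & drop)
    if n_nested:
        logger.info("removed %d nested/hosting genes", n_nested)
    return kept


def sense_sequence(chrom_seq: str, start: int, end: int, strand: str) -> str:
    """Sense-strand sequence of [start, end] (1-based inclusive).

    Plus strand returns the substring; minus strand its reverse complement.
    """
    if not (1 <= start <= end <= len(chrom_seq)):
        raise CoordinateError(
            f"coordinates [{start}, {end}] out of range for length {len(chrom_seq)}")
    sub = chrom_seq[start - 1:end]
    return sub if strand == "+" else revcomp(sub)
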