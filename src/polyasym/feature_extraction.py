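"""Trimmed, sense-oriented exon/intron features and distance-anchored bins.

Splice signals themselves (donor, acceptor, polypyrimidine tract) would
dominate any motif-asymmetry measurement near intron boundaries, so feature
sequences are trimmed before counting: by default 3 nt off each exon end and
6 nt off the intron 5' end / 40 nt off the intron 3' end.  A short-intron
mode (6/6) exists for genomes whose introns are typically shorter than the
40-nt acceptor-side trim.

Distance profiles slice the *trimmed* intron into nonoverlapping fixed-width
bins anchored at either end; bin 0 is adjacent to the anchor and therefore
starts 6 nt into the annotated intron when anchored at the 5' splice site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .genome_io import GeneModel, sense_sequence

logger = logging.getLogger("polyasym")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class TrimPolicy:
    """Nucleotides removed from feature ends before motif counting."""

    exon_left: int = 3
    exon_right: int = 3
    intron_left: int = 6
    intron_right: int = 40

    def __post_init__(self) -> None:
        if min(self.exon_left, self.exon_right, self.intron_left, self.intron_right) < 0:
            raise ValueError("trim amounts must be >= 0")

    @classmethod
    def short_intron_mode(cls) -> "TrimPolicy":
        """6/6 intron trimming for genomes with very short introns."""
        return cls(intron_left=6, intron_right=6)


@dataclass(frozen=True)
class FeatureSequence:
    """A sense-oriented exon or intron with its position class.

    ``ordinal`` is 1-based in transcription order; ``position_class`` is one
    of first/internal/last/only given the count of sibling features of the
    same kind.  ``trim_applied`` is (left, right) nt already removed from
    ``seq``; ``original_length`` is the untrimmed length.
    """

    gene_id: str
    kind: str  # "exon" | "intron"
    position_class: str  # "first" | "internal" | "last" | "only"
    ordinal: int
    seq: str
    original_length: int
    trim_applied: tuple[int, int] = (0, 0)


def _position_class(ordinal: int, n: int) -> str:
    if n == 1:
        return "only"
    if ordinal == 1:
        return "first"
    if ordinal == n:
        return "last"
    return "internal"


def build_features(model: GeneModel, genome: dict[str, str]) -> list[FeatureSequence]:
    """Untrimmed exon and intron features of one gene, interleaved in
    transcription order (exon 1, intron 1, exon 2, ...).

    n exons yield n-1 introns (the inter-exon gaps); abutting exons are an
    annotation error.  Minus-strand genes are handled by the transcription
    ordering of ``model.exons`` and by reverse-complementing each slice.
    """
    chrom = genome[model.chrom]
    feats: list[FeatureSequence] = []
    n_ex = len(model.exons)
    introns = model.introns_genomic()
    n_in = len(introns)
    for i, (s, e) in enumerate(model.exons, start=1):
        feats.append(FeatureSequence(
            gene_id=model.gene_id, kind="exon",
            position_class=_position_class(i, n_ex), ordinal=i,
            seq=sense_sequence(chrom, s, e, model.strand),
            original_length=e - s + 1))
        if i <= n_in:
            s2, e2 = introns[i - 1]
            if e2 < s2:
                raise AnnotationError(
                    f"zero-length intron between exons {i} and {i+1} of {model.gene_id}")
            feats.append(FeatureSequence(
                gene_id=model.gene_id, kind="intron",
                position_class=_position_class(i, n_in), ordinal=i,
                seq=sense_sequence(chrom, s2, e2, model.strand),
                original_length=e2 - s2 + 1))
    return feats


def trim_feature(feature: FeatureSequence, policy: TrimPolicy,
                 min_len: int = 6) -> FeatureSequence | None:
    """Trim one feature; returns None (exclusion) if it becomes shorter than min_len."""
    if feature.kind == "intron":
        left, right = policy.intron_left, policy.intron_right
    else:
        left, right = policy.exon_left, policy.exon_right
    L = feature.original_length - left - right
    if L < min_len:
        return None
    seq = feature.seq[left:len(feature.seq) - right if right else len(feature.seq)]
    return replace(feature, seq=seq, trim_applied=(left, right))


def trim_features(features, policy: TrimPolicy, min_len: int = 6):
    """Trim a feature list, logging how many were excluded as too short."""
    kept = []
    n_excluded = 0
    for f in features:
        t = trim_feature(f, policy, min_len)
        if t is None:
            n_excluded += 1
        else:
            kept.append(t)
    if n_excluded:
        logger.info("excluded %d features shorter than %d nt after trimming",
                    n_excluded, min_len)
    return kept


def slice_intervals(seq: str, width: int, anchor: str = "five_prime",
                    max_bins: int | None = None) -> list[tuple[int, str]]:
    """Nonoverlapping full-width bins of a trimmed intron, laid out from the anchor.

    ``anchor="five_prime"`` tiles left to right; ``"three_prime"`` measures
    from the trimmed 3' end toward the 5' end (bin 0 is the last ``width``
    nt, still given 5'->3').  A partial remainder is dropped, so the summed
    bin lengths differ from the intron length by less than ``width``.
    """
    if anchor not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown anchor {anchor!r}")
    L = len(seq)
    n = L // width
    if max_bins is not None:
        n = min(n, max_bins)
    out = []
    for i in range(n):
        if anchor == "five_prime":
            out.append((i, seq[i * width:(i + 1) * width]))
        else:
            start = L - (i + 1) * width
            out.append((i, seq[start:start + width]))
    return out


def export_features_tsv(features) -> str:
    """BED-like audit table of extracted features (one row per feature)."""
    lines = ["gene_id\tkind\tposition_class\tordinal\ttrimmed_length\toriginal_length"]
    for f in features:
        lines.append(f"{f.gene_id}\t{f.kind}\t{f.position_class}\t{f.ordinal}"
                     f"\t{len(f.seq)}\t{f.original_length}")
    return "\n".join(lines) + "\n"


def gene_end_regions(model: GeneModel, genome: dict[str, str], policy: TrimPolicy,
                     min_len: int = 6) -> tuple[FeatureSequence | None, FeatureSequence | None]:
    """Trimmed first and last exon of a gene (the 5'-end / 3'-end regions).

    Slots whose exon is too short after trimming are returned as None.
    """
    if len(model.exons) < 2:
        raise ValueError("gene_end_regions requires >= 2 exons")
    feats = [f for f in build_features(model, genome) if f.kind == "exon"]
    first = trim_feature(feats[0], policy, min_len)
    last = trim_feature(feats[-1], policy, min_len)
    return first, last
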