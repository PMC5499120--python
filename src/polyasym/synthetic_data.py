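"""Synthetic annotated genomes with known, tunable AATAAA depletion.

No public generative model exists for the strand-asymmetry patterns this
package measures, so this module plants them: multi-exon genes on both
strands over a near-complement-symmetric background, canonical GT..AG splice
sites whose positional consensus sharpens with a latent per-gene strength
s in [0, 1], and forward-strand motif occurrences removed with probability

    q(d, s) = q0 * exp(-d / tau) * (1 + coupling * (1 - s)),   clipped to [0, 1]

where d is the occurrence's distance from the intron 5' end (tau = 0 means
distance-independent) and coupling links weak splice sites to stronger
depletion.  Reverse-complement occurrences are never touched, so when
forward occurrences are removed independently with probability q the
expected downstream DSA is -q / (2 - q).

Removal is composition-preserving: the motif window is letter-permuted until
it is neither the motif nor its reverse complement, and the edited
neighbourhood is re-scanned so no disallowed occurrence is created.  Every
realized removal is recorded in a TruthRecord for parameter-recovery tests.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dsa_core import revcomp

logger = logging.getLogger("polyasym")


class ConfigurationError(ValueError):
    pass


class CapacityError(ValueError):
    pass


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# positional consensus of the planted splice windows (GT / AG are forced)
FIVE_EXONIC_CONSENSUS = "CAG"          # last 3 exon nt
FIVE_INTRONIC_CONSENSUS = "GTAAGT"     # first 6 intron nt
THREE_INTRONIC_CONSENSUS = "T" * 17 + "CAG"  # last 20 intron nt
THREE_EXONIC_CONSENSUS = "GTC"         # first 3 exon nt


def _draw(law: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample from a (name, *params) distribution law."""
    name = law[0]
    if name == "constant":
        return np.full(size, law[1], dtype=float)
    if name == "uniform_int":
        return rng.integers(int(law[1]), int(law[2]) + 1, size=size).astype(float)
    if name == "uniform":
        return rng.uniform(law[1], law[2], size=size)
    if name == "lognormal":  # parametrized by (median, sigma of log)
        return rng.lognormal(math.log(law[1]), law[2], size=size)
    if name == "poisson_shifted":  # law[1] = rate, law[2] = shift
        return (law[2] + rng.poisson(law[1], size=size)).astype(float)
    raise ConfigurationError(f"unknown distribution law {name!r}")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the standard study conditions.

    ``base_composition`` is (A, C, G, T) and defaults to the AT-rich,
    complement-symmetric (0.3, 0.2, 0.2, 0.3).  Length laws are
    (name, *params) tuples; introns default to log-normal with median 500 nt
    and exons to median 200 nt.  ``chrom_length`` of None sizes the
    chromosome to fit.
    """

    n_genes: int = 100
    chrom_length: int | None = None
    strand_fraction_plus: float = 0.5
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    exon_length_law: tuple = ("lognormal", 200, 0.6)
    intron_length_law: tuple = ("lognormal", 500, 0.7)
    exons_per_gene_law: tuple = ("uniform_int", 3, 6)
    depletion_base_q: float = 0.0
    depletion_distance_decay_tau: float = 0.0
    depletion_strength_coupling: float = 0.0
    expression_depletion_coupling: float = 0.0
    splice_site_strength_law: tuple = ("uniform", 0.0, 1.0)
    expression_law: tuple = ("lognormal", 10, 1.0)
    seed: int = 0
    motif: str = "AATAAA"
    # motifs the neutralization must not create (analysis panel + controls)
    protected_motifs: tuple = ("ATTAAA", "AATATA", "TATAAA", "TAAAAA", "AAAAAT")
    chrom_id: str = "chr1"
    intergenic_gap: int = 200
    min_exon_len: int = 12
    min_intron_len: int = 60
    depletion_margin_five: int = 6   # splice-signal margin never edited
    depletion_margin_three: int = 40

    def validate(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
            raise ConfigurationError(
                f"base_composition must be 4 nonnegative probabilities summing to 1, "
                f"got {self.base_composition}")
        if not 0 <= self.depletion_base_q <= 1:
            raise ConfigurationError("depletion_base_q must be in [0, 1]")
        if self.depletion_distance_decay_tau < 0:
            raise ConfigurationError("tau must be >= 0")
        if not 0 <= self.strand_fraction_plus <= 1:
            raise ConfigurationError("strand_fraction_plus must be in [0, 1]")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.min_exon_len < 6 or self.min_intron_len < 26:
            raise ConfigurationError(
                "exons must fit 3+3 splice margins and introns the 6+20 windows")

    def is_complement_symmetric(self) -> bool:
        a, c, g, t = self.base_composition
        return abs(a - t) < 1e-12 and abs(c - g) < 1e-12


@dataclass
class RemovalEvent:
    position: int  # 0-based within the intron, occurrence start
    prob: float    # probability that was applied


@dataclass
class IntronTruth:
    gene_id: str
    ordinal: int       # 1-based, transcription order
    strength: float    # latent 5'ss strength in [0, 1]
    length: int
    n_candidates: int  # motif occurrences eligible for removal
    events: list[RemovalEvent] = field(default_factory=list)


@dataclass
class TruthRecord:
    """Planted ground truth: per-intron removal events plus sense sequences."""

    introns: list[IntronTruth] = field(default_factory=list)
    q_eff: float = 0.0
    # generator-internal sense sequences, for byte-exact round-trip checks
    sense_exons: dict[str, list[str]] = field(default_factory=dict)
    sense_introns: dict[str, list[str]] = field(default_factory=dict)
    strands: dict[str, str] = field(default_factory=dict)
    n_failed_neutralizations: int = 0

    def to_text(self) -> str:
        lines = ["# polyasym truth v1", f"q_eff\t{self.q_eff:.10g}",
                 f"n_failed_neutralizations\t{self.n_failed_neutralizations}"]
        for it in self.introns:
            ev = ";".join(f"{e.position}:{e.prob:.10g}" for e in it.events)
            lines.append(f"intron\t{it.gene_id}\t{it.ordinal}\t{it.strength:.10g}"
                         f"\t{it.length}\t{it.n_candidates}\t{ev}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TruthRecord":
        rec = cls()
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "q_eff":
                rec.q_eff = float(parts[1])
            elif parts[0] == "n_failed_neutralizations":
                rec.n_failed_neutralizations = int(parts[1])
            elif parts[0] == "intron":
                _, gid, order, s, L, nc, ev = parts
                events = []
                if ev:
                    for tok in ev.split(";"):
                        pos, prob = tok.split(":")
                        events.append(RemovalEvent(int(pos), float(prob)))
                rec.introns.append(IntronTruth(gid, int(order), float(s),
                                               int(L), int(nc), events))
        return rec


@dataclass
class GenomeBundle:
    """FASTA + GFF3 + expression table + truth, as plain text."""

    fasta_text: str
    gff_text: str
    expression_text: str
    truth: TruthRecord

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, text in [("genome.fa", self.fasta_text),
                           ("annotation.gff3", self.gff_text),
                           ("expression.tsv", self.expression_text),
                           ("truth.txt", self.truth.to_text())]:
            with open(os.path.join(outdir, name), "w") as fh:
                fh.write(text)


def _random_seq(n: int, comp: np.ndarray, rng: np.random.Generator) -> str:
    if n <= 0:
        return ""
    codes = rng.choice(4, size=n, p=comp)
    return _BASES[codes].tobytes().decode("ascii")


def _sample_consensus(consensus: str, strength: float, rng: np.random.Generator,
                      forced: dict[int, str] | None = None) -> str:
    """Sample a window whose per-position consensus probability scales with strength."""
    p_cons = 0.25 + 0.72 * strength
    out = []
    for i, c in enumerate(consensus):
        if forced and i in forced:
            out.append(forced[i])
        elif rng.random() < p_cons:
            out.append(c)
        else:
            others = [b for b in "ACGT" if b != c]
            out.append(others[int(rng.integers(0, 3))])
    return "".join(out)


def _overlapping_occurrences(text: str, motif: str, lo: int, win_start: int,
                             win_end: int) -> set[int]:
    """Absolute start positions of ``motif`` in ``text`` (offset ``lo``)
    whose span overlaps [win_start, win_end)."""
    out = set()
    k = len(motif)
    j = text.find(motif)
    while j != -1:
        a = lo + j
        if a < win_end and a + k > win_start:
            out.add(a)
        j = text.find(motif, j + 1)
    return out


def plant_depletion(seq: str, motif: str, removal_prob: Callable[[float, float], float],
                    rng: np.random.Generator, latent_strength: float = 0.0,
                    start: int = 0, stop: int | None = None,
                    protected: tuple[str, ...] = (),
                    max_retries: int = 50) -> tuple[str, list[RemovalEvent], int, int]:
    """Remove forward motif occurrences with a positional probability.

    Each occurrence of ``motif`` (start within [start, stop-len)) in the
    sense-oriented ``seq`` is independently removed with probability
    ``removal_prob(distance_from_5p_end, latent_strength)``.  Removal
    permutes the window's letters (composition-preserving) until the edited
    neighbourhood contains no motif or reverse-complement occurrence
    overlapping the window and no *new* occurrence of a ``protected`` motif
    (or its reverse complement) — without protection, neutralizing AATAAA
    would leak counts into its anagrams, e.g. TAAAAA and AAAAAT.  Windows
    that cannot be neutralized within ``max_retries`` (e.g. homopolymers)
    are left unchanged and logged.  Reverse-complement occurrences are
    never targeted.

    Returns (sequence, removal events, n_candidate_occurrences, n_failed).
    """
    if not set(motif) <= set("ACGT"):
        raise ValueError("motif must be over A/C/G/T")
    k = len(motif)
    rc = revcomp(motif)
    watched = {motif, rc}
    guarded = set()
    for m in protected:
        guarded.update({m, revcomp(m)})
    guarded -= watched
    stop = len(seq) if stop is None else stop
    occ = []
    i = seq.find(motif, start)
    while i != -1 and i + k <= stop:
        occ.append(i)
        i = seq.find(motif, i + 1)
    if not occ:
        return seq, [], 0, 0
    arr = list(seq)
    events: list[RemovalEvent] = []
    n_failed = 0
    max_k = max([k] + [len(m) for m in guarded])
    for p in occ:
        if "".join(arr[p:p + k]) != motif:  # destroyed by an earlier overlapping edit
            continue
        q = min(max(float(removal_prob(p, latent_strength)), 0.0), 1.0)
        if rng.random() >= q:
            continue
        lo = max(0, p - max_k + 1)
        hi = min(len(arr), p + k + max_k - 1)
        before = "".join(arr[lo:hi])
        preexisting = {m: _overlapping_occurrences(before, m, lo, p, p + k)
                       for m in guarded}
        orig = arr[p:p + k]
        ok = False
        # phase 1 honours the protected list; phase 2 falls back to avoiding
        # only the motif and its reverse complement, so that protection can
        # never suppress the realized removal probability
        for phase_guarded in ([guarded, set()] if guarded else [set()]):
            for _ in range(max_retries):
                perm = rng.permutation(k)
                arr[p:p + k] = [orig[j] for j in perm]
                region = "".join(arr[lo:hi])
                bad = False
                for m in watched:
                    if _overlapping_occurrences(region, m, lo, p, p + k):
                        bad = True
                        break
                if not bad:
                    for m in phase_guarded:
                        if _overlapping_occurrences(region, m, lo, p, p + k) - preexisting[m]:
                            bad = True
                            break
                if not bad:
                    ok = True
                    break
            if ok:
                break
        if ok:
            events.append(RemovalEvent(p, q))
        else:
            arr[p:p + k] = orig
            n_failed += 1
            logger.warning("could not neutralize %s at %d; left unchanged", motif, p)
    return "".join(arr), events, len(occ), n_failed


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def generate_genome(config: SyntheticConfig, seed: int | None = None) -> GenomeBundle:
    """Generate a (FASTA, GFF3, expression, truth) bundle.

    Identical (config, seed) yields a byte-identical bundle.  Genes are laid
    out sequentially (never nested or overlapping) separated by
    ``intergenic_gap`` nt of background sequence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    comp = np.asarray(config.base_composition, dtype=float)
    motif = config.motif
    truth = TruthRecord()

    if config.n_genes == 0:
        L = config.chrom_length or 1000
        chrom = _random_seq(L, comp, rng)
        fasta = f">{config.chrom_id}\n{_wrap_fasta(chrom)}\n"
        gff = f"##gff-version 3\n##sequence-region {config.chrom_id} 1 {L}\n"
        return GenomeBundle(fasta, gff, "gene_id\tvalue\n", truth)

    n = config.n_genes
    n_exons = np.maximum(2, _draw(config.exons_per_gene_law, n, rng).astype(int))
    plus = rng.random(n) < config.strand_fraction_plus
    strengths = np.clip(_draw(config.splice_site_strength_law, n, rng), 0.0, 1.0)
    expression = _draw(config.expression_law, n, rng)
    if n > 1:
        expr_rank = np.argsort(np.argsort(expression)) / (n - 1)
    else:
        expr_rank = np.zeros(n)

    q0 = config.depletion_base_q
    tau = config.depletion_distance_decay_tau
    coupling = config.depletion_strength_coupling
    ecoupling = config.expression_depletion_coupling

    gene_records = []  # (gene_id, strand, exon_lens, intron_lens, sense_seq)
    total_candidates = 0
    total_removed = 0
    for g in range(n):
        gid = f"g{g:05d}"
        strand = "+" if plus[g] else "-"
        s = float(strengths[g])
        ne = int(n_exons[g])
        ni = ne - 1
        exon_lens = np.maximum(config.min_exon_len,
                               _draw(config.exon_length_law, ne, rng).astype(int))
        intron_lens = np.maximum(config.min_intron_len,
                                 _draw(config.intron_length_law, ni, rng).astype(int))
        exon_seqs = [_random_seq(int(l), comp, rng) for l in exon_lens]
        intron_seqs = [_random_seq(int(l), comp, rng) for l in intron_lens]
        for i in range(ni):
            exon_seqs[i] = (exon_seqs[i][:-3]
                            + _sample_consensus(FIVE_EXONIC_CONSENSUS, s, rng))
            five = _sample_consensus(FIVE_INTRONIC_CONSENSUS, s, rng,
                                     forced={0: "G", 1: "T"})
            three = _sample_consensus(THREE_INTRONIC_CONSENSUS, s, rng,
                                      forced={18: "A", 19: "G"})
            intron_seqs[i] = five + intron_seqs[i][6:-20] + three
            exon_seqs[i + 1] = (_sample_consensus(THREE_EXONIC_CONSENSUS, s, rng)
                                + exon_seqs[i + 1][3:])
        mult = (1.0 + coupling * (1.0 - s)) * (1.0 + ecoupling * float(expr_rank[g]))

        def prob_fn(d: float, s_: float, _mult=mult) -> float:
            decay = math.exp(-d / tau) if tau > 0 else 1.0
            return min(max(q0 * decay * _mult, 0.0), 1.0)

        truth.sense_exons[gid] = []
        truth.sense_introns[gid] = []
        truth.strands[gid] = strand
        for i in range(ni):
            iseq = intron_seqs[i]
            L = len(iseq)
            lo = config.depletion_margin_five
            hi = L - config.depletion_margin_three
            events: list[RemovalEvent] = []
            n_cand = 0
            if q0 > 0 and hi - lo >= len(motif):
                iseq, events, n_cand, n_failed = plant_depletion(
                    iseq, motif, prob_fn, rng, s, start=lo, stop=hi,
                    protected=tuple(config.protected_motifs))
                intron_seqs[i] = iseq
                truth.n_failed_neutralizations += n_failed
            total_candidates += n_cand
            total_removed += len(events)
            truth.introns.append(IntronTruth(gid, i + 1, s, L, n_cand, events))
        truth.sense_exons[gid] = list(exon_seqs)
        truth.sense_introns[gid] = list(intron_seqs)
        sense_parts = []
        for i in range(ne):
            sense_parts.append(exon_seqs[i])
            if i < ni:
                sense_parts.append(intron_seqs[i])
        gene_records.append((gid, strand, exon_lens, intron_lens, "".join(sense_parts)))

    truth.q_eff = total_removed / total_candidates if total_candidates else 0.0

    # layout: sequential placement with intergenic gaps
    gap = config.intergenic_gap
    placements = []  # (gid, strand, g_start, g_end, exon_coords transcription order)
    cursor = 0  # last occupied position (0 = none)
    for gid, strand, exon_lens, intron_lens, sense in gene_records:
        g_start = cursor + gap + 1
        g_end = g_start + len(sense) - 1
        # sense-offset intervals of exons
        offs = []
        o = 0
        for i, el in enumerate(exon_lens):
            offs.append((o, o + int(el) - 1))
            o += int(el)
            if i < len(intron_lens):
                o += int(intron_lens[i])
        if strand == "+":
            coords = [(g_start + a, g_start + b) for a, b in offs]
        else:
            coords = [(g_end - b, g_end - a) for a, b in offs]
        placements.append((gid, strand, g_start, g_end, coords, sense))
        cursor = g_end
    needed = cursor + gap
    if config.chrom_length is not None:
        if needed > config.chrom_length:
            raise CapacityError(
                f"chrom_length {config.chrom_length} cannot hold {n} genes "
                f"(need {needed})")
        L = config.chrom_length
    else:
        L = needed

    parts = []
    pos = 1
    for gid, strand, g_start, g_end, coords, sense in placements:
        parts.append(_random_seq(g_start - pos, comp, rng))
        parts.append(sense if strand == "+" else revcomp(sense))
        pos = g_end + 1
    parts.append(_random_seq(L - pos + 1, comp, rng))
    chrom = "".join(parts)

    gff_lines = ["##gff-version 3", f"##sequence-region {config.chrom_id} 1 {L}"]
    expr_lines = ["gene_id\tvalue"]
    for gi, (gid, strand, g_start, g_end, coords, _sense) in enumerate(placements):
        c = config.chrom_id
        gff_lines.append(f"{c}\tpolyasym\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gid}")
        gff_lines.append(f"{c}\tpolyasym\tmRNA\t{g_start}\t{g_end}\t.\t{strand}\t.\t"
                         f"ID={gid}.t1;Parent={gid}")
        for a, b in sorted(coords):
            gff_lines.append(f"{c}\tpolyasym\texon\t{a}\t{b}\t.\t{strand}\t.\t"
                             f"Parent={gid}.t1")
        expr_lines.append(f"{gid}\t{expression[gi]:.6g}")

    fasta = f">{config.chrom_id}\n{_wrap_fasta(chrom)}\n"
    gff = "\n".join(gff_lines) + "\n"
    expr = "\n".join(expr_lines) + "\n"
    return GenomeBundle(fasta, gff, expr, truth)
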