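"""Motif counting, the DNA strand asymmetry (DSA) statistic, and bootstrap tests.

Under Chargaff's second parity rule a motif and its reverse complement occur
at near-equal frequencies within a single DNA strand.  The DSA of a motif m
over a set of sense-oriented sequences,

    DSA(m) = (F - R) / (F + R),

where F is the pooled count of m and R the pooled count of revcomp(m) on the
same strand, measures the deviation from that parity.  A negative DSA is the
signature of selection against the motif on the transcribed strand; a
positive DSA indicates selection for it.

Counts are pooled across sequences rather than averaged per sequence: short
features frequently contain zero occurrences, which makes per-sequence ratios
unstable.  Significance is assessed by a seeded nonparametric bootstrap over
sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("polyasym")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_ACGT = frozenset("ACGT")

# byte code lookup: A,C,G,T -> 0..3, everything else -> 255 (invalid)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifCount:
    """Pooled forward / reverse-complement tallies of one motif.

    F and R are counts of the motif and of its reverse complement on the
    sense strand; n_windows is the number of k-windows scanned that contain
    only A/C/G/T (windows with ambiguity codes are excluded).
    """

    motif: str
    F: int
    R: int
    n_seqs: int
    n_windows: int

    def __post_init__(self) -> None:
        if self.F < 0 or self.R < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class DsaResult:
    """DSA = (F - R)/(F + R); undefined (NaN + flag) when F + R = 0."""

    motif: str
    dsa: float
    F: int
    R: int
    undefined: bool = False
    se_bootstrap: float | None = None
    se_undefined: bool = False
    sample_id: str = ""


@dataclass
class ContrastResult:
    """Two-sided bootstrap contrast between two DSA values."""

    kind: str  # "motif_vs_motif" | "group_vs_group"
    delta_dsa: float
    p_value: float
    n_boot: int
    seed: int
    unreliable: bool = False


def _count_in_seq(seq: str, motif: str) -> int:
    """Overlapping occurrence count of motif in one sequence."""
    n = 0
    i = seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


def _n_valid_windows(seq: str, k: int) -> int:
    """Number of k-windows made only of A/C/G/T."""
    L = len(seq)
    if L < k:
        return 0
    if _ACGT.issuperset(set(seq)):
        return L - k + 1
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = codes == 255
    # window invalid iff it contains any bad position
    ok = ~bad
    csum = np.concatenate([[0], np.cumsum(ok)])
    return int(np.count_nonzero(csum[k:] - csum[:-k] == k))


def count_occurrences(seqs: Iterable[str], motif: str) -> MotifCount:
    """Pool overlapping counts of ``motif`` and its reverse complement.

    Sequences are assumed sense-oriented and uppercase.  Windows containing
    non-ACGT letters never match and are excluded from ``n_windows``.
    """
    if not motif:
        raise ValueError("motif must be a nonempty A/C/G/T string")
    if not _ACGT.issuperset(motif):
        raise ValueError(f"motif must be over A/C/G/T, got {motif!r}")
    rc = revcomp(motif)
    k = len(motif)
    F = R = n_seqs = n_windows = 0
    for s in seqs:
        F += _count_in_seq(s, motif)
        R += _count_in_seq(s, rc)
        n_seqs += 1
        n_windows += _n_valid_windows(s, k)
    return MotifCount(motif=motif, F=F, R=R, n_seqs=n_seqs, n_windows=n_windows)


def per_sequence_counts(seqs: Sequence[str], motif: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence (F_i, R_i) arrays; resampling these reproduces pooled counts."""
    rc = revcomp(motif)
    F = np.fromiter((_count_in_seq(s, motif) for s in seqs), dtype=np.int64, count=len(seqs))
    R = np.fromiter((_count_in_seq(s, rc) for s in seqs), dtype=np.int64, count=len(seqs))
    return F, R


def dsa(count: MotifCount, sample_id: str = "") -> DsaResult:
    """DSA of a motif count; F + R = 0 yields an explicit undefined flag."""
    tot = count.F + count.R
    if tot == 0:
        return DsaResult(count.motif, math.nan, count.F, count.R, undefined=True,
                         sample_id=sample_id)
    return DsaResult(count.motif, (count.F - count.R) / tot, count.F, count.R,
                     sample_id=sample_id)


def dsa_of(seqs: Iterable[str], motif: str, sample_id: str = "") -> DsaResult:
    """Convenience: count then score."""
    return dsa(count_occurrences(seqs, motif), sample_id=sample_id)


# ---------------------------------------------------------------------------
# exhaustive k-mer tables
# ---------------------------------------------------------------------------

def _encode_kmer(kmer: str) -> int:
    v = 0
    for c in kmer:
        v = v * 4 + int(_CODE[ord(c)])
    return v


def _decode_kmer(v: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[v % 4])
        v //= 4
    return "".join(reversed(out))


def kmer_count_table(seqs: Iterable[str], k: int) -> np.ndarray:
    """Pooled overlapping counts of every k-mer (length-4**k array).

    Windows with non-ACGT letters are skipped.  Vectorized rolling encode.
    """
    counts = np.zeros(4**k, dtype=np.int64)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    for s in seqs:
        if len(s) < k:
            continue
        codes = _CODE[np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)]
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (win != 255).all(axis=1)
        if not valid.any():
            continue
        vals = (win[valid].astype(np.int64) * powers).sum(axis=1)
        counts += np.bincount(vals, minlength=4**k)
    return counts


@dataclass
class KmerRanking:
    """All-k-mer DSA table plus the query motif's percentile rank."""

    table: pd.DataFrame  # columns: motif, F, R, dsa (undefined rows dropped)
    query: str
    query_dsa: float
    percentile: float  # NaN when unavailable
    in_bottom_5pct: bool
    query_undefined: bool = False
    degenerate: bool = False  # all defined DSA values identical


def rank_all_kmers(seqs: Sequence[str], k: int, query: str) -> KmerRanking:
    """DSA of every k-mer over ``seqs`` and the query's rank among them.

    The percentile is the fraction of defined k-mers whose DSA lies strictly
    below the query's, with ties contributing half weight (mid-rank).  A
    query with F + R = 0 has no rank; when every defined DSA is identical the
    ranking is flagged degenerate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(query) != k:
        raise ValueError("query length must equal k")
    counts = kmer_count_table(seqs, k)
    n = 4**k
    # R[m] = F[revcomp(m)]
    rc_index = np.fromiter(
        (_encode_kmer(revcomp(_decode_kmer(v, k))) for v in range(n)),
        dtype=np.int64, count=n)
    F = counts
    R = counts[rc_index]
    tot = F + R
    defined = tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        dsa_vals = np.where(defined, (F - R) / np.where(tot == 0, 1, tot), np.nan)
    motifs = [_decode_kmer(v, k) for v in range(n)]
    table = pd.DataFrame({"motif": motifs, "F": F, "R": R, "dsa": dsa_vals})
    table = table[defined].reset_index(drop=True)

    qi = _encode_kmer(query)
    if not defined[qi]:
        return KmerRanking(table, query, math.nan, math.nan, False,
                           query_undefined=True)
    qd = float(dsa_vals[qi])
    vals = table["dsa"].to_numpy()
    below = int(np.count_nonzero(vals < qd))
    ties = int(np.count_nonzero(vals == qd))
    pct = (below + 0.5 * ties) / len(vals)
    degenerate = bool(np.ptp(vals) == 0) if len(vals) else True
    return KmerRanking(table, query, qd, pct, pct <= 0.05 and not degenerate,
                       degenerate=degenerate)


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------

def _boot_dsa(F: np.ndarray, R: np.ndarray, idx: np.ndarray) -> float:
    f = int(F[idx].sum())
    r = int(R[idx].sum())
    tot = f + r
    return (f - r) / tot if tot else math.nan


def bootstrap_se(seqs: Sequence[str], motif: str, n_boot: int, seed: int,
                 sample_id: str = "") -> DsaResult:
    """DSA with a bootstrap standard error over sequence resamples.

    Sequences are resampled with replacement ``n_boot`` times; the SE is the
    standard deviation of the replicate DSA values (undefined replicates are
    dropped; if all are undefined the SE itself is flagged undefined).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    seqs = list(seqs)
    F, R = per_sequence_counts(seqs, motif)
    res = dsa(MotifCount(motif, int(F.sum()), int(R.sum()), len(seqs),
                         sum(_n_valid_windows(s, len(motif)) for s in seqs)),
              sample_id=sample_id)
    rng = np.random.default_rng(seed)
    n = len(seqs)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        v = _boot_dsa(F, R, idx)
        if not math.isnan(v):
            reps.append(v)
    if not reps:
        res.se_bootstrap = math.nan
        res.se_undefined = True
    else:
        res.se_bootstrap = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
    return res


def _two_sided_p(deltas: np.ndarray, n_boot: int) -> float:
    ge = int(np.count_nonzero(deltas >= 0))
    le = int(np.count_nonzero(deltas <= 0))
    p = (2 * min(ge, le) + 1) / (n_boot + 1)
    return min(p, 1.0)


def compare_motifs(seqs: Sequence[str], motif_a: str, motif_b: str,
                   n_boot: int, seed: int) -> ContrastResult:
    """Paired bootstrap test of DSA(motif_a) - DSA(motif_b) on one sequence set.

    Each replicate resamples the sequences once and evaluates both motifs on
    the same resample; p = (2*min(#{d>=0}, #{d<=0}) + 1)/(n_boot + 1), two
    sided, capped at 1.
    """
    if len(motif_a) != len(motif_b):
        raise ValueError("motifs must have equal length")
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty sequence set")
    Fa, Ra = per_sequence_counts(seqs, motif_a)
    Fb, Rb = per_sequence_counts(seqs, motif_b)
    da = dsa_of(seqs, motif_a)
    db = dsa_of(seqs, motif_b)
    delta_hat = da.dsa - db.dsa
    rng = np.random.default_rng(seed)
    n = len(seqs)
    deltas = []
    n_undef = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        va = _boot_dsa(Fa, Ra, idx)
        vb = _boot_dsa(Fb, Rb, idx)
        if math.isnan(va) or math.isnan(vb):
            n_undef += 1
        else:
            deltas.append(va - vb)
    unreliable = n_undef > 0.1 * n_boot
    n_eff = len(deltas)
    if n_eff == 0:
        return ContrastResult("motif_vs_motif", delta_hat, 1.0, 0, seed, True)
    p = _two_sided_p(np.asarray(deltas), n_eff)
    return ContrastResult("motif_vs_motif", delta_hat, p, n_eff, seed, unreliable)


def compare_groups(seqs_1: Sequence[str], seqs_2: Sequence[str], motif: str,
                   n_boot: int, seed: int) -> ContrastResult:
    """Bootstrap test of DSA(group 1) - DSA(group 2), groups resampled independently."""
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    seqs_1, seqs_2 = list(seqs_1), list(seqs_2)
    if not seqs_1 or not seqs_2:
        raise ValueError("both groups must be nonempty")
    F1, R1 = per_sequence_counts(seqs_1, motif)
    F2, R2 = per_sequence_counts(seqs_2, motif)
    delta_hat = dsa_of(seqs_1, motif).dsa - dsa_of(seqs_2, motif).dsa
    rng = np.random.default_rng(seed)
    n1, n2 = len(seqs_1), len(seqs_2)
    deltas = []
    n_undef = 0
    for _ in range(n_boot):
        i1 = rng.integers(0, n1, size=n1)
        i2 = rng.integers(0, n2, size=n2)
        v1 = _boot_dsa(F1, R1, i1)
        v2 = _boot_dsa(F2, R2, i2)
        if math.isnan(v1) or math.isnan(v2):
            n_undef += 1
        else:
            deltas.append(v1 - v2)
    unreliable = n_undef > 0.1 * n_boot
    n_eff = len(deltas)
    if n_eff == 0:
        return ContrastResult("group_vs_group", delta_hat, 1.0, 0, seed, True)
    p = _two_sided_p(np.asarray(deltas), n_eff)
    return ContrastResult("group_vs_group", delta_hat, p, n_eff, seed, unreliable)
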