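"""Maximum-entropy splice-site models and strength quartiles.

Splice-site strength is scored as the log2 odds of a window under a
maximum-entropy sequence model versus a background composition.  The donor
(5'ss) window is 9 nt — 3 exonic + 6 intronic, GT at intron positions
+1/+2 — and the acceptor (3'ss) window is 23 nt — 20 intronic + 3 exonic,
AG at intron positions -2/-1.

An order-1 model constrains the positional nucleotide marginals and is
exactly the positional-frequency product model.  An order-2 model
additionally constrains position-pair dinucleotide marginals and is fitted
by iterative proportional scaling (IPF).  The 9-mer donor space is small
enough to constrain every pair and fit exhaustively.  The 23-mer acceptor
space is not enumerable, so its order-2 model is a chain of overlapping
blocks (each <= 9 positions): every block is fitted exhaustively with all
within-block pair constraints, and blocks are combined by conditioning on
their overlaps, which keeps the model exactly normalized.  Pairs spanning
distant positions in different blocks are only approximately constrained —
the same subset-decomposition compromise the established max-ent splice
scorers make for the acceptor site.  Models are retrained from any window
set; agreement with any published parameter set is not a goal.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .feature_extraction import build_features
from .genome_io import GeneModel

logger = logging.getLogger("polyasym")

FIVE_PRIME_LEN = 9   # 3 exonic + 6 intronic
THREE_PRIME_LEN = 23  # 20 intronic + 3 exonic

_CODE = {c: i for i, c in enumerate("ACGT")}


@dataclass(frozen=True)
class SpliceWindow:
    """One sense-oriented splice-site window."""

    site_type: str  # "five_prime" | "three_prime"
    seq: str
    gene_id: str = ""
    ordinal: int = 0  # intron ordinal, 1-based

    def is_canonical(self) -> bool:
        if self.site_type == "five_prime":
            return self.seq[3:5] == "GT"
        return self.seq[18:20] == "AG"


@dataclass
class FitDiagnostics:
    iterations: int = 0
    max_violation: float = math.inf
    converged: bool = False


@dataclass
class SpliceScore:
    window: str
    score: float  # bits; NaN when unscorable
    unscorable: bool = False


@dataclass
class BlockModel:
    """One exhaustively fitted block of a chained long-window model.

    ``pair_factors`` are local to the block (position indices relative to
    ``start``); ``overlap`` positions at the block's left edge are shared
    with the previous block and conditioned away when scoring.
    """

    start: int
    length: int
    overlap: int
    pair_factors: dict  # local (i, j) -> (4, 4)
    log2_table: np.ndarray | None = None    # (4,)*length, cached
    log2_overlap: np.ndarray | None = None  # (4,)*overlap, cached


@dataclass
class SpliceSiteModel:
    """Fitted max-ent distribution, represented by positional and pair factors.

    Enumerable windows: P(w) proportional to
    prod_i positional[i, w_i] * prod_{i<j} pair_factors[i,j][w_i, w_j],
    normalized by log2_z.  Long windows (order 2, length > 10) instead carry
    ``blocks``: a chain of exhaustively fitted overlapping block tables
    combined by conditioning on overlaps (exactly normalized, log2_z = 0).
    Order-1 models have neither and log2_z = 0.
    """

    site_type: str
    order: int
    length: int
    positional: np.ndarray              # (L, 4)
    background: np.ndarray              # (4,)
    pair_factors: dict = field(default_factory=dict)  # (i, j) -> (4, 4)
    blocks: list[BlockModel] | None = None
    log2_z: float = 0.0
    diagnostics: FitDiagnostics = field(default_factory=FitDiagnostics)


def extract_site_windows(model: GeneModel, genome: dict[str, str]) -> list[SpliceWindow]:
    """One donor and one acceptor window per intron, sense-oriented.

    Introns or flanking exons too short to host a window are skipped (counts
    logged at debug level).
    """
    feats = build_features(model, genome)
    exons = [f.seq for f in feats if f.kind == "exon"]
    introns = [f.seq for f in feats if f.kind == "intron"]
    out = []
    n_skip = 0
    for i, intron in enumerate(introns):
        up, down = exons[i], exons[i + 1]
        if len(up) >= 3 and len(intron) >= 6:
            out.append(SpliceWindow("five_prime", up[-3:] + intron[:6],
                                    model.gene_id, i + 1))
        else:
            n_skip += 1
        if len(intron) >= 20 and len(down) >= 3:
            out.append(SpliceWindow("three_prime", intron[-20:] + down[:3],
                                    model.gene_id, i + 1))
        else:
            n_skip += 1
    if n_skip:
        logger.debug("%s: skipped %d windows (feature too short)", model.gene_id, n_skip)
    return out


def extract_all_site_windows(models: Iterable[GeneModel],
                             genome: dict[str, str]) -> list[SpliceWindow]:
    out: list[SpliceWindow] = []
    for m in models:
        out.extend(extract_site_windows(m, genome))
    return out


def _window_seqs(windows, site_type):
    seqs = []
    for w in windows:
        if isinstance(w, SpliceWindow):
            if site_type is None:
                site_type = w.site_type
            if w.site_type == site_type:
                seqs.append(w.seq)
        else:
            seqs.append(w)
    return seqs, site_type


def _encode_matrix(seqs: Sequence[str], L: int) -> np.ndarray:
    mat = np.empty((len(seqs), L), dtype=np.int8)
    for r, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError(f"window length {len(s)} != model length {L}")
        for c, ch in enumerate(s):
            mat[r, c] = _CODE[ch]
    return mat


def fit_maxent(windows, order: int = 2, tolerance: float = 1e-4,
               max_iterations: int = 100, pseudocount: float = 0.5,
               background: np.ndarray | None = None, site_type: str | None = None,
               canonical_filter: bool = True) -> SpliceSiteModel:
    """Fit a maximum-entropy model to a training window set.

    Order 1 constrains positional nucleotide marginals (closed form: the
    independence model).  Order 2 additionally constrains position-pair
    dinucleotide marginals via iterative proportional scaling, run until the
    largest constraint violation drops below ``tolerance`` or
    ``max_iterations`` sweeps: all pairs for windows short enough to
    enumerate (length <= 10), within-block pairs of a chained
    overlapping-block decomposition otherwise.  A pseudocount (default 0.5
    per cell) smooths the empirical marginals.  Non-canonical windows (no
    GT / AG) are dropped before training unless ``canonical_filter`` is off.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    seqs, site_type = _window_seqs(windows, site_type)
    if canonical_filter:
        kept = []
        for s in seqs:
            if len(s) == FIVE_PRIME_LEN and s[3:5] != "GT":
                continue
            if len(s) == THREE_PRIME_LEN and s[18:20] != "AG":
                continue
            kept.append(s)
        if len(kept) < len(seqs):
            logger.info("canonical filter dropped %d of %d windows",
                        len(seqs) - len(kept), len(seqs))
        seqs = kept
    if len(seqs) < 100:
        raise ValueError(f"need >= 100 training windows, got {len(seqs)}")
    L = len(seqs[0])
    if site_type is None:
        site_type = "five_prime" if L == FIVE_PRIME_LEN else "three_prime"
    mat = _encode_matrix(seqs, L)
    N = len(seqs)

    # smoothed positional marginals
    positional = np.empty((L, 4))
    for i in range(L):
        counts = np.bincount(mat[:, i], minlength=4).astype(float) + pseudocount
        positional[i] = counts / counts.sum()
    if background is None:
        bg_counts = np.bincount(mat.ravel(), minlength=4).astype(float)
        bg = bg_counts / bg_counts.sum()
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()

    model = SpliceSiteModel(site_type=site_type, order=order, length=L,
                            positional=positional, background=bg)
    if order == 1:
        model.diagnostics = FitDiagnostics(0, 0.0, True)
        return model

    def emp_pair(i: int, j: int) -> np.ndarray:
        idx = mat[:, i].astype(np.int64) * 4 + mat[:, j]
        counts = np.bincount(idx, minlength=16).astype(float) + pseudocount
        return (counts / counts.sum()).reshape(4, 4)

    if L <= 10:
        pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
        emp = {p: emp_pair(*p) for p in pairs}
        table, factors, it, viol = _ipf(model.positional, emp, tolerance,
                                        max_iterations)
        model.pair_factors = factors
        model.log2_z = float(np.log2(table.sum()))
        model.diagnostics = FitDiagnostics(it, viol, viol < tolerance)
    else:
        _fit_blocked(model, emp_pair, tolerance, max_iterations)
    if not model.diagnostics.converged:
        logger.warning("max-ent fit did not converge: max violation %.3g",
                       model.diagnostics.max_violation)
    return model


def _ipf(positional: np.ndarray, emp: dict, tolerance: float,
         max_iterations: int):
    """Iterative proportional fitting of all pair constraints on an
    exhaustive joint table initialized at the independence model."""
    w = positional.shape[0]
    table = np.ones((4,) * w)
    for i in range(w):
        shape = [1] * w
        shape[i] = 4
        table = table * positional[i].reshape(shape)
    pairs = sorted(emp)
    factors = {p: np.ones((4, 4)) for p in pairs}
    other_axes = {(i, j): tuple(k for k in range(w) if k not in (i, j))
                  for i, j in pairs}
    it = 0
    viol = math.inf
    for it in range(1, max_iterations + 1):
        for (i, j) in pairs:
            m = table.sum(axis=other_axes[(i, j)])
            f = emp[(i, j)] / np.maximum(m, 1e-300)
            shape = [1] * w
            shape[i] = 4
            shape[j] = 4
            table = table * f.reshape(shape)
            factors[(i, j)] *= f
        viol = max(np.abs(table.sum(axis=other_axes[p]) - emp[p]).max()
                   for p in pairs)
        if viol < tolerance:
            break
    return table, factors, it, float(viol)


def _block_layout(L: int, width: int = 9, step: int = 5) -> list[tuple[int, int]]:
    """(start, overlap-with-previous) for a chain of overlapping blocks."""
    starts = list(range(0, L - width, step))
    starts.append(L - width)
    out = []
    prev_end = None
    for s in starts:
        overlap = 0 if prev_end is None else prev_end - s + 1
        out.append((s, overlap))
        prev_end = s + width - 1
    return out


def _fit_blocked(model, emp_pair, tolerance, max_iterations, width: int = 9):
    """Order-2 fit for windows too long to enumerate: a chain of
    exhaustively IPF-fitted overlapping blocks, combined by conditioning
    each block on its overlap with the previous one.  The combined model is
    exactly normalized; pairs spanning two blocks without a common block are
    only approximately constrained."""
    L = model.length
    blocks = []
    max_it = 0
    viol = 0.0
    converged = True
    for start, overlap in _block_layout(L, width):
        w = min(width, L - start)
        emp = {(i, j): emp_pair(start + i, start + j)
               for i in range(w) for j in range(i + 1, w)}
        table, factors, it, v = _ipf(model.positional[start:start + w], emp,
                                     tolerance, max_iterations)
        table = table / table.sum()
        blk = BlockModel(start=start, length=w, overlap=overlap,
                         pair_factors=factors)
        blk.log2_table = np.log2(np.maximum(table, 1e-300))
        if overlap:
            marg = table.sum(axis=tuple(range(overlap, w)))
            blk.log2_overlap = np.log2(np.maximum(marg, 1e-300))
        blocks.append(blk)
        max_it = max(max_it, it)
        viol = max(viol, v)
        converged = converged and v < tolerance
    model.blocks = blocks
    model.pair_factors = {}
    model.log2_z = 0.0
    model.diagnostics = FitDiagnostics(max_it, viol, converged)


def _rebuild_block_tables(model: SpliceSiteModel) -> None:
    """Recompute cached block tables from positional rows and pair factors."""
    for blk in model.blocks or []:
        w = blk.length
        table = np.ones((4,) * w)
        for i in range(w):
            shape = [1] * w
            shape[i] = 4
            table = table * model.positional[blk.start + i].reshape(shape)
        for (i, j), f in blk.pair_factors.items():
            shape = [1] * w
            shape[i] = 4
            shape[j] = 4
            table = table * f.reshape(shape)
        table = table / table.sum()
        blk.log2_table = np.log2(np.maximum(table, 1e-300))
        if blk.overlap:
            marg = table.sum(axis=tuple(range(blk.overlap, w)))
            blk.log2_overlap = np.log2(np.maximum(marg, 1e-300))


def log2_model_probability(model: SpliceSiteModel, window: str) -> float:
    codes = [_CODE.get(c, -1) for c in window]
    if -1 in codes or len(codes) != model.length:
        return math.nan
    if model.blocks:
        lp = 0.0
        for blk in model.blocks:
            sub = tuple(codes[blk.start:blk.start + blk.length])
            lp += float(blk.log2_table[sub])
            if blk.overlap:
                lp -= float(blk.log2_overlap[sub[:blk.overlap]])
        return lp
    lp = 0.0
    for i, c in enumerate(codes):
        lp += math.log2(model.positional[i, c])
    for (i, j), f in model.pair_factors.items():
        lp += math.log2(f[codes[i], codes[j]])
    return lp - model.log2_z


def score_window(model: SpliceSiteModel, window) -> SpliceScore:
    """log2(P_model / P_background) in bits; non-ACGT windows are unscorable."""
    seq = window.seq if isinstance(window, SpliceWindow) else window
    lp = log2_model_probability(model, seq)
    if math.isnan(lp):
        return SpliceScore(seq, math.nan, unscorable=True)
    lbg = sum(math.log2(model.background[_CODE[c]]) for c in seq)
    return SpliceScore(seq, lp - lbg)


def score_windows(model: SpliceSiteModel, windows) -> list[SpliceScore]:
    return [score_window(model, w) for w in windows]


def strength_quartiles(scores: Sequence[float]) -> tuple[list[str], bool]:
    """Label each score low (<= Q1), high (>= Q3) or mid.

    Quartiles use linear interpolation; when Q1 == Q3 the distribution is
    degenerate and everything is labeled mid (flag returned True).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 4:
        raise ValueError("need >= 4 scores for quartiles")
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    if q1 == q3:
        return ["mid"] * len(scores), True
    labels = []
    for s in scores:
        if s <= q1:
            labels.append("low")
        elif s >= q3:
            labels.append("high")
        else:
            labels.append("mid")
    return labels, False


# ---------------------------------------------------------------------------
# flat-text serialization
# ---------------------------------------------------------------------------

def save_model_text(model: SpliceSiteModel) -> str:
    buf = io.StringIO()
    buf.write("# polyasym splice model v1\n")
    buf.write(f"site_type\t{model.site_type}\n")
    buf.write(f"order\t{model.order}\n")
    buf.write(f"length\t{model.length}\n")
    buf.write(f"log2_z\t{model.log2_z:.17g}\n")
    buf.write("background\t" + "\t".join(f"{v:.17g}" for v in model.background) + "\n")
    for i in range(model.length):
        buf.write(f"positional\t{i}\t"
                  + "\t".join(f"{v:.17g}" for v in model.positional[i]) + "\n")
    for (i, j), f in sorted(model.pair_factors.items()):
        buf.write(f"pair\t{i}\t{j}\t"
                  + "\t".join(f"{v:.17g}" for v in f.ravel()) + "\n")
    for b, blk in enumerate(model.blocks or []):
        buf.write(f"block\t{b}\t{blk.start}\t{blk.length}\t{blk.overlap}\n")
        for (i, j), f in sorted(blk.pair_factors.items()):
            buf.write(f"bpair\t{b}\t{i}\t{j}\t"
                      + "\t".join(f"{v:.17g}" for v in f.ravel()) + "\n")
    return buf.getvalue()


def load_model_text(text: str) -> SpliceSiteModel:
    site_type = ""
    order = 1
    length = 0
    log2_z = 0.0
    background = np.zeros(4)
    positional_rows: dict[int, np.ndarray] = {}
    pair_factors: dict = {}
    blocks: dict[int, BlockModel] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        key = parts[0]
        if key == "site_type":
            site_type = parts[1]
        elif key == "order":
            order = int(parts[1])
        elif key == "length":
            length = int(parts[1])
        elif key == "log2_z":
            log2_z = float(parts[1])
        elif key == "background":
            background = np.array([float(v) for v in parts[1:5]])
        elif key == "positional":
            positional_rows[int(parts[1])] = np.array([float(v) for v in parts[2:6]])
        elif key == "pair":
            i, j = int(parts[1]), int(parts[2])
            pair_factors[(i, j)] = np.array([float(v) for v in parts[3:19]]).reshape(4, 4)
        elif key == "block":
            b = int(parts[1])
            blocks[b] = BlockModel(start=int(parts[2]), length=int(parts[3]),
                                   overlap=int(parts[4]), pair_factors={})
        elif key == "bpair":
            b, i, j = int(parts[1]), int(parts[2]), int(parts[3])
            blocks[b].pair_factors[(i, j)] = np.array(
                [float(v) for v in parts[4:20]]).reshape(4, 4)
    positional = np.vstack([positional_rows[i] for i in range(length)])
    model = SpliceSiteModel(site_type=site_type, order=order, length=length,
                            positional=positional, background=background,
                            pair_factors=pair_factors, log2_z=log2_z,
                            blocks=[blocks[b] for b in sorted(blocks)] or None)
    if model.blocks:
        _rebuild_block_tables(model)
    model.diagnostics = FitDiagnostics(0, 0.0, True)
    return model
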