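"""End-to-end orchestration of the strand-asymmetry analyses.

Each ``run_*`` function executes one analysis over a genome bundle (real or
synthetic) and returns a tidy DataFrame, one row per (analysis, sample,
motif).  Samples smaller than ``min_sample_n`` sequences (default 500) are
flagged ``below-min-n`` and carry no DSA value; nothing is dropped silently.
A single master seed fixes isoform selection and every bootstrap, so two
runs over the same inputs produce identical reports.
"""

from __future__ import annotations

import logging
import math
import os
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import dsa_core, splice_strength
from .dsa_core import bootstrap_se, compare_groups, compare_motifs, rank_all_kmers
from .feature_extraction import (FeatureSequence, TrimPolicy, build_features,
                                 slice_intervals, trim_feature, trim_features,
                                 gene_end_regions)
from .genome_io import GeneModel, filter_genes, read_fasta, read_gff, select_isoforms
from .splice_strength import (extract_all_site_windows, fit_maxent, score_window,
                              strength_quartiles)
from .synthetic_data import GenomeBundle

logger = logging.getLogger("polyasym")

REPORT_COLUMNS = ["analysis", "sample_id", "motif", "n_seqs", "F", "R", "dsa",
                  "se", "p_value", "percentile", "in_bottom_5pct", "mean_score",
                  "flags"]


@dataclass
class AnalysisConfig:
    """Analysis constants; defaults mirror the standard study conditions."""

    trim_policy: TrimPolicy = field(default_factory=TrimPolicy)
    short_intron_mode: bool = False
    min_introns: int = 2
    remove_nested: bool = True
    min_sample_n: int = 500
    min_len: int = 6
    distance_width: int = 500
    distance_bins: int = 4
    strength_width: int = 100
    strength_bins: int = 5
    motif: str = "AATAAA"
    panel: tuple = ("AATAAA", "ATTAAA", "AATATA", "TATAAA")
    controls: tuple = ("TAAAAA", "AAAAAT")
    n_boot: int = 200
    maxent_order: int = 2
    adjust_p: bool = False  # Benjamini-Hochberg across an analysis' contrasts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_width < 6 or self.strength_width < 6:
            raise ValueError("interval widths must be >= motif length")
        if self.min_sample_n < 1:
            raise ValueError("min_sample_n must be >= 1")

    def effective_policy(self) -> TrimPolicy:
        if self.short_intron_mode:
            return replace(self.trim_policy, intron_left=6, intron_right=6)
        return self.trim_policy


@dataclass
class Bundle:
    """Parsed and filtered genome: sequences plus one gene model per gene."""

    genome: dict[str, str]
    models: list[GeneModel]


def _seed_for(config: AnalysisConfig, label: str) -> int:
    """Deterministic per-sample bootstrap seed derived from the master seed."""
    return (config.seed * 1000003 + zlib.adler32(label.encode())) % (2**31 - 1)


def load_bundle(fasta_source, gff_source, config: AnalysisConfig) -> Bundle:
    """Read FASTA + GFF3, pick one isoform per gene, apply gene filters."""
    genome = read_fasta(fasta_source)
    candidates = read_gff(gff_source)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    models = select_isoforms(candidates, rng)
    models = filter_genes(models, min_introns=config.min_introns,
                          remove_nested=config.remove_nested)
    return Bundle(genome=genome, models=models)


def bundle_from_synthetic(gb: GenomeBundle, config: AnalysisConfig) -> Bundle:
    return load_bundle(gb.fasta_text, gb.gff_text, config)


def trimmed_introns(bundle: Bundle, config: AnalysisConfig) -> list[FeatureSequence]:
    policy = config.effective_policy()
    feats = []
    for m in bundle.models:
        feats.extend(f for f in build_features(m, bundle.genome) if f.kind == "intron")
    return trim_features(feats, policy, config.min_len)


def _empty_row(analysis: str, sample_id: str, motif: str) -> dict:
    row = {c: math.nan for c in REPORT_COLUMNS}
    row.update(analysis=analysis, sample_id=sample_id, motif=motif, flags="")
    return row


def _dsa_row(analysis: str, sample_id: str, motif: str, seqs: list[str],
             config: AnalysisConfig) -> dict:
    row = _empty_row(analysis, sample_id, motif)
    row["n_seqs"] = len(seqs)
    if len(seqs) < config.min_sample_n:
        row["flags"] = "below-min-n"
        return row
    res = bootstrap_se(seqs, motif, config.n_boot,
                       _seed_for(config, f"{analysis}|{sample_id}|{motif}"))
    row.update(F=res.F, R=res.R)
    if res.undefined:
        row["flags"] = "undefined"
    else:
        row.update(dsa=res.dsa, se=res.se_bootstrap)
    return row


def _finish(rows: list[dict], config: AnalysisConfig | None = None) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if config is not None and config.adjust_p and len(df):
        mask = df["p_value"].notna()
        if mask.any():
            df.loc[mask, "p_value"] = stats.false_discovery_control(
                df.loc[mask, "p_value"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def run_species_summary(bundle: Bundle, config: AnalysisConfig) -> pd.DataFrame:
    """Whole-genome summary: intronic DSA of the motif panel and controls,
    six-mer ranking of the query motif, and DSA of first exons and of the
    gene 3' end (operationalized as the trimmed last exon)."""
    rows: list[dict] = []
    if not bundle.models:
        return _finish(rows, config)
    introns = trimmed_introns(bundle, config)
    iseqs = [f.seq for f in introns]
    for motif in tuple(config.panel) + tuple(config.controls):
        rows.append(_dsa_row("species_summary", "introns_all", motif, iseqs, config))

    ranking = rank_all_kmers(iseqs, len(config.motif), config.motif)
    row = _empty_row("sixmer_rank", "introns_all", config.motif)
    row["n_seqs"] = len(iseqs)
    if ranking.query_undefined:
        row["flags"] = "undefined"
    else:
        row.update(dsa=ranking.query_dsa, percentile=ranking.percentile,
                   in_bottom_5pct=ranking.in_bottom_5pct)
        if ranking.degenerate:
            row["flags"] = "degenerate-ranking"
    rows.append(row)

    policy = config.effective_policy()
    firsts, lasts = [], []
    for m in bundle.models:
        f, l = gene_end_regions(m, bundle.genome, policy, config.min_len)
        if f is not None:
            firsts.append(f.seq)
        if l is not None:
            lasts.append(l.seq)
    for motif in tuple(config.panel) + tuple(config.controls):
        rows.append(_dsa_row("species_summary", "first_exons", motif, firsts, config))
        rows.append(_dsa_row("species_summary", "gene_3prime_end", motif, lasts, config))
    return _finish(rows, config)


def run_distance_profile(bundle: Bundle, config: AnalysisConfig) -> pd.DataFrame:
    """DSA of the query motif in fixed-width intronic bins at increasing
    distance from the upstream 5' splice site (bin 0 adjacent to it)."""
    introns = trimmed_introns(bundle, config)
    w = config.distance_width
    bins: dict[int, list[str]] = {i: [] for i in range(config.distance_bins)}
    for f in introns:
        for i, sub in slice_intervals(f.seq, w, "five_prime", config.distance_bins):
            bins[i].append(sub)
    rows = []
    for i in range(config.distance_bins):
        sample = f"bin{i}_{i * w}-{(i + 1) * w}nt"
        rows.append(_dsa_row("distance_profile", sample, config.motif, bins[i], config))
    return _finish(rows, config)


def _score_introns(bundle: Bundle, config: AnalysisConfig, site_type: str):
    """Fit a max-ent model on the bundle's own windows and score each intron.

    Returns ({(gene_id, ordinal): score}, model) — or (None, None) when
    there are too few windows to train.
    """
    windows = [w for w in extract_all_site_windows(bundle.models, bundle.genome)
               if w.site_type == site_type]
    try:
        model = fit_maxent(windows, order=config.maxent_order,
                           site_type=site_type)
    except ValueError as exc:
        logger.warning("cannot fit %s model: %s", site_type, exc)
        return None, None
    scores = {}
    for w in windows:
        sc = score_window(model, w)
        if not sc.unscorable:
            scores[(w.gene_id, w.ordinal)] = sc.score
    return scores, model


def run_strength_profile(bundle: Bundle, config: AnalysisConfig) -> pd.DataFrame:
    """DSA in fixed-width intronic bins anchored at the 5'ss (or 3'ss),
    stratified by the low/high quartile of the anchoring site's strength.

    The 3'ss variant anchors bins at the trimmed intron 3' end.  Degenerate
    score distributions (Q1 == Q3) skip the analysis with a flag.
    """
    introns = trimmed_introns(bundle, config)
    by_key = {(f.gene_id, f.ordinal): f for f in introns}
    rows = []
    for site_type, anchor, tag in [("five_prime", "five_prime", "5ss"),
                                   ("three_prime", "three_prime", "3ss")]:
        scores, _model = _score_introns(bundle, config, site_type)
        if scores is None:
            row = _empty_row("strength_profile", f"{tag}_all", config.motif)
            row["flags"] = "no-model"
            rows.append(row)
            continue
        keys = sorted(k for k in scores if k in by_key)
        if len(keys) < 4:
            row = _empty_row("strength_profile", f"{tag}_all", config.motif)
            row["flags"] = "below-min-n"
            rows.append(row)
            continue
        labels, degenerate = strength_quartiles([scores[k] for k in keys])
        if degenerate:
            row = _empty_row("strength_profile", f"{tag}_all", config.motif)
            row["flags"] = "degenerate-quartiles"
            rows.append(row)
            continue
        w = config.strength_width
        binned: dict[tuple[str, int], list[str]] = {}
        for k, lab in zip(keys, labels):
            if lab == "mid":
                continue
            for i, sub in slice_intervals(by_key[k].seq, w, anchor,
                                          config.strength_bins):
                binned.setdefault((lab, i), []).append(sub)
        for i in range(config.strength_bins):
            for lab in ("low", "high"):
                seqs = binned.get((lab, i), [])
                rows.append(_dsa_row("strength_profile", f"{tag}_{lab}_bin{i}",
                                     config.motif, seqs, config))
            lo = binned.get(("low", i), [])
            hi = binned.get(("high", i), [])
            if len(lo) >= config.min_sample_n and len(hi) >= config.min_sample_n:
                label = f"strength_profile|{tag}_bin{i}_low_vs_high"
                res = compare_groups(lo, hi, config.motif, max(config.n_boot, 99),
                                     _seed_for(config, label))
                row = _empty_row("strength_profile", f"{tag}_bin{i}_low_vs_high",
                                 config.motif)
                row.update(dsa=res.delta_dsa, p_value=res.p_value,
                           flags="unreliable" if res.unreliable else "")
                rows.append(row)
    return _finish(rows, config)


def run_position_classes(bundle: Bundle, config: AnalysisConfig) -> pd.DataFrame:
    """DSA of the query motif per intron position class, with pairwise
    bootstrap contrasts between classes."""
    introns = trimmed_introns(bundle, config)
    groups: dict[str, list[str]] = {"first": [], "internal": [], "last": [], "only": []}
    for f in introns:
        groups[f.position_class].append(f.seq)
    rows = []
    for cls in ("first", "internal", "last", "only"):
        seqs = groups[cls]
        if cls == "only" and not seqs:
            continue
        row = _dsa_row("position_classes", cls, config.motif, seqs, config)
        if not seqs:
            row["flags"] = "empty-class"
        rows.append(row)
    for a, b in [("first", "last"), ("first", "internal"), ("internal", "last")]:
        if (len(groups[a]) >= config.min_sample_n
                and len(groups[b]) >= config.min_sample_n):
            res = compare_groups(groups[a], groups[b], config.motif,
                                 max(config.n_boot, 99),
                                 _seed_for(config, f"position|{a}_vs_{b}"))
            row = _empty_row("position_classes", f"{a}_vs_{b}", config.motif)
            row.update(dsa=res.delta_dsa, p_value=res.p_value,
                       flags="unreliable" if res.unreliable else "")
            rows.append(row)
    return _finish(rows, config)


def read_expression_table(source) -> dict[str, float]:
    """Two-column (gene_id, value) TSV; a header line is tolerated."""
    if isinstance(source, dict):
        return dict(source)
    if isinstance(source, str) and "\t" in source:
        import io as _io
        df = pd.read_csv(_io.StringIO(source), sep="\t", header=None,
                         names=["gene_id", "value"], comment="#")
    else:
        df = pd.read_csv(source, sep="\t", header=None,
                         names=["gene_id", "value"], comment="#")
    # drop a header row if present
    df = df[pd.to_numeric(df["value"], errors="coerce").notna()]
    return dict(zip(df["gene_id"], df["value"].astype(float)))


def run_expression_strata(bundle: Bundle, expression, config: AnalysisConfig
                          ) -> pd.DataFrame:
    """DSA of the motif panel per expression quartile (q1 lowest .. q4
    highest), plus mean splice-site strengths per quartile and a rank-sum
    test of strengths between the lowest and highest quartiles."""
    expr = read_expression_table(expression)
    models = [m for m in bundle.models if m.gene_id in expr]
    n_missing = len(bundle.models) - len(models)
    if n_missing:
        logger.info("excluded %d genes missing from the expression table", n_missing)
    rows = []
    if len(models) < 4:
        row = _empty_row("expression_strata", "all", config.motif)
        row["flags"] = "quartile-error"
        rows.append(row)
        return _finish(rows, config)
    vals = np.array([expr[m.gene_id] for m in models])
    edges = np.quantile(vals, [0.25, 0.5, 0.75])
    quart = np.searchsorted(edges, vals, side="right")  # 0..3

    policy = config.effective_policy()
    strata: dict[int, list[str]] = {q: [] for q in range(4)}
    for m, q in zip(models, quart):
        feats = [f for f in build_features(m, bundle.genome) if f.kind == "intron"]
        strata[q].extend(f.seq for f in trim_features(feats, policy, config.min_len))
    for q in range(4):
        for motif in tuple(config.panel) + tuple(config.controls):
            rows.append(_dsa_row("expression_strata", f"q{q + 1}", motif,
                                 strata[q], config))

    model_by_gene = {m.gene_id: m for m in models}
    for site_type, tag in [("five_prime", "5ss"), ("three_prime", "3ss")]:
        scores, _ = _score_introns(Bundle(bundle.genome, models), config, site_type)
        if scores is None:
            continue
        per_q: dict[int, list[float]] = {q: [] for q in range(4)}
        qmap = {m.gene_id: q for m, q in zip(models, quart)}
        for (gid, _ordinal), sc in scores.items():
            per_q[qmap[gid]].append(sc)
        for q in range(4):
            row = _empty_row("expression_strata", f"{tag}_strength_q{q + 1}", "")
            row["n_seqs"] = len(per_q[q])
            row["mean_score"] = float(np.mean(per_q[q])) if per_q[q] else math.nan
            rows.append(row)
        if len(per_q[0]) >= 2 and len(per_q[3]) >= 2:
            method = "exact" if min(len(per_q[0]), len(per_q[3])) < 20 else "asymptotic"
            u = stats.mannwhitneyu(per_q[0], per_q[3], alternative="two-sided",
                                   method=method)
            row = _empty_row("expression_strata", f"{tag}_strength_q1_vs_q4", "")
            row["p_value"] = float(u.pvalue)
            rows.append(row)
    return _finish(rows, config)


def run_geneset(bundle: Bundle, gene_ids, config: AnalysisConfig) -> pd.DataFrame:
    """DSA of the query motif versus its anagram controls over one gene set,
    with paired-bootstrap p-values and the set's mean 5'ss strength."""
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene-id list")
    idset = set(gene_ids)
    models = [m for m in bundle.models if m.gene_id in idset]
    sub = Bundle(bundle.genome, models)
    iseqs = [f.seq for f in trimmed_introns(sub, config)]
    rows = [_dsa_row("geneset", "introns", config.motif, iseqs, config)]
    for ctrl in config.controls:
        rows.append(_dsa_row("geneset", "introns", ctrl, iseqs, config))
        if len(iseqs) >= config.min_sample_n:
            res = compare_motifs(iseqs, config.motif, ctrl, max(config.n_boot, 99),
                                 _seed_for(config, f"geneset|{config.motif}_vs_{ctrl}"))
            row = _empty_row("geneset", f"{config.motif}_vs_{ctrl}", ctrl)
            row.update(dsa=res.delta_dsa, p_value=res.p_value,
                       flags="unreliable" if res.unreliable else "")
            rows.append(row)
    scores, _ = _score_introns(bundle, config, "five_prime")
    if scores is not None:
        set_scores = [s for (gid, _o), s in scores.items() if gid in idset]
        row = _empty_row("geneset", "5ss_strength_mean", "")
        row["n_seqs"] = len(set_scores)
        row["mean_score"] = float(np.mean(set_scores)) if set_scores else math.nan
        rows.append(row)
    return _finish(rows, config)


def run_all(bundle: Bundle, config: AnalysisConfig, outdir: str,
            expression=None, genesets: dict[str, list[str]] | None = None) -> None:
    """Run every applicable analysis and write one tidy TSV each."""
    os.makedirs(outdir, exist_ok=True)
    outputs = {
        "species_summary.tsv": run_species_summary(bundle, config),
        "distance_profile.tsv": run_distance_profile(bundle, config),
        "strength_profile.tsv": run_strength_profile(bundle, config),
        "position_classes.tsv": run_position_classes(bundle, config),
    }
    if expression is not None:
        outputs["expression_strata.tsv"] = run_expression_strata(
            bundle, expression, config)
    for name, ids in (genesets or {}).items():
        outputs[f"geneset_{name}.tsv"] = run_geneset(bundle, ids, config)
    for name, df in outputs.items():
        df.to_csv(os.path.join(outdir, name), sep="\t", index=False,
                  float_format="%.6g")
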