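"""Calibration and parameter-recovery experiments on synthetic genomes.

These routines drive the full pipeline — generate a synthetic bundle, parse
it back through the FASTA/GFF3 readers, extract and trim features, count —
and summarize how well known planted parameters are recovered.  They back
both the test suite and the reproduction script.

Key expectation: when forward occurrences of a motif are independently
removed with probability q and reverse-complement occurrences are left
alone, E[F] = (1 - q) * lambda and E[R] = lambda, so

    E[DSA] = ((1 - q) - 1) / ((1 - q) + 1) = -q / (2 - q).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .analysis_pipeline import (AnalysisConfig, Bundle, bundle_from_synthetic,
                                run_distance_profile, run_strength_profile,
                                trimmed_introns)
from .dsa_core import bootstrap_se, compare_motifs
from .synthetic_data import SyntheticConfig, generate_genome


def expected_dsa(q: float) -> float:
    """Analytic DSA under independent forward removal with probability q."""
    return -q / (2.0 - q)


def null_config(n_genes: int = 500) -> SyntheticConfig:
    """Standard null genome: symmetric composition, no depletion, 4 introns/gene."""
    return SyntheticConfig(n_genes=n_genes, exons_per_gene_law=("constant", 5),
                           depletion_base_q=0.0)


def analysis_config(seed: int = 0, **kw) -> AnalysisConfig:
    return AnalysisConfig(seed=seed, **kw)


@dataclass
class CalibrationResult:
    n_replicates: int
    n_within_3se: int
    dsa_values: list[float]
    se_values: list[float]
    rejections_at_05: int  # compare_motifs AATAAA vs TAAAAA, p <= 0.05

    @property
    def frac_within_3se(self) -> float:
        return self.n_within_3se / self.n_replicates

    @property
    def type_i_rate(self) -> float:
        return self.rejections_at_05 / self.n_replicates


def run_null_calibration(n_replicates: int = 200, n_genes: int = 500,
                         n_boot: int = 200, seed: int = 1) -> CalibrationResult:
    """Null genomes through the full pipeline: |DSA| vs 3*bootstrap-SE
    coverage of 0, and the type-I error of the paired motif contrast."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_replicates) % (2**31 - 1)
    cfg = null_config(n_genes)
    acfg = analysis_config()
    within = 0
    rejections = 0
    dsa_vals, se_vals = [], []
    for r in range(n_replicates):
        gb = generate_genome(cfg, seed=int(seeds[2 * r]))
        bundle = bundle_from_synthetic(gb, acfg)
        seqs = [f.seq for f in trimmed_introns(bundle, acfg)]
        res = bootstrap_se(seqs, "AATAAA", n_boot, int(seeds[2 * r + 1]))
        dsa_vals.append(res.dsa)
        se_vals.append(res.se_bootstrap)
        if abs(res.dsa) < 3 * res.se_bootstrap:
            within += 1
        contrast = compare_motifs(seqs, "AATAAA", "TAAAAA", n_boot=199,
                                  seed=int(seeds[2 * r + 1]))
        if contrast.p_value <= 0.05:
            rejections += 1
    return CalibrationResult(n_replicates, within, dsa_vals, se_vals, rejections)


@dataclass
class RecoveryResult:
    q: float
    expected: float
    dsa: float
    se: float

    @property
    def within_3se(self) -> bool:
        return abs(self.dsa - self.expected) <= 3 * self.se


def run_depletion_recovery(qs=(0.25, 0.5, 0.75), n_genes: int = 500,
                           n_boot: int = 200, seed: int = 2) -> list[RecoveryResult]:
    """Planted uniform depletion at several q; measured DSA vs -q/(2-q)."""
    out = []
    acfg = analysis_config()
    for i, q in enumerate(qs):
        cfg = replace(null_config(n_genes), depletion_base_q=float(q))
        gb = generate_genome(cfg, seed=seed * 1000 + i)
        bundle = bundle_from_synthetic(gb, acfg)
        seqs = [f.seq for f in trimmed_introns(bundle, acfg)]
        res = bootstrap_se(seqs, "AATAAA", n_boot, seed * 1000 + 500 + i)
        out.append(RecoveryResult(float(q), expected_dsa(q), res.dsa,
                                  res.se_bootstrap))
    return out


def gradient_config(q0: float = 0.6, tau: float = 400.0,
                    n_genes: int = 800) -> SyntheticConfig:
    """Long-intron genome for distance-gradient experiments (3 x 500-nt bins)."""
    return SyntheticConfig(n_genes=n_genes, exons_per_gene_law=("constant", 4),
                           intron_length_law=("lognormal", 3000, 0.4),
                           depletion_base_q=q0,
                           depletion_distance_decay_tau=tau)


@dataclass
class GradientResult:
    bin_dsa: np.ndarray  # (n_genomes, n_bins)
    n_b0_lt_b1: int
    n_b1_lt_b2: int
    n_genomes: int

    def sign_test_p(self, successes: int, alternative: str = "greater") -> float:
        from scipy.stats import binomtest
        return binomtest(successes, self.n_genomes, 0.5,
                         alternative=alternative).pvalue


def run_distance_gradient(n_genomes: int = 25, q0: float = 0.6, tau: float = 400.0,
                          seed: int = 3, n_genes: int = 800) -> GradientResult:
    """Per-genome DSA in the first three 500-nt bins from the 5'ss."""
    acfg = analysis_config(min_sample_n=200, distance_bins=3, n_boot=99)
    cfg = gradient_config(q0, tau, n_genes)
    ss = np.random.SeedSequence([seed, 55])
    seeds = ss.generate_state(n_genomes) % (2**31 - 1)
    mat = np.full((n_genomes, 3), np.nan)
    for g in range(n_genomes):
        gb = generate_genome(cfg, seed=int(seeds[g]))
        bundle = bundle_from_synthetic(gb, acfg)
        df = run_distance_profile(bundle, acfg)
        mat[g] = df["dsa"].to_numpy()[:3]
    b01 = int(np.sum(mat[:, 0] < mat[:, 1]))
    b12 = int(np.sum(mat[:, 1] < mat[:, 2]))
    return GradientResult(mat, b01, b12, n_genomes)


def coupling_config(q0: float = 0.4, coupling: float = 1.0, tau: float = 400.0,
                    n_genes: int = 500) -> SyntheticConfig:
    """Strength-coupled depletion decaying from the 5'ss, on long introns so
    the intron 3' end lies outside the depleted zone."""
    return SyntheticConfig(n_genes=n_genes, exons_per_gene_law=("constant", 5),
                           intron_length_law=("lognormal", 2000, 0.4),
                           depletion_base_q=q0,
                           depletion_distance_decay_tau=tau,
                           depletion_strength_coupling=coupling)


@dataclass
class CouplingResult:
    five_low_bin0: np.ndarray
    five_high_bin0: np.ndarray
    three_low_bin0: np.ndarray
    three_high_bin0: np.ndarray
    n_genomes: int

    @property
    def n_five_low_lt_high(self) -> int:
        return int(np.sum(self.five_low_bin0 < self.five_high_bin0))

    @property
    def n_three_low_lt_high(self) -> int:
        return int(np.sum(self.three_low_bin0 < self.three_high_bin0))


def run_strength_coupling(n_genomes: int = 20, q0: float = 0.4,
                          coupling: float = 1.0, tau: float = 400.0,
                          seed: int = 4, n_genes: int = 500) -> CouplingResult:
    """Per-genome bin-0 DSA for low vs high splice-site-strength quartiles,
    anchored at the 5'ss and, as a specificity control, at the 3'ss."""
    acfg = analysis_config(min_sample_n=50, strength_bins=1, n_boot=99,
                           maxent_order=1)
    cfg = coupling_config(q0, coupling, tau, n_genes)
    ss = np.random.SeedSequence([seed, 77])
    seeds = ss.generate_state(n_genomes) % (2**31 - 1)
    cols = {("5ss", "low"): [], ("5ss", "high"): [],
            ("3ss", "low"): [], ("3ss", "high"): []}
    for g in range(n_genomes):
        gb = generate_genome(cfg, seed=int(seeds[g]))
        bundle = bundle_from_synthetic(gb, acfg)
        df = run_strength_profile(bundle, acfg).set_index("sample_id")
        for tag in ("5ss", "3ss"):
            for lab in ("low", "high"):
                cols[(tag, lab)].append(float(df.loc[f"{tag}_{lab}_bin0", "dsa"]))
    return CouplingResult(np.array(cols[("5ss", "low")]),
                          np.array(cols[("5ss", "high")]),
                          np.array(cols[("3ss", "low")]),
                          np.array(cols[("3ss", "high")]),
                          n_genomes)
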