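# polyasym

DNA strand asymmetry of polyadenylation signals in spliceosomal introns.

## The problem

The hexamer AATAAA is the canonical polyadenylation signal (PAS): when
cleavage-and-polyadenylation factors bind it, the nascent transcript is cut
and polyadenylated.  A cryptic AATAAA inside an intron is therefore a
liability — it invites premature cleavage unless it is suppressed — and
selection is expected to purge it from transcribed strands.

Chargaff's second parity rule says that, absent selection or mutational
bias, a motif and its reverse complement occur at near-equal frequencies
within a single DNA strand.  Deviations from parity on the sense
(transcribed) strand are a signature of selection.  For a motif *m* counted
over a set of sense-oriented sequences this package measures

```
DSA(m) = (F − R) / (F + R)
```

where *F* is the pooled count of *m* and *R* the pooled count of its
reverse complement on the same strand.  DSA < 0 means the motif is
counter-selected; DSA > 0 means it is favoured (as AATAAA is at gene 3'
ends, where it works as the real PAS).

`polyasym` is a tested reimplementation of this analysis for annotated
genomes (FASTA + GFF3): gene-model assembly with isoform selection and
nested-gene removal, splice-signal-aware trimming of exons and introns,
motif counting and DSA with bootstrap errors and contrasts, six-mer
ranking, distance profiles from the 5' splice site, stratification by
maximum-entropy splice-site strength, intron position classes (first /
internal / last), expression strata and gene-set contrasts.  Because the
interesting patterns live in real genomes that are expensive to obtain and
have no ground truth, the package ships a synthetic-genome generator that
plants known AATAAA depletion — with tunable distance decay and
splice-site-strength coupling — so every stage of the pipeline can be
verified against an analytic expectation: removing forward occurrences
independently with probability *q* gives E[DSA] = −q/(2−q).

Intended users: genome-evolution and RNA-processing researchers who want a
reproducible strand-asymmetry pipeline, and anyone who needs a
planted-truth simulator to validate motif-selection inference.

## Worked example

Generate a 500-gene synthetic genome in which every intronic AATAAA
occurrence (outside the splice-signal margins) is removed with probability
q = 0.5, then run the genome-wide summary:

```python
from polyasym import (SyntheticConfig, generate_genome,
                      AnalysisConfig, bundle_from_synthetic)
from polyasym.analysis_pipeline import run_species_summary

cfg = SyntheticConfig(n_genes=500, exons_per_gene_law=("constant", 5),
                      depletion_base_q=0.5, seed=7)
bundle = bundle_from_synthetic(generate_genome(cfg), AnalysisConfig(seed=7))
report = run_species_summary(bundle, AnalysisConfig(seed=7))
print(report.query("sample_id == 'introns_all'")
      [["sample_id", "motif", "n_seqs", "F", "R", "dsa", "se"]])
```

Output (2000 trimmed introns):

```
  sample_id  motif  n_seqs       F       R    dsa    se
introns_all AATAAA    2000 439.000 949.000 -0.367 0.025
introns_all ATTAAA    2000 894.000 870.000  0.014 0.022
introns_all AATATA    2000 886.000 865.000  0.012 0.022
introns_all TATAAA    2000 916.000 818.000  0.057 0.026
introns_all TAAAAA    2000 867.000 894.000 -0.015 0.024
introns_all AAAAAT    2000 946.000 893.000  0.029 0.024
```

The depleted motif shows DSA = −0.37 ± 0.03, consistent with the analytic
−q/(2−q) = −1/3 at q = 0.5, while the three PAS-like hexamers and the two
anagram controls (same base composition, no PAS function) stay within ~2
standard errors of parity.  The same report also ranks AATAAA against all
4096 six-mers (here: percentile 0.0001, bottom-5% flag set).

The same analyses run from the shell:

```
polyasym simulate --config sim.cfg --out simdir --seed 7
polyasym run --fasta simdir/genome.fa --gff simdir/annotation.gff3 \
             --expression simdir/expression.tsv --out reports --seed 7
```

which writes one tidy TSV per analysis (species summary, distance profile,
strength profile, position classes, expression strata).

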