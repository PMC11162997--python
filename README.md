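# microjxn

Junction-read quantification of microexon splicing isoforms, with the cohort
analytics needed to characterize such an event across tissues, cancers, and
perturbation time courses.

## The problem

Microexons (3–30 nt) are routinely missed by exon-level quantification.  The
human ribosomal protein gene *RPS24* carries three of them (3, 18 and 22 bp)
between constitutive exons 4 and 6, producing four main splicing isoforms
that exon-based tools conflate.  Reads spanning splice junctions resolve the
ambiguity: every junction whose donor side abuts exon 4 names the next exon
in the mature transcript, and therefore the isoform the read supports.

For a sample with junction read counts `n_c` over isoform classes
`c ∈ {ex4:ex6, ex4:22bp, ex4:22bp/3bp, ex4:22bp/18bp, unclassified}`, the
package computes

    total = Σ_c n_c          (a proxy for overall gene expression)
    π_c   = n_c / total      (the isoform proportion; undefined when total = 0)

and then operates on the per-sample proportions: top-k tissue enrichment,
one-way ANOVA across molecular subtypes (with adjusted R² and a p < 0.001
flag), tumor-vs-normal deltas with Welch t-tests, Spearman trend tests for
EMT-style time courses, a splicing-factor screen flagging genes whose
maximum absolute Pearson correlation with an isoform proportion exceeds 0.4,
and a from-scratch pre-ranked GSEA (weighted Kolmogorov–Smirnov enrichment
score, gene-label permutation null, NES, nominal p, FDR).

A synthetic-data module generates Dirichlet-multinomial junction-count
cohorts, expression matrices with planted correlations, and logistic EMT
time courses — all with known ground truth, so every stage is testable
without consortium downloads.  The gene model is an editable YAML config
(`examples/rps24_model.yaml`); nothing is hard-coded to one locus.

## Worked example

Simulate a tumor/normal cohort whose true mean `ex4:22bp` proportions are
0.60 and 0.70, quantify it through the junction classifier, and test the
group difference:

```python
from microjxn.exon_model import build_classifier
from microjxn.junction_quant import aggregate_cohort, quantify_sample
from microjxn.cohort_stats import group_delta
from microjxn.synthetic_data import SimConfig, SimGroup, simulate_cohort, toy_gene_model

clf = build_classifier(toy_gene_model())
config = SimConfig(
    seed=7,
    groups=[
        SimGroup("tumor", 50, (60.0, 15.0, 14.0, 11.0)),   # mean ex4:22bp = 0.60
        SimGroup("normal", 50, (70.0, 12.0, 10.0, 8.0)),   # mean ex4:22bp = 0.70
    ],
    noise_fraction=0.001,
)
sim = simulate_cohort(config)
quants = [quantify_sample(recs, clf, sample_id=sid) for sid, recs in sim.records.items()]
cohort = aggregate_cohort(quants, sim.metadata)
print(cohort[["ex4:22bp", "ex4:ex6", "total", "group"]].head(3))

res = group_delta(cohort, "ex4:22bp", tumor_tag="tumor", normal_tag="normal")
print(f"delta = {res.delta:+.3f}, t = {res.t:.2f}, df = {res.df:.1f}, p = {res.p:.2e}")
```

Output:

```
            ex4:22bp   ex4:ex6  total  group
sample_id
tumor_0000  0.562023  0.179389   2096  tumor
tumor_0001  0.554752  0.146694   1936  tumor
tumor_0002  0.620520  0.136475   2037  tumor
delta = -0.107, t = -12.09, df = 96.6, p = 4.92e-21
```

Each row is one sample: its isoform proportions, its total exon-4 junction
reads (`total`, the expression proxy), and its group.  The comparison
recovers the planted −0.10 shift in `ex4:22bp` (here −0.107) and rejects
equality decisively.

The same pipeline is available from the shell:

```sh
microjxn simulate cohort --config sim.yaml --out simdir/
microjxn quantify --model examples/rps24_model.yaml --sj-dir simdir/ \
    --metadata simdir/metadata.tsv --out cohort.tsv
microjxn compare --cohort cohort.tsv --groups tumor,normal --out compare.tsv
```

`microjxn --help` lists the remaining subcommands (`enrich`, `trend`,
`screen`, `rank`, `gsea`, `run`).  Every output table carries a `#`
provenance header (tool version, config hash, seed) and a JSON sidecar.

## Layout

- `src/microjxn/exon_model.py` — gene model, validation, junction classifier
- `src/microjxn/junction_quant.py` — SJ.out.tab / junction-matrix readers, proportions
- `src/microjxn/cohort_stats.py` — tissue ranking, ANOVA, Welch tests, trend test
- `src/microjxn/correlation_screen.py` — splicing-factor screen and ranking
- `src/microjxn/gsea_preranked.py` — pre-ranked GSEA (ES/NES/p/FDR)
- `src/microjxn/synthetic_data.py` — ground-truth generators
- `src/microjxn/cli.py` — `microjxn` subcommands
- `docs/methods.md` — models, assumptions, parameter choices, limitations
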