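# dyadnet

Analysis pipeline for paired bacterial (16S, genus-level) and fungal (ITS2,
species-level) amplicon count tables from mother–infant dyads: compositional
diversity, ordination, PERMANOVA, dyad similarity testing, Procrustes
congruence, and prevalence-filtered interkingdom Spearman co-abundance
networks with an edges-per-node connectedness statistic. A synthetic cohort
generator with planted ground truth makes every stage testable end to end.

## Layout

| module | contents |
| --- | --- |
| `dyadnet.core_data` | `TaxaTable`, `SampleMetadata`, `DistanceMatrix`; TSV/BIOM-JSON readers and writers; sample alignment across kingdoms |
| `dyadnet.synthetic_data` | Gaussian-copula cohort generator: planted bacteria–fungus correlations, dyad-shared shifts, covariate effects, multinomial counts, prevalence thinning |
| `dyadnet.compositional_diversity` | CLR transform, Shannon/Simpson, Aitchison / Bray-Curtis / unweighted UniFrac distances, PCoA |
| `dyadnet.permanova` | sequential (Type-I SS) PERMANOVA with free label permutation |
| `dyadnet.dyad_similarity` | related vs unrelated mother–infant distance test via random derangements (per-repetition Wilcoxon + calibrated permutation p) |
| `dyadnet.congruence` | symmetric Procrustes m2 with Monte-Carlo significance |
| `dyadnet.interkingdom_network` | prevalence filter (≥30% inclusive), per-pair Spearman edges at uncorrected p < 0.05, connectedness = edges/nodes, network comparison, Fruchterman-Reingold layout, TSV/GraphML export |
| `dyadnet.diffabund` | Wilcoxon rank-sum (exact ≤ 20, else tie/continuity-corrected normal) with Hodges–Lehmann shift CI; Benjamini–Hochberg FDR, significance at q < 0.25 |
| `dyadnet.cli_pipeline` | YAML run config, stage orchestration, manifest, CLI |

Notable conventions: Simpson diversity is reported as the complement form
1 − Σp²; CLR uses a pseudocount of 1 by default; edge p-values are
deliberately **uncorrected** (an optional BH mode exists); the connectedness
denominator counts *all* prevalence-filtered taxa, including edgeless ones.

## CLI

```bash
dyadnet demo --seed 1 --out demo/                 # cohort + full pipeline run
dyadnet simulate --seed 1 --out cohort/           # synthetic cohort only
dyadnet run --config demo/run_config.yaml         # pipeline from a run config
dyadnet network --bact b.tsv --fung f.tsv --metadata m.tsv --out edges.tsv
dyadnet permanova --bact b.tsv --fung f.tsv --metadata m.tsv \
    --terms sample_type,birth_mode --out perm.tsv
dyadnet procrustes --bact b.tsv --fung f.tsv --metadata m.tsv
dyadnet dyadtest --bact b.tsv --fung f.tsv --metadata m.tsv
dyadnet diffabund --bact b.tsv --fung f.tsv --metadata m.tsv --out da.tsv
```

Count tables are TSV, taxa in rows (first column = taxon label), samples in
columns (header = sample ids). Metadata is TSV with mandatory columns
`sample_id, subject_id, dyad_id, sample_type, birth_mode` and four antibiotic
exposure flags. Trees are rooted newick with branch lengths (UniFrac only).
All randomness is seed-driven; reruns with the same config are byte-identical.

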