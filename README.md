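# amphievo

A desk-scale toolkit for the comparative molecular-evolution analyses used
in multi-species ortholog studies: supermatrix quality filtration,
fixed-topology hypothesis testing, lineage-specific selection scans,
rapidly evolving GO-category detection, parallel/convergent substitution
analysis, per-site conservation profiling, and qPCR ΔΔCt quantification.
A first-class synthetic-data module generates every input the pipeline
consumes, so the whole analysis chain is testable without downloads.

## Modules

| Module | What it does |
| --- | --- |
| `amphievo.synthetic_data` | GY94 codon and JTT+Γ protein alignment simulation, multispecies-coalescent gene trees, alignment corruption (missing data, GC bias), synthetic Ct tables |
| `amphievo.alignment_qc` | completeness, RCFV, chi-square composition tests, Bowker matched-pairs symmetry matrices, threshold-based gene filtration |
| `amphievo.topology_tests` | GTR+Γ fixed-topology ML (per-site log-likelihoods), AU test (multiscale RELL + WLS), per-hypothesis gene support counts, GAC step-matrix parsimony supertrees, MP-EST-style triplet pseudo-likelihood |
| `amphievo.codon_selection` | GY94 rate matrices, one/two/free-ratio branch models, branch-site Model A positive-selection scan (LRT + BH-FDR, NEB site posteriors), group dN/dS summaries with the >5 exclusion rule, 4-fold degenerate site rates |
| `amphievo.go_rego` | GO DAG handling with ancestor propagation, one-sided Wilcoxon REGO scan, development-proportion summaries |
| `amphievo.parallel_evolution` | marginal ancestral reconstruction (empirical AA + Γ), group-shared derived changes, parallel/common classification, Poisson chance probabilities |
| `amphievo.conservation_profile` | empirical-Bayes per-site rates, sign-flipped normalized conservation scores, GCV cubic smoothing spline |
| `amphievo.qpcr_ddct` | 2^−ΔΔCt relative quantification, Welch tests vs baseline with BH adjustment |

## CLI

Everything is reachable through the `amphievo` entry point; inputs are
plain-text FASTA / Newick / TSV / CSV:

```bash
amphievo simulate codon --tree sp.nwk --config sim.yaml --out gene.fasta
amphievo simulate genetrees --species-tree sp.nwk --n-genes 200 --out gts.nwk
amphievo qc gene1.fasta gene2.fasta --alphabet CODON61 --out-prefix qc
amphievo hypotheses gene*.fasta --topologies hypotheses.tsv --n-boot 10000
amphievo supertree gac --gene-trees gts.nwk
amphievo supertree mpest --gene-trees gts.nwk --species-tree sp.nwk
amphievo select feg gene*.fasta --tree sp.nwk --classes classes.yaml --fg-class salamander
amphievo select psg gene*.fasta --tree sp.nwk --classes classes.yaml --fg-class salamander
amphievo select fourfold gene.fasta --tree sp.nwk
amphievo rego --omega omega.tsv --annotation gene_term.tsv --dag term_parent.tsv
amphievo parallel --alignment aln.fasta --tree rooted.nwk --groups groups.yaml
amphievo conserve --alignment aln.fasta --tree tree.nwk
amphievo qpcr ct.csv --reference-gene ACTIN --baseline-time 0h
```

`sim.yaml` holds the simulation parameters (seed, n_sites, kappa, omega per
branch class, gamma shape, planted changes); `classes.yaml` maps branch-class
labels to clade taxa. Five backbone hypothesis topologies are bundled at
`amphievo/data/hypotheses.nwk` and can be expanded to resolved trees with
`amphievo.topology_tests.expand_hypothesis`.

## Notes

- Likelihood gauge: all rate matrices are scaled to one expected
  substitution per unit time at stationarity; branch lengths are expected
  substitutions per site (per codon for codon models).
- Branch-site site posteriors are naive empirical Bayes at the MLEs, not
  Bayes empirical Bayes.
- The bundled amino-acid model is JTT (`amphievo/data/jtt.dat`).
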