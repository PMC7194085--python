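# comphet

Composition-heterogeneous Bayesian phylogenetics in Python: curation of
multi-gene codon alignments, codon-degenerate recoding, Bayesian MCMC tree
inference under tree-homogeneous (CV1) and tree-heterogeneous (NDCH,
NDCH2) composition models, posterior-predictive X² adequacy testing,
marginal-likelihood estimation, a gene-genealogy-interrogation (GGI)
monophyly screen built on constrained ML and the AU test, and a
synthetic-data generator that reproduces the statistical pathologies these
methods are designed to handle (lineage-specific composition bias,
synonymous saturation, per-gene taxon dropout).

## Why

Deep-divergence phylogenies can be misled by two processes that simple
models absorb into topology:

* **among-lineage composition heterogeneity** — unrelated lineages with
  convergent base/amino-acid compositions attract each other;
* **synonymous saturation** — fast synonymous substitutions at third codon
  positions carry homoplasy rather than signal.

The remedies implemented here are **codon-degenerate recoding** (replace
each codon by an IUPAC-ambiguity pattern covering its synonymous family,
making synonymous differences invisible to the likelihood) and **NDCH2**
(a separate composition vector at every tree node, constrained by a
Dirichlet prior centered on the empirical composition with a sampled
concentration).  Model adequacy is checked by posterior-predictive
simulation of the X² composition-homogeneity statistic, and per-gene
reliability by a 15-constraint-topology AU screen.

## CLI

```bash
# synthetic attraction data set (codon mode emits sense codons only)
comphet simulate --mode codon --n-sites 5001 --n-genes 4 --seed 1 --outdir data/

# curation: occupancy/gene-length filters + concatenation
comphet curate data/manifest.yaml --min-occupancy 0.5 --min-gene-length 200 --out concat.fasta

# codon-degenerate recoding (with an auditable codon->pattern table)
comphet recode concat.fasta --out degen.fasta --dump-table-to degen_table.tsv

# Bayesian inference (cv1 | ndch | ndch2), one chain per call
comphet infer degen.fasta --mode ndch2 --alphabet degenerate \
    --iterations 20000 --seed 0 --out trace0.jsonl

# diagnostics and summaries
comphet consensus trace0.jsonl trace1.jsonl --out consensus.nwk   # + ASDSF
comphet ppred trace0.jsonl degen.fasta --alphabet degenerate --out ppred.json
comphet marglik trace0.jsonl --out marglik.json

# per-gene GGI screen (constrained ML + AU test per constraint topology)
comphet ggi data/manifest.yaml --groups groups.yaml --out ggi_report.tsv

# everything end-to-end from a YAML config
comphet run-all config.yaml
```

`run-all` executes curate → (recode|translate) → replicate MCMC chains →
ASDSF/marginal-likelihood convergence check (<0.01 and <10 log-units) →
majority-rule consensus with named-split support → posterior-predictive
X² test, persisting every intermediate with config-hash + seed provenance.
Convergence failure is flagged in the report, not fatal.

## Library layout

| module | contents |
| --- | --- |
| `comphet.msa_io` | FASTA/PHYLIP/NEXUS I/O, occupancy & gene filters, concatenation, translation |
| `comphet.recode` | degeneracy-table construction and codon-degenerate recoding |
| `comphet.phylo_model` | GTR/empirical rate matrices, discrete-gamma, pruning likelihood with per-node compositions (CV1/NDCH/NDCH2), PAML matrix reader (LG, JTT bundled) |
| `comphet.mcmc` | Metropolis-Hastings sampler (NNI, SPR, multipliers, Dirichlet proposals), priors, ASDSF, majority-rule consensus, convergence rule |
| `comphet.ppred` | X² composition statistic and posterior-predictive p-value |
| `comphet.marglik` | working-prior (Gelfand-Dey) marginal-likelihood estimator with bootstrap SE |
| `comphet.ggi` | constraint-topology enumeration ((2g-5)!!), constrained ML hill-climb, multiscale-RELL AU test, monophyly screen |
| `comphet.simdata` | sequence simulation (incl. codon mode with a synonymous-rate multiplier) and the attraction scenario builder |
| `comphet.pipeline` / `comphet.cli` | orchestration, provenance, CLI |

## Conventions worth knowing

* The branch leading into node *v* evolves under the rate matrix built
  from *v*'s composition vector; the root's vector is the root state
  distribution.  Every branch's Q is rescaled to one expected substitution
  per unit length under its own composition.
* Gap `-` and missing `?` are both fully ambiguous to the likelihood but
  distinguished in reports; degenerate-recoded data are handled purely via
  ambiguity-aware leaf partials.
* Occupancy filtering keeps columns *at* the threshold and operates on
  whole codons for codon data (per-column mode available).
* Chains are deterministic given their seed; every output file carries the
  config hash and seed.
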