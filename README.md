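# repeatscape

Transposable-element (TE) discovery and genome-community analysis from
**unassembled** whole-genome shotgun reads.

Most plant genomes are dominated by TEs, yet assembling a repeat-rich
genome just to measure its repeat content is wasteful: at even sub-1×
coverage, the reads themselves carry the signal.  `repeatscape`
implements a graph-based pipeline for exactly this setting, plus the
quantitative layers needed to treat a genome as an ecological
community of TE families:

1. **Read-level repeat discovery.**  Paired-end reads are quality- and
   complexity-filtered (PRINSEQ-style policy: min length 40, mean
   Phred ≥ 15, trinucleotide-entropy ≥ 60, right-end N trimming),
   optionally screened against organelle/contaminant sequences, and
   sampled.  An all-vs-all comparison (k-mer-seeded banded
   Smith–Waterman/Gotoh; match +1, mismatch −3, gap open −5,
   extend −2) builds a weighted read graph whose communities — found by
   seeded **Louvain modularity maximization** — are repeat clusters.
   Clusters spanned by enough mate pairs are merged.
2. **Annotation and genome composition.**  Each read in a cluster
   votes for its best hit in a repeat consensus library
   (RepBase-style, `>name<TAB>superfamily<TAB>family` headers); the
   cluster takes the plurality family.  A family's genomic fraction is
   its clusters' read share weighted by the supporting-vote fraction,
   estimated as mean ± SD over replicate samplings.
3. **Genome size.**  Reads are mapped to single-copy transcripts;
   with per-transcript depth `Cov_i = N/L` (aligned bases over
   transcript length, alignments ≥ 60 bp and ≥ 70 % identity), the
   genome size is `Cval = P · n · l / mean(Cov_i)` after trimming the
   top 10 % of transcripts by depth.
4. **TE community ecology.**  Treating families as species and copies
   as individuals, five rank-abundance/dominance models are fitted by
   Poisson maximum likelihood and ranked by `BIC = −2·logL + k·ln S`:
   brokenstick/Null (`(J/S)·Σ_{x=r}^{S} 1/x`, k=0), niche preemption
   (`J·α(1−α)^{r−1}`), lognormal (`exp(μ+σ·Φ⁻¹((S−r+½)/S))`), Zipf
   (`J·p·r^γ`) and Zipf–Mandelbrot (`J·c·(r+β)^γ`), together with
   Shannon diversity `H = −Σ p_i ln p_i` and evenness `E = H/ln S`.
5. **Phylogenetic signal.**  Blomberg's **K** (K = 1 under Brownian
   motion), significance by permutation of the phylogenetically
   independent contrast (PIC) variance, phylogenetic GLS under the
   Brownian tree covariance, and ordinary GLS trend tests of a trait
   against phylogenetic position.

A first-class synthetic-data module generates every input with a
ground-truth ledger — genomes with planted TE families (controllable
copy number, length, divergence, indels), paired reads (coverage, 100
bp reads, 400 bp inserts, base errors), transcript sets, pure-birth
trees and Brownian traits — so every layer is tested by parameter
recovery against planted truth.

## Worked example

Plant three superfamilies (Gypsy 30 %, Copia 15 %, L1 5 %) in a 1 Mb
genome, simulate 1× paired-end coverage, and run one
sample→cluster→merge→annotate pass:

```python
from repeatscape import synthetic, annotate

spec = synthetic.planted_superfamily_spec(seed=42)   # 1 Mb, 30/15/5 %
genome, ledger, library = synthetic.make_genome(spec)
pairs, _ = synthetic.simulate_reads(genome, coverage=1.0, seed=42)
comp = annotate.run_replicate(pairs, library, k=len(pairs), seed=7)
print(annotate.superfamily_composition(comp).round(4))
```

```
superfamily
unannotated    0.3082
Gypsy          0.2886
unclustered    0.2015
Copia          0.1513
L1             0.0504
```

The planted 30/15/5 % fractions come back as 28.9/15.1/5.0 % — within
about one percentage point at only 1× coverage.  `unclustered` is
mostly the single-copy background (reads with no similar partner);
`unannotated` is clustered sequence without a library hit, so the five
rows always sum to 1.

Fit the five RAD models to a ranked family-abundance vector:

```python
from repeatscape import ecology

fits = ecology.select_model([120, 60, 30, 15, 8, 4, 2, 1])
best = fits[0]
print(best.model, best.parameters, round(best.bic, 3))
```

```
Preemption {'alpha': 0.4959} -1490.655
```

The geometric series wins (each family takes ~half of what remains —
ΔBIC 4.3 to the runner-up Mandelbrot), and
`ecology.diversity(...)` reports `H = 1.3707`, `E = 0.6592` for the
same vector.  These fits agree with R `vegan::radfit` to printed
precision (cross-checked in the test suite).

Phylogenetic signal of a trait on a 4-tip tree:

```python
from repeatscape import phylo, seqio

tree = seqio.read_newick("((A:1.0,B:1.0):0.5,(C:0.7,D:0.7):0.8);")
res = phylo.k_significance(tree, {"A": 1.2, "B": 2.3, "C": 4.1, "D": 3.9},
                           n_perm=999, seed=1)
print(round(res.K, 4), round(res.p, 4))   # 1.4855 0.192
```

`K = 1.4855` matches `picante::Kcalc` on the same inputs.

## Command line

```bash
repeatscape simulate genome --seed 1 --out sim/       # planted genome + truth
repeatscape filter --in1 R1.fq --in2 R2.fq --out filt
repeatscape cluster --reads sample.fq --seed 1 --out clusters/
repeatscape annotate --clusters clusters/ --library repbase.fa --total 100000 --out comp.tsv
repeatscape genomesize --reads r.fq --transcripts t.fa --ploidy 2
repeatscape radfit --abundance comp.tsv --out radfit.json
repeatscape phylosignal --tree tree.nwk --traits traits.tsv --nperm 999 --seed 7
repeatscape run --config run.json                     # full pipeline + manifest
```

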