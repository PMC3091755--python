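# escapex

Sex-biased gene expression screening across mouse tissues, and discovery of
X-chromosome domains in which a protein-coding gene and a long non-coding RNA
jointly escape X-inactivation.

`escapex` is aimed at transcriptomics analysts working with sex-balanced bulk
expression data (microarray-style log2 intensity matrices). It packages the
full analysis chain as tested, reusable library functions plus a thin CLI:

1. **Array QC** — per-array standardization to mean 8 / SD 2; detection of
   sex-mislabeled arrays from Xist probe intensities (Xist is expressed
   almost exclusively in females, ~10⁴-fold); per-tissue sex balancing.
2. **Sex-bias screen** — per-probe two-sided Wilcoxon–Mann–Whitney tests,
   Benjamini–Hochberg FDR control (hits at adjusted p ≤ 0.05), and signed
   linear fold changes (positive = female-up, negative reciprocal =
   male-up).
3. **Chromosome enrichment** — observed vs expected significant genes per
   chromosome with a hypergeometric upper-tail test.
4. **Cross-tissue overlap** — Venn-region intersection of per-tissue hit
   lists within an array platform, and categorization of shared genes into
   known sex-linked / novel sex-linked / autosomal.
5. **Escapee domains** — pairing of female-biased non-coding X genes with
   their nearest female-biased coding X gene (within 50 kb or containing
   them), a permutation null for the observed co-localization, and
   H3K27me3 peak-coverage depletion scoring over the domains.
6. **qPCR validation** — standard-curve quantification, geometric-mean
   normalization to Actb/Gapdh, and Welch t-tests per gene and tissue.

A first-class synthetic-data module generates seeded datasets with known
ground truth (planted effects, mislabeled arrays, domain coordinates, peak
tracks, Ct tables), so every stage is verifiable without downloads.

## The co-localization statistic

The headline inference concerns four female-biased lncRNAs found next to
coding X-inactivation escapees. With the anchor set *A* = {Xist-like,
Jpx-like, and the coding escapee loci} held fixed, each permutation draws
k = 4 distinct non-anchor X-linked probes uniformly without replacement and
succeeds when **all four** fall within *w* = 50 kb of an anchor gene body:

```
FDR = (# permutations with all k probes within w of A) / n_perm,   n_perm = 10^4
```

The estimator has the closed-form expectation C(n_in, k) / C(n_total, k),
where n_in counts eligible probes inside the extended anchor windows — the
package exposes this as `analytic_coloc_probability` and the test suite uses
it as an independent oracle. At realistic probe densities the FDR rounds
to 0.00.

## Worked example

```python
from escapex import SimulationConfig
from escapex.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    simulation=SimulationConfig(
        n_tissues=2, samples_per_sex_per_tissue=60, n_probes=800,
        frac_sex_biased=0.03, mislabel_frac=0.02, seed=1,
    ),
    seed=1,
)
summary = run_pipeline(cfg)
print(summary.hit_counts)
print(summary.coloc_fdr, summary.coloc_successes)
for d in summary.domains:
    print(d["coding"], d["noncoding"], d["gap"], d["relation"])
```

prints

```
{'tissue1': {'female_up': 18, 'male_up': 13}, 'tissue2': {'female_up': 21, 'male_up': 9}}
0.0002 2
Ddx3x 2010308F09Rik 33000 head_to_head
2610029G23Rik 5530601H04Rik 9700 head_to_head
Eif2s3x D330035K16Rik 0 nested_intronic
Kdm5c D930009K15Rik 2600 tandem
```

Reading the output: each tissue screen recovered roughly the 3% of probes
carrying planted sex effects (the five QC-flagged mislabeled arrays were
excluded first — `summary.qc_flagged` lists them). The co-localization
permutation found 2 successes in 10⁴ draws (FDR 0.0002, printing as 0.00 at
two decimals), and all four planted coding/non-coding domains came back with
their exact gap distances — 33 kb head-to-head, 9.7 kb head-to-head, one
lncRNA nested in a host intron, and one 2.6 kb tandem pair. The same summary
carries per-chromosome enrichment (X and Y strongly over-represented,
e.g. tissue1 X: 12 observed vs 1.7 expected), H3K27me3 coverage (0.00 inside
every escapee domain vs ~0.66 in the flanks, while the X-inactivated Rps4x
control stays covered at 0.66), and the qPCR table (planted female/male
ratios of 1.3–1.8 recovered with `***`, Xist at ~1.3 × 10⁴, Rps4x `ns`).

The same stages are available from the shell:

```bash
escapex simulate --config sim.yaml --outdir data --seed 1
escapex screen --expr data/expression.tsv --meta data/samples.tsv \
    --annot data/annotation.bed --out hits.tsv
escapex coloc --annot data/annotation.bed --nperm 10000 --seed 1
escapex run --config run.yaml
```

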