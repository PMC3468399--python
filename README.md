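# protpair

Pairwise relative-expression biomarker discovery for label-free,
bottom-up proteomics.

Single-protein markers measured by LC-MS peak areas rarely separate two
clinical groups on their own: raw peak areas carry arbitrary per-run scale
factors and wide between-patient variation. `protpair` instead scores
**pairs**: within each sample it forms the intensity ratio of two peptides,
which cancels any common per-sample scale factor, and asks how well the
ratio distributions separate the two classes. Pair scores are rolled up
from peptides to proteins, assessed against a permutation null, and turned
into a one-threshold classifier evaluated by patient-grouped leave-one-out
cross-validation. The intended user is a proteomics analyst with a
peptide-by-sample peak-area matrix, a sample annotation (patient, class,
replicate), and a peptide-to-protein map — all plain TSV/CSV.

## The statistic

For peptides *i, j* and sample *k*, the relative abundance is
R<sub>ijk</sub> = I<sub>ik</sub>/I<sub>jk</sub>. With controls *C* and
progressors *P*, the **Discriminability Index** of the pair is

    d_ij = ( median(R^C_ij) − median(R^P_ij) ) / ( sd(R^C_ij) · sd(R^P_ij) )

evaluated on log-ratios by default (`ratio_scale="log"`), which makes the
index scale-free and orientation-antisymmetric; a literal raw-ratio mode is
available. All N·(N−1)/2 peptide pairs are scanned and ranked by |d|. For a
protein pair (P1, P2), **D(P1, P2)** is the median signed d over all
cross-protein peptide pairs, so a high |D| demands consistent,
same-direction discrimination across every constituent peptide pair; the
top-ranked protein pair maximises |D|.

Significance comes from rerunning the entire scan under patient-level
permutations of the class labels: empirical p-values are null exceedance
fractions, and the empirical FDR at threshold T is S_null/S_true with null
counts rescaled to the observed-set size. Predictive power is estimated by
leave-one-patient-out cross-validation of a single ratio-threshold
classifier refit from scratch in every fold; the reported rate is 1 − e/N.

## Worked example

```python
import protpair as pp

table, annot, pmap, truth = pp.generate_cohort(pp.SimConfig(seed=7))
ftable, fmap = pp.filter_min_peptides(table, pmap, min_peptides=2)
scores = pp.scan_peptide_pairs(ftable, annot)
ranked = pp.rank_protein_pairs(pp.aggregate_protein_pairs(scores, fmap))
print(ranked.head(3))
```

```text
protein_1 protein_2         D    abs_D  n_peptide_pairs  direction_consistency up_in_P
  PROT001   PROT011 -4.965431 4.965431                8                    1.0 PROT001
  PROT001   PROT027 -4.816513 4.816513               16                    1.0 PROT001
  PROT002   PROT018  4.508613 4.508613               12                    1.0 PROT018
```

The cohort (8 control / 13 progressor patients, 2 technical replicates,
50 proteins) carries one planted anti-correlated pair, PROT001 up and
PROT002 down in progressors. Every top-ranked pair involves a planted
protein, with `up_in_P` naming the member whose relative abundance rises
in progressors and all constituent peptide pairs agreeing on the direction
(`direction_consistency` 1.0). The `examples/` scripts continue from here:
permutation significance (`02`), cross-validation (`03`) and
identification-free MS1 feature scanning (`04`).

The same pipeline is available from the shell:

```sh
protpair simulate --seed 7 --out cohort/
protpair rank     --intensities cohort/intensities.tsv \
                  --annotation cohort/annotation.tsv \
                  --map cohort/peptide_map.tsv --out results/
protpair permtest --n-perm 100 --seed 0 ...   # adds p_value and fdr columns
protpair cv       ...                         # per-sample TSV + JSON summary
```

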