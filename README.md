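# beconcord

Cross-system molecular concordance analysis for Barrett's esophagus (BE).

Barrett's esophagus is a premalignant condition in which the squamous
epithelium of the distal esophagus is replaced by intestinal-type columnar
epithelium under chronic gastroesophageal reflux.  Researchers study it with
in vitro models (esophageal squamous cell lines such as Het-1A and EPC2
exposed to acidified bile-salt mixtures) and in vivo models (the
esophagogastroduodenal-anastomosis, EGDA, rat), but how faithfully each model
reproduces the human disease at the molecular level is an open question.

`beconcord` implements, as a tested and reusable pipeline, the analysis that
answers that question with a direction-concordance score:

1. **Marker-panel selection** (`beconcord.diffexpr`).  Two-group differential
   expression on probe × sample log2 matrices: logFC = mean(BE) −
   mean(normal); an empirical-Bayes *moderated t-statistic* in which the
   per-gene residual variance s²_g (df_g degrees of freedom) is shrunk
   toward a prior, s̃²_g = (d₀s₀² + df_g s²_g)/(d₀ + df_g), with
   hyperparameters (d₀, s₀²) estimated by moment matching of log s²_g; and
   Benjamini–Hochberg FDR adjustment.  A gene joins the BE marker panel when
   it is present in all datasets considered and at least one shows
   |logFC| > 2 with adjusted p < 0.05.  Applied to the packaged evidence
   table from three GEO comparisons of BE vs normal squamous biopsies
   (GSE13083, GSE34619, GSE1420) this yields the 23-gene panel: 10
   squamous-specific keratins down (KRT1, 4, 5, 6, 13, 14, 15, 16, 23, 24)
   and 13 columnar/intestinal genes up (KRT7, 8, 18, 20, TFF1–3, VIL1,
   MUC2, MUC3A/B, MUC5B, MUC6, MUC13).
2. **qPCR relative quantification** (`beconcord.qpcr`).  The 2^−ΔΔCt method
   with dual reference genes (ACTB/GAPDH): per sample ΔCt = mean target Ct −
   mean reference Ct; ΔΔCt against the untreated/intact condition;
   RQ = 2^−ΔΔCt.  Group significance on ΔCt by Student's t-test (two
   conditions) or many-to-one Dunnett comparisons (more), with the Dunnett
   adjusted p evaluated exactly by quadrature over the equicorrelated
   multivariate-t representation.  Direction calls require both "at least a
   two-fold" change (RQ ≥ 2 or ≤ 0.5, boundary inclusive) and p < 0.05;
   genes that never amplify are `na`, unassayed genes `nd`.
3. **Concordance scoring** (`beconcord.concordance`).  Each model system's
   per-gene call is compared with the human panel direction.  `nd` genes
   leave the denominator; `na` and `no_change` stay and never match.  A
   combined score counts a gene as matched if any listed system matches.
   On the packaged cross-system profile: rat 10/22 = 45%, EPC2 13/23 = 57%,
   Het-1A 6/23 = 26%, and the two cell lines combined 17/23 = 73% (floor
   rounding).
4. **Synthetic data** (`beconcord.simulate`).  Expression matrices with
   scaled inverse-chi-square gene variances and Ct tables generated from
   known fold changes, so every stage is testable with no downloads.

## Worked example

Score the packaged cross-system direction profile for the rat model:

```sh
barrett-concord concord \
    --profile src/beconcord/data/cross_system_profile.tsv --system rat
```

prints

```json
{
  "denominator": 22,
  "fraction": 0.45454545454545453,
  "matched_genes": ["KRT13", "KRT15", "KRT18", "KRT20", "KRT4", "KRT7",
                    "KRT8", "MUC13", "MUC2", "TFF3"],
  "matches": 10,
  "pct_floor": 45,
  "pct_nearest": 45,
  "pct_printed": 45,
  "rounding": "nearest",
  "systems": ["rat"],
  "venn": {}
}
```

i.e. 10 of the 22 panel genes evaluated in the rat (KRT6 was not determined
there and leaves the denominator) change in the same direction as in human
BE biopsies — the EGDA rat reflects about 45% of the clinical BE expression
profile.  The same command with `--combine het1a,epc2` gives the combined
in vitro score 17/23 (73% under floor rounding) together with the Venn
partition of the two cell lines' match sets.

From Python, the stages are statsmodels-style model/results pairs:

```python
from beconcord import ModeratedT, RelativeQuantifier, select_genes
from beconcord.io import packaged_evidence

panel = select_genes(packaged_evidence())          # the 23-gene panel
res = ModeratedT(dataset).fit()                    # DEResults: logFC, t, p, adj_p
quant = RelativeQuantifier(ct_table).fit()         # QuantResults: dCt, ddCt, RQ, p
print(res.summary())
```

A full pipeline run (selection → qPCR calling → concordance) is driven by a
flat YAML config: `barrett-concord run --config config.yaml`.

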