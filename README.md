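# nmrmarker

Marker discovery for multi-group ¹H-NMR metabolomics studies.

The package targets the standard clinical-NMR workflow used to ask whether
two treatment arms perturb the metabolome of several biological matrices
(serum, urine, tissue extracts) relative to a control group, and which
metabolites carry the difference. It implements the full chain:

1. **Preprocessing** — chemical-shift referencing (TSP at δ 0.00, or the
   left split of the lactate methyl doublet for serum), exclusion of
   residual-water and urea windows, binning into fixed 0.004 ppm buckets
   (2.4 Hz at 600 MHz), constant-sum normalization to 100, and
   probabilistic quotient normalization (PQN) against a control-group
   median reference to remove per-sample dilution.
2. **Chemometrics** — from-scratch NIPALS PCA, PLS-DA and OPLS-DA.
   For a two-class comparison with y ∈ {−1, +1}, OPLS-DA extracts one
   predictive component t = Xw (w ∝ Xᵀy) after iteratively removing
   orthogonal components w_o ∝ p − (wᵀp)w; the orthogonal rank is chosen
   by 7-fold cross-validated Q² improvement. Models report R²X, R²Y,
   Q² = 1 − PRESS/TSS, and a label-permutation p-value
   p = (1 + #{Q²_perm ≥ Q²_obs}) / (N_perm + 1) with 200 permutations.
3. **Marker selection** — the *enhanced four-dimensional volcano plot*:
   −log₁₀ of the Bonferroni-adjusted pooled-variance t-test p against
   log₂ fold-change, with circle size from the VIP quantile category
   (top 5% / 10% / 20% / rest 80%, VIP_j = √K·|w_j|/‖w‖ so ΣVIP² = K)
   and circle colour from |r|, the correlation of each variable with the
   predictive score. A metabolite is selected when |r| ≥ 0.6, VIP falls
   in the top 20%, adjusted p ≤ 0.05 and |log₂FC| ≥ 0.1.
4. **Power analysis** — Cohen's d (pooled SD) per selected marker and the
   exact noncentral-t power of the two-sided two-sample t-test at
   α = 0.01, n = 8 per group, plus a minimal-sample-size search.
5. **Pathway impact** — hypergeometric over-representation combined with
   topological impact (sum of relative betweenness centralities of the
   hit compounds); a pathway is flagged when impact ≥ 0.4 and
   −log₁₀(p) ≥ 2.

Because studies of this kind rarely deposit raw spectra, the package
ships a first-class synthetic-study generator: a 73-compound template
library rendered as Lorentzian multiplets on a uniform 0.0005 ppm grid,
with log-normal biological variation, per-sample dilution factors,
additive spectral noise, and planted shared / group-specific /
opposite-direction effects whose ground truth drives all recovery tests.

## Worked example

```python
from nmrmarker.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, sample_types=("serum",),
                                n_permutations=200))
res = report.per_sample_type["serum"]
for comparison, cres in res["comparisons"].items():
    d = cres["diagnostics"]
    sel = cres["markers"].query("selected")
    print(f"{comparison}-vs-control: R2Y={d['r2y']:.3f} Q2={d['q2']:.3f} "
          f"p_perm={d['p_perm']:.4f} n_orth={d['n_orth']} markers={len(sel)}")
```

prints

```
SMFY-vs-control: R2Y=0.991 Q2=0.924 p_perm=0.0050 n_orth=1 markers=10
GMFS-vs-control: R2Y=0.951 Q2=0.936 p_perm=0.0050 n_orth=0 markers=9
```

Both serum models are strongly predictive (cross-validated Q² > 0.9) and
survive the 200-permutation test at the smallest attainable p = 1/201.
The ten selected SMFY markers are exactly the ten planted ones; e.g. the
marker table shows lactate up (log₂FC = +0.91, VIP top 5%, |r| = 0.93)
and methionine down (log₂FC = −0.75), while the same metabolite comes out
*up* in the GMFS comparison — the opposite-direction pattern planted in
the generator. The companion power table reports d = 2.2–5.1 for the
selected markers, i.e. post-hoc power 0.90–1.00 at α = 0.01, n = 8.

The same pipeline is scriptable from the shell:

```
nmrmarker all --seed 1 --out results/run1        # full study, all matrices
nmrmarker simulate --seed 7 --out data/          # spectra + ground truth TSVs
nmrmarker preprocess --spectra data/spectra_serum.tsv \
    --metadata data/metadata.tsv --sample-type serum --out buckets.tsv
```

Every stage writes plain TSV/JSON artifacts (bucket matrices, score
tables, marker and power tables, enrichment tables, a checksummed run
manifest) and is independently re-runnable from the previous stage's
output.

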