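# pqtlmr

Proteome-wide **cis-pQTL Mendelian randomization** for drug-target
discovery: a tested, reusable pipeline that screens circulating proteins
for causal effects on cancer risk from GWAS/pQTL summary statistics, and
grades the hits into four drug-target tiers.

## Who this is for

Genetic epidemiologists who want the full discovery → validation →
prioritization chain — instrument selection, causal estimation,
direction checks, colocalization, replication, and drug-target
annotation — as one coherent, scriptable workflow, with a synthetic
summary-statistics generator so every stage can be exercised and
calibrated without access to consortium data.

## The method

Proteins are treated as exposures, instrumented by **cis-pQTLs** selected
by five criteria: genome-wide significance (P < 5×10⁻⁸), exclusion of
the MHC region (chr6: 26–34 Mb), LD clumping (r² < 0.001), cis location
(±1 Mb of the gene's TSS), and instrument strength F > 10, where
PVE = β²/(β² + n·se²) and F = PVE·(n−2)/(1−PVE).

For a protein with a single instrument the causal effect on disease is
the **Wald ratio** β̂ = β_out/β_exp (SE = se_out/|β_exp|); with k ≥ 2
instruments the fixed-effect **IVW** estimate Σwᵢβ̂ᵢ/Σwᵢ with wᵢ = 1/se(β̂ᵢ)²,
plus Cochran's Q for heterogeneity and MR-Egger's intercept for
directional pleiotropy. Effects are reported as odds ratios per SD of
genetically predicted protein; family-wise error is controlled by
Bonferroni over the number of proteins tested.

Discovery hits are then guarded and graded:

* **Steiger filtering** — instruments must explain more variance in the
  protein than in the disease (Fisher-z test on Σ z²/(z²+n));
* **bidirectional MR** — disease → protein analysis with genome-wide
  disease instruments; reverse-causal proteins are excluded;
* **Bayesian colocalization** — Wakefield approximate Bayes factors
  under a single-causal-variant model; five hypotheses H0–H4, priors
  p1 = p2 = 10⁻⁴, p12 = 10⁻⁵; the region colocalizes when PPH4 ≥ 0.8;
* **external replication** — same-variant and significant-variant
  strategies in an independent pQTL/outcome dataset at P < 0.05 with
  consistent direction;
* **PPI drug linkage** — a STRING-style network (combined score ≥ 0.4)
  connecting the protein to targets of existing drugs for the indication;
* **tier classification** — tier 1: colocalizes and replicates; tier 2:
  drug-linked and replicates; tier 3: exactly one line of evidence;
  tier 4: the rest.

## Worked example

Simulate a 20-protein study (one causal protein, one reverse-causation
protein) and run the whole workflow:

```bash
pqtlmr all --out demo/ --seed 17 --n-proteins 20 --fraction-causal 0.05 --n-reverse 1
# 2 significant, 1 tier-1 target(s); outputs in demo/
pqtlmr report --results demo/
#  tier  count
#     1      1
#     2      0
#     3      0
#     4      0
```

Two proteins clear the Bonferroni threshold (0.05/20 = 2.5×10⁻³ here):
the planted causal protein P013 and the reverse-causation protein P012.
The manifest records what happened to each:

```
{'n_significant': 2, 'excluded_reverse_causal': ['P012'], 'bonferroni_threshold': 0.0025}
```

P012 is flagged by bidirectional MR (the "protein" signal is really a
disease locus) and excluded; P013 survives every gate and is the sole
tier-1 target:

```
protein  outcome  replicated  coloc_pass  ppi_drug_link  tier
P013     cancer   True        True        False          1
```

`demo/mr_results.tsv` holds the per-protein estimates (OR, 95% CI, P,
PVE, F, Steiger and bidirectional columns), `demo/coloc_results.tsv` the
PPH0–PPH4 posteriors, and `demo/volcano.tsv` the ln(OR) vs −log10(P)
plot data.

The same stages are available as library functions
(`pqtlmr.build_instruments`, `pqtlmr.ivw`, `pqtlmr.coloc_abf`,
`pqtlmr.steiger_test`, `pqtlmr.classify_tier`, …) operating on
`GwasRecord`/`HarmonizedPair` objects; `pqtlmr.simulate_region` and
`pqtlmr.simulate_proteome` generate summary statistics with known truth.

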