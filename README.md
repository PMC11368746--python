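# mrnetwork

Two-sample Mendelian randomization (MR) at the scale of a trait *universe*:
instead of estimating one exposure–outcome effect, `mrnetwork` screens every
ordered pair of immune-cell phenotypes, circulating immune proteins and
sarcopenia traits, assembles the significant estimates into directed signed
causal networks, and ranks the hub traits by a rank-sum consensus over twelve
centrality algorithms.

It is written for biostatisticians and genetic epidemiologists who work with
GWAS/pQTL summary statistics and want a tested, reproducible implementation
of the full screening design — including a synthetic-data generator with a
known causal graph, so every stage can be validated against ground truth
before touching real data.

## The method

For an exposure *X* and outcome *Y*, each genetic instrument *j* contributes
a Wald ratio θ̂ⱼ = β̂_Yj / β̂_Xj. The inverse-variance-weighted (IVW)
estimate is the zero-intercept weighted regression of β̂_Yj on β̂_Xj with
weights 1/se²(β̂_Yj):

  β̂_IVW = Σⱼ wⱼ β̂_Xj β̂_Yj / Σⱼ wⱼ β̂²_Xj,  wⱼ = se⁻²(β̂_Yj)

Seven estimators are fitted per pair — multiplicative random-effects IVW
(the main model), fixed-effect IVW, robust (Tukey-biweight) IVW, MR-Egger
(slope + pleiotropy intercept), weighted and simple median, and the weighted
mode — together with Cochran's Q, the Egger intercept test, and MR-PRESSO
outlier detection and pruning.

Instruments pass six filtration steps before estimation: association with
the exposure at p < 5×10⁻⁶, LD/distance clumping, removal of variants
instrumenting more than one exposure of the analysis group, removal of
confounder-associated and outcome-associated variants, and allele
harmonization (strand flips, frequency-based orientation of palindromes).
Per-IV strength is reported as R²ⱼ = 2β̂²_Xj·EAFⱼ(1−EAFⱼ) and
Fⱼ = (N−2)R²ⱼ/(1−R²ⱼ).

Five analysis groups cover the design: cells→sarcopenia traits and the
reverse, proteins→sarcopenia traits and the reverse, and bidirectional
cell↔protein runs for couples that share a significant sarcopenia
association. Benjamini–Hochberg FDR is applied per (group, model, outcome)
family. Significant main-model results become edges (exposure → outcome,
sign = sign of β̂); per-outcome maps are integrated into a comprehensive
network and pruned to a final map (immune nodes need ≥ 2 causal links and a
direct FDR-significant sarcopenia edge). Node importance is the rank sum
over MCC, MNC, DMNC, Degree, EPC, BottleNeck, EcCentricity, harmonic
Closeness, Radiality, Betweenness, Stress and the Clustering Coefficient.

## Worked example

The built-in scenario simulates 20 immune-cell traits, 8 immune proteins and
2 sarcopenia outcomes with 12 true causal edges (effects 0.15–0.4, n =
200,000 per GWAS, 5% balanced pleiotropy, 2% outlier instruments):

```python
import mrnetwork as mr

graph, arch = mr.default_scenario(seed=1)
registry, sumstats = mr.simulate_universe(graph, arch)
study = mr.run_study(registry, sumstats, seed=1)

main = study.results.query(
    "method == 'RE_IVW' and exposure == 'cell_01' and outcome == 'grip_strength'"
)
print(main[["beta", "se", "pval", "fdr", "nsnp"]].to_string(index=False))

edges = study.edges("fdr")
print(f"{len(edges)} FDR-significant causal edges")

net = mr.build_trait_network(edges, "grip_strength", registry, threshold_kind="fdr")
scores = mr.compute_scores(net, mr.CentralityConfig(seed=1))
immune = [v for v in net if registry[v].trait_class in ("cell", "protein")]
report = mr.rank_sum(scores, nodes=immune)
print("grip-strength map:", net.number_of_nodes(), "nodes /", net.number_of_edges(), "edges")
print("top hub traits:", report.top_k[:3])
```

which prints:

```
    beta       se         pval          fdr  nsnp
0.332153 0.029938 1.332081e-28 8.880537e-28    15
21 FDR-significant causal edges
grip-strength map: 6 nodes / 8 edges
top hub traits: ['prot_01', 'cell_04', 'cell_08']
```

`cell_01 → grip_strength` has a true effect of 0.30; the RE-IVW estimate
0.33 ± 0.03 recovers it from the 15 instruments surviving filtration and
MR-PRESSO, and survives the B-H correction. The 21 FDR edges recover all 17
nonzero total effects among the tested pairs (the extra edges are the cost
of screening ~300 pairs at FDR 0.05 with contaminated instruments). In the
grip-strength map, `prot_01` — the protein mediating `cell_04`'s effect on
grip strength — tops the rank-sum consensus.

The same run is available from the shell:

```sh
mrnetwork simulate --seed 1 --out data/
mrnetwork run --registry data/registry.yaml --seed 1 --out results/
mrnetwork report --run-report results/run_report.json
```

which writes the MR result and sensitivity tables, per-step instrument
provenance, per-trait networks (CSV/GraphML/SIF), the comprehensive and
final maps, and the centrality reports.

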