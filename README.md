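# npxscreen

Treatment-specific protein screening for two-arm, two-timepoint targeted
proteomics trials on the Olink NPX scale.

## The problem

A small randomized trial measures a targeted protein panel (e.g. 92
cardiovascular assays) in both arms before and after an intervention.  Any
single contrast confounds what the investigator actually wants — proteins
the *treatment* moved — with two nuisance signals: proteins drifting over
time in everyone (disease course, storage, season) and proteins that
differed between arms already at baseline (imbalance despite
randomization).  `npxscreen` implements the analysis chain that separates
these: per-protein moderated-t differential expression over six contrasts,
an orthogonal set-algebra screen, clinical-score correlations,
random-forest importance ranking, and hypergeometric enrichment — plus a
synthetic-cohort generator with planted ground truth so the whole chain is
verifiable by parameter recovery without any external data.

## The model

With trial cells T1/T2 (treatment baseline/post) and C1/C2 (control
baseline/post), six contrasts are computed: unpaired G1: T2 vs C1,
G2: C2 vs T1, G3: T1 vs C1, G4: T2 vs C2, and paired (within-subject)
P1: T2 vs T1, P2: C2 vs C1.  NPX is already a log2-scale unit, so each
effect estimate is directly a log2 fold change.

Each contrast reduces protein *g* to an effect `b_g`, residual variance
`s²_g` on `d_g` degrees of freedom, and unscaled standard error `u_g`.
Variances are shrunk toward a panel-wide empirical-Bayes prior
`(d₀, s₀²)`, estimated from the observed log-variances by method of
moments, giving the moderated statistic

```
s̃²_g  = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
t_g   = b_g / (s̃_g · u_g)      ~  t(d₀ + d_g)  under the null
```

The screen then applies set algebra at a significance threshold α:

* **Set 1** — no baseline difference (G3 p > α) but a post-intervention
  arm difference (G4 p < α)
* **Set 2** — time-dependent: changed in the control arm (P2 p < α)
* **Set 3** — treatment-responsive: changed in the treatment arm (P1 p < α)
* **Set 4** = Set 1 \ Set 2, **Set 5** = Set 1 ∩ Set 3
* **core** = Set 3 ∩ Set 4 ∩ Set 5 ≡ (Set 1 ∩ Set 3) \ Set 2 — the
  treatment-specific candidates.

Downstream, Spearman correlations relate proteins to clinical scores
(NIHSS 0–42, ESRS 0–9), a bagged forest ranks the Set-3 proteins by
out-of-bag permutation and Gini importance, and over-representation of the
sets against user-supplied GMT term collections is tested with the exact
hypergeometric upper tail.

## Worked example

```python
from npxscreen import (AnalysisConfig, SimulationConfig, simulate_full,
                       validate_design, run_contrasts, build_screen_sets,
                       evaluate_recovery)

config = SimulationConfig(seed=1)          # 22+22 subjects, 92 proteins
matrix, truth = simulate_full(config)
design = validate_design(matrix)

acfg = AnalysisConfig(alpha=0.05)
results = run_contrasts(matrix, design, acfg)
for name in ("G1", "G2", "G3", "G4", "P1", "P2"):
    n_sig = int((results[name].p < acfg.alpha).sum())
    print(f"{name}: {n_sig} significant proteins")

sets = build_screen_sets(results, acfg)
print("cardinalities:", sets.cardinalities())
report = evaluate_recovery(sets, truth)
print(f"sensitivity={report.sensitivity:.2f}  "
      f"time-dependent leakage={report.leakage['time_dependent']:.2f}")
```

prints

```
G1: 24 significant proteins
G2: 18 significant proteins
G3: 2 significant proteins
G4: 17 significant proteins
P1: 27 significant proteins
P2: 20 significant proteins
cardinalities: {'set1': 17, 'set2': 20, 'set3': 27, 'set4': 11, 'set5': 13, 'core': 9}
sensitivity=0.90  time-dependent leakage=0.00
```

This cohort planted 10 treatment-specific, 10 time-dependent and 5 mixed
(time + treatment) proteins among 67 nulls.  G3 is nearly empty (the arms
are exchangeable at baseline), P1 picks up both treatment and time effects,
and the core recovers 9 of the 10 planted treatment-specific proteins while
admitting none of the purely time-dependent ones — the screen's purpose.

## Command line

```sh
npxscreen simulate --out-dir sim --seed 3          # synthetic cohort files
npxscreen run --config config.yaml --out-dir out   # full pipeline -> TSVs + summary.json
npxscreen replicate --config deposit.yaml          # computed-vs-published count table
npxscreen report --out-dir out                     # re-print a run's summary
```

A config names either real input files (`input: {npx: …, annotations: …}`
— long-format CSV/TSV with case-insensitive header aliases) or a
`simulation:` block; `analysis:` sets α, the fold-change cut, the DEP
membership rule (`p_only` or `p_and_fc`) and forest settings;
`enrichment: {gmt: …}` enables the enrichment stages.  The `replicate` verb
expects the emulated study's deposited tables (Zenodo DOI
10.5281/zenodo.16551369) downloaded locally.

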