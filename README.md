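# improcoord

Coordination analysis for large, freely improvising musical ensembles —
groups that play without a score, a shared plan, or a conductor.

The package answers two questions about such a group from 1 Hz behavioral
time series: do the musicians *interact* (mutually forward-predict each
other), and are those interactions *coordinated* toward a group outcome
(co-playing and turn-taking, congruent intentions, group-wide alignment at
specific phases of the piece)? It works from two matrices per performance —
a binary **musical action** matrix (musician × second: playing or silent)
and a continuous **directional intention** matrix in [0, 1] (0 = intend to
change the group's music, 1 = support it, 0.5 = neutral) — plus an expert
segmentation of the piece into formal sequences and per-musician metadata.
Because such behavioral recordings are rarely shared, a synthetic ensemble
generator with known ground-truth coupling makes every stage testable.

## The statistics

For each unordered pair of musicians *(a, b)*:

- **Causal density** — Granger causality is computed in both directions by
  a restricted-vs-unrestricted OLS F test with *L* lags (default *L* = 16 s);
  causal density is the mean of the two significance indicators,
  (1[p_ab < α] + 1[p_ba < α]) / 2 ∈ {0, ½, 1}. Series are
  checked for stationarity (augmented Dickey–Fuller) and linearly
  detrended when the test fails to reject.
- **Correlation** — Spearman's ρ between action series, Pearson's ρ between
  intention series, with pairs classified positive / negative / none at α.
- **Sonic organization** — |ρ| of the action correlation: organization
  regardless of sign, so co-playing and turn-taking both count.
- **Mean slider distance** — mean over t of |x_t − y_t| between two
  intention series.

Chance levels come from **time-scrambled surrogates**: independent uniform
permutations of each series' time indices, which keep the value
distribution and destroy temporal structure. Real and surrogate metrics
are compared with paired t tests and Cohen's d.

At the group level, per second: the percentage of musicians playing, the
mean slider value, and **group alignment**
|#{x_i > 0.5} − #{x_i < 0.5}| / N (1 = unanimous direction, 0 = even
split; exactly-neutral sliders count in neither camp). Alignment inside
±16 s windows around each sequence's temporal middle is contrasted against
windows around the junctions between sequences (Welch t test).

Finally, coordination outcomes are regressed on relational factors
(pair familiarity, seats-between spatial proximity, same-instrument-family
indicator) in linear mixed models with crossed random intercepts for the
two pair members, and on individual factors (expertise, familiarity with
others, spatial eccentricity, instrument family as three pairwise
contrasts) in robust-SE OLS, each term with a likelihood-ratio χ².

## Worked example

```python
import improcoord as ic

rec, truth = ic.generate_ensemble(ic.SimulationConfig(rng_seed=1))
cfg = ic.AnalysisConfig(max_lag=16, n_surrogates=20, rng_seed=1)

pairs = ic.all_pairs(rec, "intentions", cfg)
res = ic.compare_to_null(
    [p.mean_slider_distance for p in pairs],
    [p.null_distance.mean for p in pairs],
)
print(f"{len(pairs)} pairs; mean slider distance "
      f"{res.mean_real:.3f} (real) vs {res.mean_null:.3f} (scrambled), "
      f"t({res.df}) = {res.t:.2f}, p = {res.p:.2g}, d = {res.d:.2f}")

align = ic.alignment_series(rec.intentions)
mid = ic.window_indices(rec.segmentation, "middle", 16)
jct = ic.window_indices(rec.segmentation, "junction", 16)
contrast = ic.compare_windows(align, mid, jct)
print(f"alignment: middle {contrast.mean_real:.2f} vs junction "
      f"{contrast.mean_null:.2f}, Welch t = {contrast.t:.2f}, p = {contrast.p:.2g}")
```

prints

```
66 pairs; mean slider distance 0.221 (real) vs 0.241 (scrambled), t(65) = -8.31, p = 8.2e-12, d = -1.02
alignment: middle 0.66 vs junction 0.24, Welch t = 19.88, p = 1.9e-64
```

The 12 slider musicians form 66 pairs; their intentions sit significantly
closer together than time-scrambled chance (the negative t means the real
distance is smaller), and group alignment peaks mid-sequence and collapses
at the junctions between sequences — the generator's attractor schedule,
recovered by the analysis.

The same analysis runs from the shell:

```sh
improcoord simulate -c examples/config.yml -o recording/   # five CSVs + ground_truth.json
improcoord analyze  -c examples/config.yml -i recording/ -o out/
improcoord report   -i out/
```

`out/` contains per-pair tables (`pairs_actions.csv`, `pairs_intentions.csv`),
per-second group metrics, window indices, factor tables, regression
results, a run manifest with file digests, and a markdown report.

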