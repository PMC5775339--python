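# dietshift

Seabird diet samples as ecosystem indicators: a tested Python pipeline from
per-bird regurgitate records to diet-composition indices, regime-shift
(change-point) detection, Arctic-vs-Atlantic permutation comparisons,
environmental correlation and community ordination.

Surface-feeding seabirds such as black-legged kittiwakes collect small fish
and zooplankton near the sea surface and regurgitate stomach contents when
handled. A long annual series of such samples is a window on a pelagic
ecosystem that is otherwise expensive to survey — in Arctic fjords it can
reveal "Atlantification", the replacement of Arctic prey (polar cod,
*Themisto libellula*) by Atlantic species (capelin, herring). `dietshift` is
for ecologists who hold this kind of long-format diet table and want the full
indicator analysis as reproducible, scriptable components rather than a
one-off analysis script.

## What it computes

**Diet indices** per prey category *c* over a scope of *n* samples (*N* of
which contain *c*):

- FO = 100·N/n — frequency of occurrence (%); presence-based, so it bridges
  early presence/absence-only records with later weighed samples;
- WW = mean over all samples of *c*'s wet mass (g), zeros included;
- MM = mean over only the samples containing *c* (g), so WW = MM·N/n exactly;
- AP = mean over samples of 100·(mass of *c*)/(total sample mass) (%).

**Regime detection**: an annual series *y(t)* is fitted by OLS under five
mean structures — constant, linear, a step (one mean per regime), a shared
slope with an intercept shift, and separate lines per regime — with every
admissible break year scanned exhaustively and the winner chosen by AICc
(small-sample Akaike criterion; near-ties go to the simpler form). A break
between years *y* and *y+1* is reported as *y*, the last year of the previous
regime.

**Permutation comparison**: per year, every sample's summed Arctic-prey and
Atlantic-prey mass enters a two-sample test on the difference of means,
enumerated exactly when C(nₐ+n_b, nₐ) ≤ 10,000 and otherwise Monte-Carlo with
p = (#{|T*| ≥ |T|}+1)/(n_perm+1).

**Environmental toolkit**: an annual sea-ice index from daily gridded
concentrations (block mean → daily mean → monthly mean → mean of 12 monthly
values), volume-weighted fjord temperature Σ T(z)A(z)Δz / Σ A(z)Δz, OLS trend
fits, linear detrending, and Pearson correlation with Fisher-z 95% CIs
(significant iff the CI excludes 0) on raw and detrended series.

**Community structure**: Bray-Curtis dissimilarity between years on the
year × taxon FO matrix, Ward (D2) hierarchical clustering with Newick export,
and non-metric MDS (Kruskal stress-1) with taxa placed at
occurrence-weighted averages of year coordinates.

**Fish morphometrics**: otolith pairing, per-species linear otolith-to-fish
length regressions (config-supplied), and age-class assignment by ordered
length cutoffs.

**Synthetic data**: a generator emulating the study design the analysis
assumes — ~879 samples over 19 sampling years, a step change in occurrence
probabilities after a configurable regime year, right-skewed lognormal meal
masses, trending covariates — so the whole pipeline runs and is validated
without any external data.

## Worked example

```sh
python examples/02_regime_shift.py
```

```
best model: constant_changepoint, break year 2006
regimes: ['1982-2006', '2007-2016']
          term  estimate       se         t            p
 intercept_pre  82.36715 2.324886 35.428466 2.254804e-17
intercept_post  33.26087 2.205581 15.080323 2.844491e-11

ranking (lower AICc = better):
                          form  changepoint_year  n_params          rss       aicc  delta_aicc
          constant_changepoint            2006.0         2   826.979626  79.293481    0.000000
            linear_changepoint            2006.0         3   777.336374  81.374392    2.080912
linear_interaction_changepoint            2006.0         4   776.571224  85.113923    5.820442
                        linear               NaN         2  4410.039129 111.096797   31.803317
                      constant               NaN         1 12249.527410 127.657269   48.363789
```

The script simulates a diet table (seed 42), computes annual Arctic-prey
occurrence, and runs model selection. The step form wins decisively
(ΔAICc ≥ 2 over every rival) and places the break at 2006 — the year the
generator was configured to switch regimes; the two intercepts (82.4% and
33.3%) estimate the per-regime mean occurrence. One narrative script per
capability lives in `examples/`.

The same analyses run from the shell: `dietshift simulate`, `dietshift
indices`, `dietshift regimes`, and `dietshift run --config run.yaml` for the
full pipeline (index tables, regime fits, per-year comparisons, correlations,
dissimilarities, dendrogram, ordination, morphometrics, plus a MANIFEST and
summary; byte-identical under a fixed seed).

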