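# spastocsy

Automated, untargeted metabolite identification in 1D ¹H-NMR spectra by
**SPA-STOCSY**: spatial clustering of spectral datapoints on a smoothed
correlation landscape (SPA), statistical total correlation spectroscopy
(STOCSY) grouping of the clusters, and matching of the groups against a
metabolite reference library. The package also ships an NMR spectrum
simulator with ground-truth bookkeeping, the SRV (Statistical Recoupling of
Variables) baseline clusterer, and coverage/identification scoring, so the
whole method can be exercised and validated end-to-end without any external
data.

It is written for NMR metabolomics practitioners and method developers who
have a set of preprocessed, aligned 1D spectra (a samples × chemical-shift
intensity matrix) and want reproducible, operator-free candidate metabolite
calls.

## The method

Given spectra `x_i(f)` on a common ppm grid (samples `i = 1..n`, datapoints
`f = 1..p`):

1. **Preprocessing** — probabilistic quotient normalization removes
   per-sample dilution; datapoints below `5·SD` of a user-chosen noise
   region are set to zero (baseline regions otherwise show spuriously high
   cross-sample correlations).
2. **SPA** — the *correlation landscape* at window start `j` is the mean of
   all `k(k−1)/2` pairwise Pearson correlations (across samples) among
   columns `j..j+k−1`:

   `Q_j = 2/(k(k−1)) · Σ_{a<b} ρ(x_{·j+a}, x_{·j+b})`

   The window `k` is selected as the smallest lag at which the partial
   autocorrelation function of the spectrum falls inside its 95% confidence
   band. The landscape is smoothed with a tricube (or Epanechnikov) kernel,
   and maximal contiguous runs with `Q ≥ λ` become spatial clusters —
   stretches of datapoints belonging to one structural unit (multiplet) of
   one metabolite. The threshold `λ` can be selected by prediction-strength
   cluster stability (split samples in half, cluster each half, score the
   median fraction of within-cluster variable pairs co-clustered in the
   other half; take the smallest `λ` within one standard error of the
   maximum) or set manually.
3. **STOCSY** — each cluster is reduced to a per-sample representative
   intensity (mean of its local-maxima peaks); clusters whose
   representatives correlate at `r ≥ 0.8` (calibratable on an internal
   standard such as DSS) are joined into connected components: putative
   same-molecule groups.
4. **Identification** — a library cluster is detected when one of its
   reference peaks lies within ±0.025 ppm of a peak of a group; each
   metabolite's *detection ratio* is the best fraction of its library
   clusters (in the 0.5–4.0 ppm window) detected by a single group, and a
   metabolite is identified when the ratio exceeds 0.55 (a nine-cluster
   metabolite needs five detected clusters). A *singlet filter* admits
   single-cluster metabolites only when their group is self-correlated.
   Groups matching nothing are reported as unannotated candidates.

The simulator generates `y_i(f) = S_i(f) + N_i(f)` with
`S = (HΣ + 1_n αᵀ) M`: synthetic reference spectra `M` (Lorentzian
multiplets, each row scaled to max 1), population concentrations
`α_l ~ χ²(γ)`, per-sample variation `H_il ~ N(0, φ²)`, metabolite
correlation `Σ`, and stationary AR(1) noise with coefficient `ρ = 0.9`.

## Worked example

Simulate the standard benchmark — 10 metabolites drawn from a 50-metabolite
synthetic library, `γ=60`, `φ=12`, `n=50` spectra, AR(1) noise — and run the
full pipeline:

```python
import spastocsy as st

observed, sampled, library_ref, noise_region = st.identification_scenario(seed=1)
library = st.MetaboliteLibrary.from_reference_spectra(library_ref)
cfg = st.PipelineConfig(preprocess=st.PreprocessConfig(noise_region),
                        spa_lambda=0.85, seed=1)
result = st.run_pipeline(observed, library, cfg)
n_correct, n_missed, n_false = st.score_identification(
    result.report, sampled.metabolite_names)
print(f"SPA clusters: {result.provenance['spa']['n_clusters']} "
      f"(window k={result.provenance['spa']['window_size']})")
print(f"STOCSY groups: {result.provenance['stocsy']['n_groups']}")
print(f"identified {n_correct}/10 simulated metabolites "
      f"({n_false} false positives from the 40 absent library entries)")
```

prints

```
SPA clusters: 34 (window k=7)
STOCSY groups: 11
identified 9/10 simulated metabolites (3 false positives from the 40 absent library entries)
```

SPA found 34 spatial clusters using the PACF-selected window of 7
datapoints; STOCSY joined them into 11 same-molecule groups; matching the
groups against the 50-entry library recovered 9 of the 10 metabolites
actually present. The one miss is a metabolite whose second resonance
cluster is buried under another metabolite's multiplet — the characteristic
failure mode of overlap-dense regions.

The same pipeline is available from the shell:

```bash
spa-stocsy simulate -L 10 -n 50 --seed 7 --out demo
spa-stocsy run --input demo_spectra.csv --library demo_library.csv \
               --outdir out --noise-region 0.5 0.65 --lambda 0.85 --seed 7
```

Subcommands `preprocess`, `spa`, `stocsy`, `identify`, `srv` and `evaluate`
expose the individual stages; all inputs and outputs are comma-delimited
text (spectra files start with a `ppm,...` axis row) and every run writes a
`provenance.json` recording the parameters actually used.

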