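# trflpipe

Community-fingerprint analysis for activated-sludge bioreactors: a tested,
reusable implementation of the full desk side of a T-RFLP
(terminal restriction fragment length polymorphism) monitoring study, from
raw sized peak lists to community-ecology and plant-performance statistics.

## Who this is for

Microbial ecologists and wastewater engineers who monitor conventional
activated-sludge (CAS) bioreactors with fingerprinting time series and need
a reproducible, scriptable path from electropherogram peak tables to the
statistics those studies report: between-plant β-diversity, diversity
ordering, the response of community structure to operational parameters,
and richness scaling with reactor size.

## What it computes

Starting from long-form peak tables (sample, enzyme, fragment size in bp,
peak height) and a monthly operational-parameter table per plant:

1. **Marker-range restriction and normalization** — only fragments within
   the 50–700 bp size-standard range are kept; each peak height is divided
   by the profile's total height.
2. **Recursive noise threshold** — per profile, the median *m* and sample
   standard deviation *s* of the working set are computed, values above
   *m* + 3*s* are removed, and the step repeats until nothing more can be
   removed; the last cutoff is the noise threshold and the real peaks are
   the values above it.
3. **Cross-gel binning** — TRFs from different profiles are aligned into
   OTUs by a greedy scan in ascending and descending size order under a
   size-dependent maximum bin span (default 2 bp), a congruence rule (one
   peak per profile per bin) and a peak-count criterion that favours larger
   bins; each OTU is labeled by the mean size of its members.
4. **β-diversity** — Bray–Curtis dissimilarity on square-root-transformed
   abundances; non-metric multidimensional scaling with 110 random restarts
   (Kruskal stress-1 of the best restart); ANOSIM and NPMANOVA permutation
   tests; SIMPER decomposition of the between-plant dissimilarity.
5. **α-diversity** — OTU richness, a paired *t*-test of richness between
   plants, and Rényi diversity profiles
   H<sub>α</sub> = ln(Σ p<sub>i</sub><sup>α</sup>)/(1−α)
   interpolating richness (α=0), Shannon (α→1), Simpson (α=2) and
   Berger–Parker (α→∞) views of diversity.
6. **Constrained ordination** — canonical correspondence analysis of the
   community matrix against ten operational variables (influent BOD and
   TSS, flow, F/M, HRT, SRT, NO₃-N, pH, PO₄³⁻, temperature), with a
   1000-permutation Monte-Carlo significance test.
7. **Performance statistics** — removal efficiencies, per-plant
   influent/effluent BOD correlation and regression, a Wald test of the
   plant × influent-BOD interaction, and the species-flow power law
   *S = cA<sup>z</sup>* (richness against average daily flow).

Because raw fingerprints of this kind are rarely public, the package ships
a synthetic-data generator (`trflpipe.synthetic`) that emulates the study
design — 12 monthly samples × 2 plants × 3 restriction enzymes, a noise
floor under a few dozen dominant peaks, sub-bp between-gel size jitter, one
stable and one erratic community, and controllable influent→effluent BOD
correlations — so every stage is testable end to end with no download.

## Worked example

```python
from trflpipe import RunConfig, run_pipeline

cfg = RunConfig.demo("demo_run", seed=1)
res = run_pipeline(cfg)
print(f"NMDS stress (3-D):  {res['nmds'].stress:.5f}")
print(f"ANOSIM  R = {res['anosim'].statistic:.4f}  p = {res['anosim'].p_value}")
print(f"NPMANOVA F = {res['npmanova'].statistic:.3f}  p = {res['npmanova'].p_value}")
print(f"paired richness t = {res['paired_t'].statistic:.2f}"
      f"  p = {res['paired_t'].p_value:.2e}")
print(f"CCA first two axes: {100 * res['cca'].fraction_first_two:.1f}% of inertia")
```

prints, for the bundled demonstration conditions:

```
NMDS stress (3-D):  0.02497
ANOSIM  R = 0.9712  p = 0.001
NPMANOVA F = 18.999  p = 0.001
paired richness t = 7.90  p = 2.78e-09
CCA first two axes: 28.6% of inertia
```

meaning the 3-D ordination faithfully represents the distance matrix
(stress well below 0.1), the two simulated plant communities are strongly
and significantly separated, the larger plant's profiles are significantly
richer, and the measured operational variables account for about 29% of the
community variation on the first two canonical axes.  The same run writes
every intermediate artifact (filtered peaks, bin audit, matrices, distance
matrix, ordinations, test summaries) plus a SHA-256 manifest into
`demo_run/`; rerunning with the same seed reproduces the manifest byte for
byte.

The same stages are available from the shell:

```bash
trflpipe simulate --seed 1 --out sim/
trflpipe filter --in sim/peaks.tsv --out filtered.tsv
trflpipe bin --in filtered.tsv --audit bins.tsv
trflpipe run --demo --seed 1 --out demo_run/
```

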