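# longreadage

Epigenetic age prediction and cell-type-of-origin deconvolution for
long-read DNA methylation data.

Single-molecule long-read sequencing reports CpG methylation directly, but
any one sample covers a sparse, sample-specific subset of the genome's CpGs
— classic array-trained epigenetic clocks, which need a fixed probe panel,
cannot score such profiles. `longreadage` addresses this with a
probabilistic clock that works on whatever CpGs a profile happens to share
with a reference cohort, and adds a fragment-level deconvolution step so
that cell-type-specific epigenetic ages can be read out of bulk leukocyte
or cell-free DNA data without cell sorting.

## The model

**Age prediction.** From a reference cohort (beta matrix B, ages A) the
package fits, per CpG site k, an ordinary least-squares regression
β<sub>k</sub> ≈ a<sub>k</sub>·age + b<sub>k</sub> together with the Pearson
correlation r<sub>k</sub> between methylation and age. For a query profile
m over the CpGs it shares with the reference, the sites with the highest
|r<sub>k</sub>| are kept (top 1% of the intersection by default, or a fixed
count), and for every age A on a grid (0–100 y, step 0.1) the predicted
methylation p<sub>k</sub>(A) = clamp(a<sub>k</sub>A + b<sub>k</sub>, ε, 1−ε)
is compared to the observation through a Bernoulli log-probability

&nbsp;&nbsp;&nbsp;&nbsp;P(A) = Σ<sub>k</sub> [ m<sub>k</sub> log p<sub>k</sub>(A) + (1−m<sub>k</sub>) log(1−p<sub>k</sub>(A)) ].

The grid age maximizing P(A) is the sample's epigenetic age.

**Cell type of origin.** A two-group differential-methylation filter bank
(coverage, mean difference, Welch t-test, quantile separation) builds an
atlas of marker CpGs with mean beta c<sub>k</sub> per cell type. Each
autosomal fragment with mapping quality ≥ 20 and ≥ 5 marker CpGs is scored
against every cell type with the similarity likelihood

&nbsp;&nbsp;&nbsp;&nbsp;L = Σ<sub>k</sub> (1 − |r<sub>k</sub> − c<sub>k</sub>|),

where r<sub>k</sub> are the fragment's methylation calls. A fragment is
assigned to a cell type whose score beats every other type's by at least
1/0.95 (≈1.053×). Assigned fragments are piled up (count mode, minimum
coverage 1) into per-cell-type methylation profiles that feed straight back
into the age predictor.

## Worked example

```python
import longreadage as lra

# fit a reference aging model on a simulated 519-sample cohort
cfg = lra.SimulationConfig(seed=11, n_reference_samples=519, n_sites=2000)
dataset, _ = lra.simulate_reference(cfg)
model = lra.fit_reference(dataset)
print(f"reference model: {model.n_sites_} CpG sites fit")

# predict the epigenetic age of a 500-CpG pileup profile at true age 52
sites = model.select_sites(model.model_.index, "fixed_number", 500)
profile = lra.simulate_profile_at_age(model, age=52.0, sites=sites,
                                      reads_per_site=10, seed=7)
pred = lra.predict_age(profile, model, selection_value=100)
print(f"epigenetic age: {pred.age_estimate:.1f} y "
      f"({pred.n_sites_used} CpGs, log-score {pred.score_at_max:.1f})")

# trace 5,000 fragments to their cell type and quantify the mixture
fcfg = lra.SimulationConfig(seed=3, n_fragments=5000, cpgs_per_read=10,
                            ineligible_fraction=0.05)
samples, _, fragments, _ = lra.simulate_atlas_and_fragments(fcfg)
atlas = lra.find_markers(samples)
clf = lra.FragmentCellTypeClassifier(atlas=atlas).fit()
results = clf.assign(fragments)
print("cell-type proportions:",
      {k: round(v, 3) for k, v in lra.cell_type_proportions(results).items()})
myeloid = lra.aggregate_profiles(fragments, results, "myeloid")
print(f"myeloid pileup: {len(myeloid)} CpGs, median deviation from own "
      f"reference {lra.profile_concordance(myeloid, atlas, 'myeloid'):.3f} "
      f"vs other {lra.profile_concordance(myeloid, atlas, 'lymphocyte'):.3f}")
```

prints

```
reference model: 2000 CpG sites fit
epigenetic age: 54.3 y (500 CpGs, log-score -303.9)
cell-type proportions: {'lymphocyte': 0.243, 'myeloid': 0.703, 'unassigned': 0.054}
myeloid pileup: 200 CpGs, median deviation from own reference 0.033 vs other 0.524
```

The predicted age (54.3 y) lands within the clock's expected error of the
true simulated age (52.0); the fragment mixture was generated at 75/25
myeloid/lymphocyte and is recovered at 70/24 with a 5% unassigned tail; the
aggregated myeloid profile is an order of magnitude closer to its own
reference methylation than to the lymphocyte reference.

The same stages are available from the shell:

```bash
longreadage simulate --seed 3 --out-dir fixtures
longreadage fit-reference --betas fixtures/reference_betas.tsv \
    --ages fixtures/reference_ages.tsv --out model.tsv
longreadage find-markers --samples-dir fixtures/atlas_samples --out atlas.tsv
longreadage assign --fragments fixtures/fragments.tsv --atlas atlas.tsv --out assignments.tsv
longreadage aggregate --fragments fixtures/fragments.tsv \
    --assignments assignments.tsv --out-dir beds
longreadage predict-age --model model.tsv --profile beds/myeloid.bed \
    --selection-value 100 --out predictions.tsv
longreadage pipeline --seed 3 --out-dir run    # all of the above, end to end
```

Every run logs the effective parameters and the filter attrition
(ineligible / unassigned / assigned fragment counts, CpGs used per
prediction); `pipeline` also writes them to `run.log`.

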