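# mgomics

Magnesium-content multi-omics association screening for paired tumor
cohorts.

Tissue magnesium is a candidate modifier of tumor biology: Mg²⁺ is a
cofactor of DNA replication and repair enzymes and of the kinases and
phosphatases that shape phospho-signaling, so intratumoral Mg content
(measured by ICP-MS as μg Mg per g extracted protein) may associate with
genome instability, proteome remodeling, and survival. `mgomics` is a
reusable, tested implementation of the full analytical chain needed to run
such a screen on TMT-based proteomics/phosphoproteomics, whole-exome
mutation calls, and clinical follow-up — plus a synthetic cohort generator
with known planted effects, so every stage can be validated end to end
without access to patient data.

## What it computes

**TMT data cleaning with internal-standard bridging** (`mgomics.ingest`).
Per batch: contaminant/reverse removal; ≥ 2 unique peptides (proteins) or
localization probability > 0.75 (phosphosites); per-channel
total-intensity equalization; division of each sample channel by the
batch's internal-standard (IS) channel, giving sample-to-standard ratios
S/S that are comparable across batches; then log₂, dual z-scoring, and
removal of features missing in > 50% of samples. Zeros are non-detections
and become missing. The pipeline is provably invariant to rescaling any
single batch.

**Mg association screens** (`mgomics.association`). Per feature, Spearman
rank correlation ρ of abundance with Mg content over pairwise-complete
samples (exact permutation p for n ≤ 9, t-approximation with n − 2 df
otherwise), screened at raw P < 0.05 with BH q-values reported; stratified
(left-/right-sided) screening with overlap sets; and a partial-Spearman
screen that calls a phosphosite Mg-associated *independently of protein
level* when both the marginal and the protein-partialled correlation are
significant with concordant sign.

**Somatic mutation association** (`mgomics.somatic`). TMB = mutations /
exome Mb; exclusion of hypermutators (TMB > 10/Mb) that carry non-silent
mutations in MSH2, MSH6, MLH1, PMS2, POLD1, or POLE; removal of genes
≥ 5000 amino acids; per-gene (mutated, wild-type) × (High-Mg, Low-Mg)
two-sided Fisher exact screening; six-class SNV substitution spectra with
strand collapsing; pairwise co-occurrence / mutual-exclusivity among the
top-20 mutated genes.

**Survival statistics** (`mgomics.survival`), self-contained:
Kaplan–Meier with Greenwood variance; k-group log-rank; the maximally
selected log-rank cutpoint max_c |S(c) − E[S(c)]| / √Var[S(c)| over all
admissible dichotomizations of a continuous covariate, with a
permutation p-value for the maximum; Cox proportional hazards fitted by
Newton–Raphson on the Breslow partial likelihood, HR = exp(β) with Wald
CIs.

**Local enrichment** (`mgomics.enrichment`): preranked GSEA (weighted
Kolmogorov–Smirnov running sum, ES/NES, gene-label permutation null,
signed-pooling FDR) and hypergeometric over-representation with BH
q-values.

**Synthetic cohorts** (`mgomics.synth`): Gaussian-copula planting of
features with a chosen Spearman correlation against Mg, batch structure
with an IS channel, configurable missingness, group-differential mutated
genes, hypermutators, a planted T>C-skewed Low-Mg SNV spectrum, and
exponential survival with log-hazard linear in Mg — all recorded in a
truth ledger. See `docs/methods.md` for the model and its limits.

## Worked example

```python
import pathlib, tempfile
import mgomics as mg

# 60 patients, 10-plex TMT batches, planted effects recorded in bundle.truth
bundle = mg.simulate_cohort(mg.CohortConfig(n_patients=60, seed=7))
d = pathlib.Path(tempfile.mkdtemp()) / "cohort"
mg.write_cohort(bundle, d)

mats = []
for p in sorted(d.glob("proteome_batch*.tsv")):
    t = mg.read_quant_table(p, kind="protein")
    t = mg.filter_features(t)            # >= 2 unique peptides
    t = mg.scale_total_intensity(t)      # equalize channel loads
    mats.append(mg.bridge_to_is(t))      # S/S ratios vs the IS channel
matrix = mg.dual_zscore(mg.filter_missing(mg.combine_batches(mats)))
print(f"cleaned matrix: {matrix.n_features} proteins x {matrix.n_samples} samples")

clinical = bundle.clinical
mg_content = dict(zip(clinical["tumor_sample"], clinical["mg_content"]))
screen = mg.spearman_screen(matrix, mg_content)
n_pos = int((screen["significant"] & (screen["direction"] == "positive")).sum())
n_neg = int((screen["significant"] & (screen["direction"] == "negative")).sum())
print(f"Mg-associated proteins at P < 0.05: {n_pos} positive, {n_neg} negative")

groups = mg.dichotomize_mg(clinical.set_index("tumor_sample"),
                           method="max_logrank", n_perm=1000, seed=7)
print(f"optimal Mg cutpoint: {groups.threshold:.1f} ug/g "
      f"({len(groups.high)} High-Mg, {len(groups.low)} Low-Mg)")

z = (clinical["mg_content"] - clinical["mg_content"].mean()) / clinical["mg_content"].std()
fit = mg.cox_fit(clinical["os_months"], clinical["os_event"], z.to_numpy(), names=["mg_z"])
print(f"Cox HR per SD of Mg: {fit.hr[0]:.2f} "
      f"(95% CI {fit.ci_lower[0]:.2f}-{fit.ci_upper[0]:.2f})")

records = mg.read_maf(d / "mutations.maf.tsv")
retained, excluded = mg.hypermutation_filter(records, list(clinical["tumor_sample"]))
print(f"hypermutation filter: {len(retained)} samples retained, {len(excluded)} excluded")
sub = mg.MgGroups(groups.threshold, {s: groups.labels[s] for s in retained}, groups.method)
gene_screen = mg.fisher_gene_screen(
    records[records["Tumor_Sample_Barcode"].isin(retained)], sub)
hit = gene_screen.nsmallest(1, "p")
print(f"top differential gene: {hit.index[0]}  "
      f"freq {hit['freq_high'].iloc[0]:.0%} High-Mg vs {hit['freq_low'].iloc[0]:.0%} Low-Mg  "
      f"p={hit['p'].iloc[0]:.1e}")

sets = mg.read_gmt(d / "gene_sets.gmt")
gsea = mg.preranked_gsea(screen.loc[screen["tested"], "rho"].dropna(), sets,
                         n_perm=1000, seed=7)
row = gsea.iloc[0]
print(f"top gene set: {gsea.index[0]}  ES={row['es']:+.2f}  "
      f"NES={row['nes']:+.2f}  p={row['p']:.3f}")
```

which prints:

```
cleaned matrix: 295 proteins x 120 samples
Mg-associated proteins at P < 0.05: 32 positive, 33 negative
optimal Mg cutpoint: 561.9 ug/g (23 High-Mg, 37 Low-Mg)
Cox HR per SD of Mg: 0.53 (95% CI 0.39-0.72)
hypermutation filter: 58 samples retained, 2 excluded
top differential gene: APC  freq 68% High-Mg vs 14% Low-Mg  p=4.1e-05
top gene set: PLANTED_POSITIVE  ES=+0.97  NES=+3.02  p=0.001
```

Reading the numbers: of 300 simulated proteins, 295 survive the filters
across 120 tumor + normal channels; the screen recovers roughly the
planted 10% + 10% correlated fractions at P < 0.05; the survival-optimal
Mg cutpoint dichotomizes the cohort and the Cox fit recovers the planted
protective effect of Mg (HR < 1 per SD); the two MMR-mutant
hypermutators are excluded; the planted High-Mg-enriched APC contrast and
the gene set built from the positively correlated proteins are both
detected.

The same run is available as a one-liner:

```sh
mgomics run-all --out run1 --seed 7        # writes run1/manifest.json + stage tables
mgomics simulate --out cohort --seed 7     # just the synthetic inputs
```

## Input formats

Quantification tables are tab-separated, one row per feature:
`feature_id`, `unique_peptides` (protein tables) or `parent_protein` +
`localization_prob` (phospho tables), `contaminant` / `reverse` flags
(`+` marks a hit), and one `intensity_<sample>` column per channel with
`intensity_IS` for the internal standard; intensity 0 means not observed.
Mutations are a MAF-style TSV (standard column names); gene sets are GMT;
the clinical table is a CSV with `tumor_sample`, `normal_sample`, `side`,
`os_months`, `os_event`, and `mg_content` per patient.

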