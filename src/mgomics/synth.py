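"""Synthetic cohort generator with known planted effects.

Emulates the four inputs of the Mg multi-omics screen — a clinical table
with Mg content and overall survival, batched TMT quantification tables
(protein and phosphosite dialects, one internal-standard channel per
batch), a MAF-style somatic mutation table, and GMT gene sets — so the
whole pipeline can be exercised and validated without restricted data.

Planted structure (all recorded in a truth ledger):

* **Mg-correlated features** via a Gaussian copula: a configurable
  fraction of proteins (and of phosphosites, protein-independently) gets a
  latent abundance whose rank correlation with Mg content is analytically
  ``(6/pi) * arcsin(r/2)`` for latent Pearson ``r``; ``r`` is inflated to
  compensate for measurement/IS noise so the *realized* Spearman matches
  ``target_rho``.  An unreachable target raises instead of clipping.
* **Batch structure**: per-batch multiplicative scale (log-normal),
  per-sample loading factors, and an IS channel carrying the same latent
  reference profile in every batch plus noise — exactly what
  total-intensity scaling and IS bridging are meant to remove.
* **Missingness**: completely at random by default (encoded as intensity
  zero, the ingest convention), with an intensity-dependent (MNAR) option.
* **Mutations**: per-gene Bernoulli background, planted genes with
  group-specific frequencies relative to the true Mg cutpoint (cohort
  median Mg), hypermutator samples exceeding the TMB threshold (half of
  them carrying mismatch-repair mutations), and a Low-Mg-enriched T>C
  substitution spectrum.
* **Survival**: exponential with log-hazard linear in standardized Mg,
  independent exponential censoring.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import write_gmt
from .ingest import INTENSITY_PREFIX, IS_CHANNEL

__all__ = ["CohortConfig", "CohortBundle", "simulate_cohort", "write_cohort", "read_cohort_dir"]

DEFAULT_PLANTED_GENES = (
    # (gene, freq_low_mg, freq_high_mg) — frequencies echo the initiation
    # driver genes' published High-/Low-Mg contrast
    ("TP53", 0.26, 0.62),
    ("APC", 0.22, 0.51),
    ("KRAS", 0.30, 0.44),
)

MMR_GENES = ("MSH2", "MSH6", "MLH1", "PMS2", "POLD1", "POLE")

SNV_CLASS_PROBS_HIGH = {
    "C>A": 0.15, "C>G": 0.10, "C>T": 0.35, "T>A": 0.10, "T>C": 0.20, "T>G": 0.10,
}
SNV_CLASS_PROBS_LOW = {
    "C>A": 0.10, "C>G": 0.08, "C>T": 0.25, "T>A": 0.07, "T>C": 0.40, "T>G": 0.10,
}
_CLASS_TO_REFALT = {
    "C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
    "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G"),
}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a mid-sized TMT study: 10-plex batches with one IS
    channel, tumor/DNT pairs, Mg content on 162–920 μg/g, and planted
    mutation frequencies matching the published initiation-driver contrast.
    """

    n_patients: int = 60
    n_batches: int = 14
    plex_size: int = 10                     # channels per batch, one is IS
    n_proteins: int = 300
    n_phosphosites: int = 150
    mg_range: tuple[float, float] = (162.0, 920.0)   # μg per g protein
    mg_distribution: str = "uniform"        # or "log_uniform"
    frac_pos_corr: float = 0.10
    frac_neg_corr: float = 0.10
    target_rho: float = 0.5
    missing_frac: float = 0.10
    missing_mechanism: str = "mcar"         # or "mnar"
    batch_scale_sd: float = 0.30
    n_genes: int = 100
    background_mut_rate: float = 0.05
    planted_genes: tuple = DEFAULT_PLANTED_GENES
    n_hypermutators: int = 4
    exome_mb: float = 38.0
    baseline_hazard: float = 1.0 / 60.0     # per month
    log_hr_per_mg_unit: float = -0.7        # per SD of (latent) Mg
    censor_rate: float = 0.3
    seed: int = 0
    # noise knobs (free parameters; replicate-QC noise is not quantified
    # in published TMT studies at this grain)
    latent_sd: float = 0.6                  # biological spread, ln scale
    noise_sd: float = 0.10                  # per-measurement noise, ln scale
    is_noise_sd: float = 0.05               # IS channel noise, ln scale
    loading_sd: float = 0.10                # per-sample loading, ln scale
    n_decoys: int = 5                       # contaminant + reverse rows per table

    def __post_init__(self) -> None:
        if self.plex_size < 2:
            raise ValueError("plex_size must be >= 2 (one sample channel plus IS)")
        if self.frac_pos_corr + self.frac_neg_corr > 1:
            raise ValueError("frac_pos_corr + frac_neg_corr must be <= 1")
        if self.mg_range[0] <= 0 or self.mg_range[1] <= self.mg_range[0]:
            raise ValueError("mg_range must be an increasing pair of positive reals")
        if not -1 < self.target_rho < 1:
            raise ValueError("target_rho must be in (-1, 1)")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")
        capacity = self.n_batches * (self.plex_size - 1)
        if capacity < 2 * self.n_patients:
            raise ValueError(
                f"{self.n_batches} batches x {self.plex_size - 1} sample channels "
                f"cannot hold {2 * self.n_patients} samples (tumor + DNT per patient)"
            )

    def latent_pearson(self) -> float:
        """Latent Pearson correlation that realizes ``target_rho`` as the
        Spearman correlation after measurement and IS noise.

        Raises when the compensation would require |r| > 1.
        """
        r_spear = 2 * np.sin(np.pi * self.target_rho / 6)
        total_sd = np.sqrt(
            self.latent_sd**2 + self.noise_sd**2 + self.is_noise_sd**2
        )
        r = r_spear * total_sd / self.latent_sd
        if abs(r) > 1:
            raise ValueError(
                f"impossible copula target: target_rho={self.target_rho} needs "
                f"latent Pearson {r:.3f} under the configured noise"
            )
        return float(r)


@dataclass
class CohortBundle:
    """Everything :func:`simulate_cohort` produces."""

    clinical: pd.DataFrame
    protein_batches: list[pd.DataFrame]     # dialect frames, one per batch
    phospho_batches: list[pd.DataFrame]
    maf: pd.DataFrame
    gene_sets: dict[str, set[str]]
    truth: dict
    config: CohortConfig = field(repr=False, default=None)


def _mg_from_latent(z: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    u = stats.norm.cdf(z)
    lo, hi = cfg.mg_range
    if cfg.mg_distribution == "uniform":
        return lo + (hi - lo) * u
    if cfg.mg_distribution == "log_uniform":
        return np.exp(np.log(lo) + (np.log(hi) - np.log(lo)) * u)
    raise ValueError("mg_distribution must be 'uniform' or 'log_uniform'")


def _apply_missing(vals: np.ndarray, cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Set entries to zero (the non-detection encoding)."""
    if cfg.missing_frac == 0:
        return vals
    if cfg.missing_mechanism == "mcar":
        drop = rng.random(vals.shape) < cfg.missing_frac
    elif cfg.missing_mechanism == "mnar":
        # lower-intensity entries are more likely to drop out; per-cell
        # probability is linear in (1 - intensity rank), mean missing_frac
        flat = vals.ravel()
        ranks = stats.rankdata(flat) / flat.size
        p = np.clip(2 * cfg.missing_frac * (1 - ranks), 0, 1).reshape(vals.shape)
        drop = rng.random(vals.shape) < p
    else:
        raise ValueError("missing_mechanism must be 'mcar' or 'mnar'")
    out = vals.copy()
    out[drop] = 0.0
    return out


def _dialect_frame(
    feature_ids,
    intensities: np.ndarray,
    channel_names: list[str],
    meta: dict[str, np.ndarray],
    decoys: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assemble a quantification table in the documented TSV dialect,
    appending contaminant/reverse decoy rows."""
    df = pd.DataFrame({"feature_id": feature_ids})
    for k, v in meta.items():
        df[k] = v
    df["contaminant"] = ""
    df["reverse"] = ""
    for j, ch in enumerate(channel_names):
        df[f"{INTENSITY_PREFIX}{ch}"] = intensities[:, j]

    if decoys:
        decoy_rows = []
        for i in range(decoys):
            flag_contaminant = i % 2 == 0
            row = {"feature_id": (f"CON_{i:03d}" if flag_contaminant else f"REV_{i:03d}")}
            for k in meta:
                row[k] = meta[k][0]
            row["contaminant"] = "+" if flag_contaminant else ""
            row["reverse"] = "" if flag_contaminant else "+"
            for ch in channel_names:
                row[f"{INTENSITY_PREFIX}{ch}"] = float(rng.uniform(1e3, 1e5))
            decoy_rows.append(row)
        df = pd.concat([df, pd.DataFrame(decoy_rows)], ignore_index=True)
    return df


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full synthetic cohort with the configured planted effects."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    r = cfg.latent_pearson()

    # ---- patients, Mg, survival -----------------------------------------
    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    tumors = [f"{p}-T" for p in patients]
    normals = [f"{p}-N" for p in patients]
    z_mg = rng.standard_normal(cfg.n_patients)
    mg = _mg_from_latent(z_mg, cfg)

    rate = cfg.baseline_hazard * np.exp(cfg.log_hr_per_mg_unit * z_mg)
    event_time = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        censor_hazard = cfg.censor_rate / (1 - cfg.censor_rate) * cfg.baseline_hazard
        censor_time = rng.exponential(1.0 / censor_hazard, cfg.n_patients)
    else:
        censor_time = np.full(cfg.n_patients, np.inf)
    os_months = np.minimum(event_time, censor_time)
    os_months = np.maximum(os_months, 0.1)  # surgery-to-event times stay positive
    os_event = (event_time <= censor_time).astype(int)

    side = rng.choice(["left", "right"], size=cfg.n_patients)
    gender = rng.choice(["female", "male"], size=cfg.n_patients)
    age = rng.integers(30, 85, size=cfg.n_patients)

    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "tumor_sample": tumors,
            "normal_sample": normals,
            "side": side,
            "gender": gender,
            "age": age,
            "os_months": np.round(os_months, 2),
            "os_event": os_event,
            "mg_content": np.round(mg, 2),
        }
    ).set_index("patient_id")

    mg_cutpoint = float(np.median(mg))
    low_mg = mg < mg_cutpoint

    # ---- planted correlation structure ----------------------------------
    n_pos = int(round(cfg.frac_pos_corr * cfg.n_proteins))
    n_neg = int(round(cfg.frac_neg_corr * cfg.n_proteins))
    protein_ids = [f"PROT{j + 1:04d}" for j in range(cfg.n_proteins)]
    pos_proteins = protein_ids[:n_pos]
    neg_proteins = protein_ids[n_pos : n_pos + n_neg]

    signs = np.zeros(cfg.n_proteins)
    signs[:n_pos] = 1.0
    signs[n_pos : n_pos + n_neg] = -1.0

    base_log = rng.normal(14.0, 1.0, cfg.n_proteins)  # ln-scale reference profile
    eps = rng.standard_normal((cfg.n_proteins, cfg.n_patients))
    latent = signs[:, None] * r * z_mg[None, :] + np.sqrt(1 - (signs[:, None] * r) ** 2) * eps
    tumor_log = base_log[:, None] + cfg.latent_sd * latent
    normal_log = base_log[:, None] + cfg.latent_sd * rng.standard_normal(
        (cfg.n_proteins, cfg.n_patients)
    )

    unique_peptides = 1 + rng.poisson(4.0, cfg.n_proteins)
    # planted features must survive the >= 2 unique peptide filter
    planted_idx = np.arange(n_pos + n_neg)
    unique_peptides[planted_idx] = np.maximum(unique_peptides[planted_idx], 2)

    # ---- phosphosites ----------------------------------------------------
    n_sites = cfg.n_phosphosites
    parent_idx = rng.integers(0, cfg.n_proteins, n_sites)
    residues = rng.integers(1, 900, n_sites)
    site_ids = [f"{protein_ids[p]}_S{res}" for p, res in zip(parent_idx, residues)]
    # de-duplicate site ids deterministically
    seen: dict[str, int] = {}
    for i, s in enumerate(site_ids):
        if s in seen:
            site_ids[i] = f"{s}{chr(ord('a') + seen[s])}"
        seen[s] = seen.get(s, 0) + 1

    n_pos_sites = int(round(cfg.frac_pos_corr * n_sites))
    n_neg_sites = int(round(cfg.frac_neg_corr * n_sites))
    site_sign = np.zeros(n_sites)
    site_sign[:n_pos_sites] = 1.0
    site_sign[n_pos_sites : n_pos_sites + n_neg_sites] = -1.0

    site_base = base_log[parent_idx] + rng.normal(0.0, 0.5, n_sites)
    site_eps = rng.standard_normal((n_sites, cfg.n_patients))
    # planted sites carry their own Mg association (protein-independent);
    # the rest track their parent protein plus site noise
    planted_site = site_sign != 0
    site_latent = np.where(
        planted_site[:, None],
        site_sign[:, None] * r * z_mg[None, :]
        + np.sqrt(1 - (site_sign[:, None] * r) ** 2) * site_eps,
        latent[parent_idx] * 0.8 + 0.6 * site_eps,
    )
    site_tumor_log = site_base[:, None] + cfg.latent_sd * site_latent
    site_normal_log = site_base[:, None] + cfg.latent_sd * rng.standard_normal(
        (n_sites, cfg.n_patients)
    )

    loc_prob = np.round(rng.uniform(0.80, 1.0, n_sites), 3)
    n_low_prob = max(1, n_sites // 10)
    low_prob_idx = np.arange(n_sites)[~planted_site][-n_low_prob:]
    loc_prob[low_prob_idx] = np.round(rng.uniform(0.3, 0.75, n_low_prob), 3)

    # ---- batch assembly --------------------------------------------------
    all_samples = [s for pair in zip(tumors, normals) for s in pair]
    order = rng.permutation(len(all_samples))
    shuffled = [all_samples[i] for i in order]
    per_batch = cfg.plex_size - 1
    batches = [shuffled[i * per_batch : (i + 1) * per_batch] for i in range(cfg.n_batches)]
    batches = [b for b in batches if b]

    sample_col = {s: i for i, s in enumerate(tumors)}
    sample_col.update({s: i for i, s in enumerate(normals)})
    is_tumor = {s: s.endswith("-T") for s in all_samples}

    batch_scale = np.exp(rng.normal(0.0, cfg.batch_scale_sd, len(batches)))
    loading = {s: float(np.exp(rng.normal(0.0, cfg.loading_sd))) for s in all_samples}

    protein_batches: list[pd.DataFrame] = []
    phospho_batches: list[pd.DataFrame] = []
    for b, members in enumerate(batches):
        chans = list(members) + [IS_CHANNEL]

        def build(log_tumor, log_normal, n_feat):
            cols = np.empty((n_feat, len(chans)))
            for j, s in enumerate(members):
                src = log_tumor if is_tumor[s] else log_normal
                noise = rng.normal(0.0, cfg.noise_sd, n_feat)
                cols[:, j] = np.exp(src[:, sample_col[s]] + noise) * batch_scale[b] * loading[s]
            is_noise = rng.normal(0.0, cfg.is_noise_sd, n_feat)
            base = base_log if n_feat == cfg.n_proteins else site_base
            cols[:, -1] = np.exp(base + is_noise) * batch_scale[b]
            return _apply_missing(cols, cfg, rng)

        prot_vals = build(tumor_log, normal_log, cfg.n_proteins)
        protein_batches.append(
            _dialect_frame(
                protein_ids, prot_vals, chans,
                {"unique_peptides": unique_peptides},
                cfg.n_decoys, rng,
            )
        )
        site_vals = build(site_tumor_log, site_normal_log, n_sites)
        phospho_batches.append(
            _dialect_frame(
                site_ids, site_vals, chans,
                {
                    "parent_protein": np.array([protein_ids[p] for p in parent_idx]),
                    "localization_prob": loc_prob,
                },
                cfg.n_decoys, rng,
            )
        )

    # ---- somatic mutations ----------------------------------------------
    background_genes = [f"GENE{j + 1:04d}" for j in range(cfg.n_genes)]
    planted = {g: (fl, fh) for g, fl, fh in cfg.planted_genes}
    maf_rows: list[dict] = []

    def add_record(sample: str, gene: str, low_group: bool, classification: str = "Missense_Mutation"):
        probs = SNV_CLASS_PROBS_LOW if low_group else SNV_CLASS_PROBS_HIGH
        classes = list(probs)
        cls = classes[rng.choice(len(classes), p=np.array([probs[c] for c in classes]))]
        ref, alt = _CLASS_TO_REFALT[cls]
        maf_rows.append(
            {
                "Hugo_Symbol": gene,
                "Tumor_Sample_Barcode": sample,
                "Variant_Classification": classification,
                "Variant_Type": "SNP",
                "Chromosome": str(rng.integers(1, 23)),
                "Start_Position": int(rng.integers(1, 2_000_000)),
                "Reference_Allele": ref,
                "Tumor_Seq_Allele2": alt,
            }
        )

    for i, sample in enumerate(tumors):
        low = bool(low_mg[i])
        for gene, (f_low, f_high) in planted.items():
            if rng.random() < (f_low if low else f_high):
                add_record(sample, gene, low)
        hit = rng.random(cfg.n_genes) < cfg.background_mut_rate
        for g in np.asarray(background_genes)[hit]:
            add_record(sample, g, low)

    hyper_samples = list(rng.choice(tumors, size=cfg.n_hypermutators, replace=False)) \
        if cfg.n_hypermutators else []
    mmr_hyper = hyper_samples[: len(hyper_samples) // 2 + len(hyper_samples) % 2]
    for sample in hyper_samples:
        low = bool(low_mg[tumors.index(sample)])
        target = int(np.ceil(10 * cfg.exome_mb * rng.uniform(1.2, 1.6)))
        for _ in range(target):
            add_record(sample, background_genes[int(rng.integers(cfg.n_genes))], low)
        if sample in mmr_hyper:
            add_record(sample, MMR_GENES[int(rng.integers(len(MMR_GENES)))], low)

    maf = pd.DataFrame(maf_rows).drop_duplicates(
        subset=["Hugo_Symbol", "Tumor_Sample_Barcode", "Chromosome", "Start_Position",
                "Reference_Allele", "Tumor_Seq_Allele2"]
    ).reset_index(drop=True)

    # ---- gene sets -------------------------------------------------------
    gene_sets: dict[str, set[str]] = {}
    if pos_proteins:
        gene_sets["PLANTED_POSITIVE"] = set(pos_proteins)
    if neg_proteins:
        gene_sets["PLANTED_NEGATIVE"] = set(neg_proteins)
    null_pool = protein_ids[n_pos + n_neg :]
    for k in range(3):
        size = min(20, max(5, len(null_pool) // 4))
        members = rng.choice(null_pool, size=size, replace=False) if null_pool else []
        gene_sets[f"RANDOM_SET_{k + 1}"] = set(members)

    truth = {
        "pos_corr_proteins": pos_proteins,
        "neg_corr_proteins": neg_proteins,
        "pos_corr_sites": [site_ids[i] for i in range(n_sites) if site_sign[i] > 0],
        "neg_corr_sites": [site_ids[i] for i in range(n_sites) if site_sign[i] < 0],
        "target_rho": cfg.target_rho,
        "latent_pearson": r,
        "mg_cutpoint": mg_cutpoint,
        "log_hr_per_mg_unit": cfg.log_hr_per_mg_unit,
        "planted_mutation_genes": {g: {"freq_low": fl, "freq_high": fh}
                                   for g, fl, fh in cfg.planted_genes},
        "hypermutators": sorted(hyper_samples),
        "hypermutators_with_mmr": sorted(mmr_hyper),
        "low_mg_samples": [tumors[i] for i in range(cfg.n_patients) if low_mg[i]],
        "snv_class_probs": {"High-Mg": SNV_CLASS_PROBS_HIGH, "Low-Mg": SNV_CLASS_PROBS_LOW},
        "n_decoys_per_table": cfg.n_decoys,
    }

    return CohortBundle(
        clinical=clinical,
        protein_batches=protein_batches,
        phospho_batches=phospho_batches,
        maf=maf,
        gene_sets=gene_sets,
        truth=truth,
        config=cfg,
    )


def write_cohort(bundle: CohortBundle, directory: str | Path, overwrite: bool = False) -> dict:
    """Serialize a cohort to disk; returns (and writes) the manifest.

    Refuses to clobber an existing cohort (``manifest.json`` present)
    unless ``overwrite`` is set.  Output is byte-stable for a fixed seed.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    directory.mkdir(parents=True, exist_ok=True)

    fmt = "%.8g"
    paths: dict[str, object] = {}

    clinical_path = directory / "clinical.csv"
    bundle.clinical.to_csv(clinical_path, float_format=fmt)
    paths["clinical"] = clinical_path.name

    paths["protein_batches"] = []
    paths["phospho_batches"] = []
    for i, df in enumerate(bundle.protein_batches):
        p = directory / f"proteome_batch{i + 1:02d}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=fmt)
        paths["protein_batches"].append(p.name)
    for i, df in enumerate(bundle.phospho_batches):
        p = directory / f"phospho_batch{i + 1:02d}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=fmt)
        paths["phospho_batches"].append(p.name)

    maf_path = directory / "mutations.maf.tsv"
    bundle.maf.to_csv(maf_path, sep="\t", index=False)
    paths["maf"] = maf_path.name

    gmt_path = directory / "gene_sets.gmt"
    write_gmt(bundle.gene_sets, gmt_path)
    paths["gene_sets"] = gmt_path.name

    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
    paths["truth"] = truth_path.name

    manifest = {
        "paths": paths,
        "config": asdict(bundle.config) if bundle.config else None,
        "checksums": {
            name: hashlib.sha256((directory / name).read_bytes()).hexdigest()
            for name in _flatten(paths)
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _flatten(paths: dict) -> list[str]:
    out: list[str] = []
    for v in paths.values():
        out.extend(v if isinstance(v, list) else [v])
    return out


def read_cohort_dir(directory: str | Path) -> dict:
    """Load the file-level pieces of a written cohort (clinical, manifest,
    truth); quantification tables go through :mod:`mgomics.ingest`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    clinical = pd.read_csv(directory / manifest["paths"]["clinical"], index_col=0)
    truth = json.loads((directory / manifest["paths"]["truth"]).read_text())
    return {"manifest": manifest, "clinical": clinical, "truth": truth, "directory": directory}
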