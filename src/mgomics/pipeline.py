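"""Configuration-driven orchestration of the full screen.

A single YAML (or dict) config either names real input files or contains a
``synthesize`` block; :func:`run_pipeline` then executes

    synth -> ingest -> association -> somatic -> survival -> enrichment

writing every stage's tables plus a manifest with input hashes, the seed,
and the thresholds used, so each "N features survived" count is auditable
and a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, enrichment, ingest, somatic, survival
from .synth import CohortConfig, simulate_cohort, write_cohort

log = logging.getLogger("mgomics")

STAGE_NAMES = ("synth", "ingest", "association", "somatic", "survival", "enrichment")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either ``synthesize`` (a :class:`CohortConfig` field dict) or explicit
    input paths must be present.  Thresholds default to the screening
    conventions: alpha 0.05, 50% missingness cap, localization probability
    0.75, >= 2 unique peptides, TMB threshold 10/Mb over a 38 Mb exome,
    cell-ratio bounds 1.2 / 0.83.
    """

    out_dir: str = "mgomics_run"
    seed: int = 0
    synthesize: dict | None = None
    inputs: dict | None = None          # clinical, protein_batches, phospho_batches, maf, gmt
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_NAMES})
    alpha: float = 0.05
    min_pairs: int = 10
    max_missing_frac: float = 0.5
    min_unique_peptides: int = 2
    min_localization_prob: float = 0.75
    tmb_threshold: float = 10.0
    exome_mb: float = 38.0
    max_aa: int = 5000
    minprop: float = 0.1
    cutpoint_n_perm: int = 500
    gsea_n_perm: int = 500
    zscore_order: str = "columns_first"
    ratio_upper: float = 1.2
    ratio_lower: float = 0.83

    def __post_init__(self) -> None:
        if self.synthesize is None and self.inputs is None:
            raise ValueError("config needs either a 'synthesize' block or input paths")
        for s in self.stages:
            if s not in STAGE_NAMES:
                raise ValueError(f"unknown stage {s!r}")
        self.stages = {s: self.stages.get(s, True) for s in STAGE_NAMES}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def _clean_kind(batch_paths, kind, cfg) -> ingest.ExpressionMatrix:
    mats = []
    for p in batch_paths:
        table = ingest.read_quant_table(p, kind=kind)
        table = ingest.filter_features(
            table,
            min_unique_peptides=cfg.min_unique_peptides,
            min_localization_prob=cfg.min_localization_prob,
        )
        table = ingest.scale_total_intensity(table)
        mats.append(ingest.bridge_to_is(table))
    combined = ingest.combine_batches(mats)
    combined = ingest.filter_missing(combined, cfg.max_missing_frac)
    return ingest.dual_zscore(combined, order=cfg.zscore_order)


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the configured stages; returns the run manifest."""
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig(**config)
    else:
        cfg = config

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {
            k: getattr(cfg, k)
            for k in ("alpha", "min_pairs", "max_missing_frac", "min_unique_peptides",
                      "min_localization_prob", "tmb_threshold", "exome_mb", "max_aa",
                      "minprop", "ratio_upper", "ratio_lower")
        },
        "stages": {},
        "inputs": {},
        "outputs": [],
    }

    current_stage = "synth"

    def record(name: str, status: str, **info):
        manifest["stages"][name] = {"status": status, **info}
        log.info("stage %s: %s %s", name, status, info or "")

    def emit(df: pd.DataFrame, name: str):
        _write_tsv(df, out / name)
        manifest["outputs"].append(name)

    try:
        # ---- synth -------------------------------------------------------
        if cfg.stages["synth"]:
            synth_cfg = dict(cfg.synthesize or {})
            synth_cfg.setdefault("seed", cfg.seed)
            if "planted_genes" in synth_cfg:
                synth_cfg["planted_genes"] = tuple(
                    tuple(x) for x in synth_cfg["planted_genes"]
                )
            if "mg_range" in synth_cfg:
                synth_cfg["mg_range"] = tuple(synth_cfg["mg_range"])
            bundle = simulate_cohort(CohortConfig(**synth_cfg))
            input_dir = out / "inputs"
            write_cohort(bundle, input_dir, overwrite=True)
            inputs = {
                "clinical": input_dir / "clinical.csv",
                "protein_batches": sorted(input_dir.glob("proteome_batch*.tsv")),
                "phospho_batches": sorted(input_dir.glob("phospho_batch*.tsv")),
                "maf": input_dir / "mutations.maf.tsv",
                "gmt": input_dir / "gene_sets.gmt",
            }
            record("synth", "complete", n_patients=len(bundle.clinical))
        else:
            raw = cfg.inputs or {}
            inputs = {
                "clinical": Path(raw["clinical"]),
                "protein_batches": [Path(p) for p in raw.get("protein_batches", [])],
                "phospho_batches": [Path(p) for p in raw.get("phospho_batches", [])],
                "maf": Path(raw["maf"]) if raw.get("maf") else None,
                "gmt": Path(raw["gmt"]) if raw.get("gmt") else None,
            }
            record("synth", "skipped")

        for key, val in inputs.items():
            files = val if isinstance(val, list) else ([val] if val else [])
            manifest["inputs"][key] = {str(p): _sha256(p) for p in files}

        clinical = pd.read_csv(inputs["clinical"], index_col=0)
        mg = dict(zip(clinical["tumor_sample"], clinical["mg_content"]))
        strata = dict(zip(clinical["tumor_sample"], clinical["side"]))

        # ---- ingest ------------------------------------------------------
        current_stage = "ingest"
        protein_z = phospho_z = None
        if cfg.stages["ingest"]:
            protein_z = _clean_kind(inputs["protein_batches"], "protein", cfg)
            emit(protein_z.values, "protein_matrix.tsv")
            (out / "protein_matrix.provenance.json").write_text(
                json.dumps({"stage": protein_z.stage, "note": protein_z.note,
                            "batch_map": protein_z.batch_map}, indent=1, sort_keys=True)
            )
            if inputs["phospho_batches"]:
                phospho_z = _clean_kind(inputs["phospho_batches"], "phospho", cfg)
                emit(phospho_z.values, "phospho_matrix.tsv")
            record("ingest", "complete",
                   n_proteins=protein_z.n_features,
                   n_phosphosites=phospho_z.n_features if phospho_z is not None else 0)
        else:
            record("ingest", "skipped")

        # ---- survival (groups are needed by the somatic stage) -----------
        current_stage = "survival"
        groups = None
        if cfg.stages["survival"]:
            cp = survival.max_selected_cutpoint(
                clinical["os_months"].to_numpy(),
                clinical["os_event"].to_numpy(),
                clinical["mg_content"].to_numpy(),
                minprop=cfg.minprop,
                n_perm=cfg.cutpoint_n_perm,
                seed=cfg.seed,
            )
            groups = association.MgGroups(
                threshold=cp.threshold,
                labels={
                    s: ("Low-Mg" if v < cp.threshold else "High-Mg")
                    for s, v in mg.items()
                },
                method="max_logrank",
            )
            km = survival.km_estimate(clinical["os_months"], clinical["os_event"])
            emit(km.table, "km_all.tsv")
            glabels = clinical["tumor_sample"].map(groups.labels)
            lr = survival.logrank_test(clinical["os_months"], clinical["os_event"], glabels)
            zmg = (clinical["mg_content"] - clinical["mg_content"].mean()) / clinical["mg_content"].std()
            cox = survival.cox_fit(
                clinical["os_months"], clinical["os_event"], zmg.to_numpy(), names=["mg_z"]
            )
            emit(cox.summary(), "cox_mg.tsv")
            (out / "survival_summary.json").write_text(json.dumps({
                "cutpoint": {"threshold": cp.threshold, "max_stat": cp.max_stat,
                             "p": cp.p, "n_low": cp.n_low, "n_high": cp.n_high},
                "logrank_groups": {"chi2": lr.statistic, "p": lr.p, "df": lr.df},
                "cox_mg_z": {"coef": float(cox.coef[0]), "hr": float(cox.hr[0]),
                             "converged": cox.converged},
            }, indent=1))
            record("survival", "complete", threshold=cp.threshold)
        else:
            record("survival", "skipped")

        # ---- association -------------------------------------------------
        current_stage = "association"
        screen = None
        if cfg.stages["association"] and protein_z is not None:
            screen = association.spearman_screen(
                protein_z, mg, alpha=cfg.alpha, min_pairs=cfg.min_pairs
            )
            emit(screen, "protein_mg_screen.tsv")
            strat = association.stratified_screen(
                protein_z, mg, strata, alpha=cfg.alpha, min_pairs=cfg.min_pairs
            )
            (out / "stratified_overlap.json").write_text(
                json.dumps(strat["overlap"], indent=1, sort_keys=True)
            )
            n_sig_pos = int(((screen["significant"]) & (screen["direction"] == "positive")).sum())
            n_sig_neg = int(((screen["significant"]) & (screen["direction"] == "negative")).sum())
            if phospho_z is not None:
                adj = association.protein_adjusted_phospho_screen(
                    phospho_z, protein_z, mg, alpha=cfg.alpha, min_pairs=cfg.min_pairs
                )
                emit(adj.drop(columns=[]), "phospho_mg_screen.tsv")
            record("association", "complete", positive=n_sig_pos, negative=n_sig_neg)
        else:
            record("association", "skipped")

        # ---- somatic -----------------------------------------------------
        current_stage = "somatic"
        if cfg.stages["somatic"] and inputs.get("maf") and groups is not None:
            records = somatic.read_maf(inputs["maf"])
            wes_samples = sorted(set(records["Tumor_Sample_Barcode"]) & set(mg))
            tmb = somatic.compute_tmb(records, wes_samples, exome_mb=cfg.exome_mb)
            retained, excl = somatic.hypermutation_filter(
                records, wes_samples, tmb_threshold=cfg.tmb_threshold, exome_mb=cfg.exome_mb
            )
            lengths = somatic.load_protein_lengths()
            filtered = somatic.gene_size_filter(records, lengths, max_aa=cfg.max_aa)
            filtered = filtered[filtered["Tumor_Sample_Barcode"].isin(retained)]
            freq = somatic.mutation_frequency(filtered, retained)
            sub_groups = association.MgGroups(
                groups.threshold,
                {s: groups.labels[s] for s in retained if s in groups.labels},
                groups.method,
            )
            gene_screen = somatic.fisher_gene_screen(filtered, sub_groups, alpha=cfg.alpha)
            emit(gene_screen.drop(columns=[]), "gene_mg_screen.tsv")
            spectrum = somatic.snv_class_summary(filtered, retained, sub_groups)
            emit(spectrum, "snv_spectrum.tsv")
            inter = somatic.somatic_interactions(filtered, retained)
            emit(inter, "somatic_interactions.tsv")
            (out / "somatic_exclusions.json").write_text(json.dumps({
                "tmb": {s: float(tmb[s]) for s in wes_samples},
                "excluded": excl,
                "n_retained": len(retained),
            }, indent=1, sort_keys=True))
            record("somatic", "complete", n_retained=len(retained),
                   n_sig=int(gene_screen["significant"].sum()))
        else:
            record("somatic", "skipped")

        # ---- enrichment --------------------------------------------------
        current_stage = "enrichment"
        if cfg.stages["enrichment"] and inputs.get("gmt") and screen is not None:
            sets = enrichment.read_gmt(inputs["gmt"])
            ranked = screen.loc[screen["tested"], "rho"].dropna()
            gsea = enrichment.preranked_gsea(
                ranked, sets, n_perm=cfg.gsea_n_perm, seed=cfg.seed
            )
            emit(gsea.assign(leading_edge=gsea["leading_edge"].map(",".join)),
                 "gsea_results.tsv")
            hits = set(screen.index[screen["significant"]])
            background = set(screen.index[screen["tested"]])
            if hits:
                ora = enrichment.ora_hypergeom(hits, background, sets)
                if not ora.empty:
                    emit(ora.assign(members=ora["members"].map(",".join)), "ora_results.tsv")
            record("enrichment", "complete", n_sets=len(gsea))
        else:
            record("enrichment", "skipped")

    except Exception as exc:
        failed_stage = current_stage
        manifest["stages"][failed_stage] = {"status": "failed", "error": str(exc)}
        manifest["incomplete"] = True
        (Path(cfg.out_dir) / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
        raise RuntimeError(f"pipeline failed at stage {failed_stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
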