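"""Somatic mutation association with Mg groups.

MAF ingestion, tumor mutational burden (TMB), the hypermutation /
mismatch-repair exclusion rule, a protein-size filter, per-gene mutation
frequencies, a per-gene High- vs Low-Mg Fisher screen, the six-class SNV
substitution spectrum, and pairwise somatic interactions (co-occurrence /
mutual exclusivity) among the top mutated genes.

Conventions
-----------
* "Mutated" means carrying at least one non-silent variant by default; the
  qualifying classification set is configurable.
* Hypermutated samples (TMB > 10 mutations/Mb) are excluded only when they
  also carry a non-silent mutation in a mismatch-repair or replicative
  polymerase gene (MSH2, MSH6, MLH1, PMS2, POLD1, POLE); hypermutators
  without such mutations are retained.
* Fisher two-sided p-values follow the probability-mass convention (sum of
  all tables, at fixed margins, with point probability not exceeding the
  observed table's).
"""

from __future__ import annotations

from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import MgGroups, bh_qvalues

__all__ = [
    "REQUIRED_MAF_COLUMNS",
    "NONSILENT_CLASSES",
    "MMR_POLYMERASE_GENES",
    "read_maf",
    "load_protein_lengths",
    "compute_tmb",
    "hypermutation_filter",
    "gene_size_filter",
    "mutation_frequency",
    "fisher_gene_screen",
    "snv_class_summary",
    "somatic_interactions",
]

REQUIRED_MAF_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)

NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

# Mismatch-repair and replicative-polymerase exclusion list.  The standard
# gene symbols are PMS2 and POLD1 (sometimes misspelled PSM2 / POLD in the
# literature); the set is a default, not a constraint.
MMR_POLYMERASE_GENES = frozenset({"MSH2", "MSH6", "MLH1", "PMS2", "POLD1", "POLE"})

#: Six pyrimidine-referenced substitution classes after strand collapsing.
SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def read_maf(path: str | Path, drop_silent: bool = False) -> pd.DataFrame:
    """Read a MAF-style TSV into a record frame.

    Exact duplicate records are dropped.  Silent variants are kept in the
    frame (they count toward TMB) unless ``drop_silent``; downstream
    "mutated gene" logic applies its own classification filter.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required MAF columns {missing}")
    df = df.drop_duplicates(subset=list(REQUIRED_MAF_COLUMNS)).reset_index(drop=True)
    df["Start_Position"] = pd.to_numeric(df["Start_Position"]).astype(int)
    if drop_silent:
        df = df[df["Variant_Classification"].isin(NONSILENT_CLASSES)].reset_index(drop=True)
    return df


def load_protein_lengths(path: str | Path | None = None) -> dict[str, int]:
    """Gene -> amino-acid length table.

    Defaults to the small annotation table shipped with the package
    (common colorectal-cancer genes plus the giant muscle proteins).
    """
    if path is None:
        ref = resources.files("mgomics").joinpath("data/gene_lengths.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"], df["aa_length"].astype(int)))


def _qualifying(records: pd.DataFrame, classes: frozenset[str] | None) -> pd.DataFrame:
    if classes is None:
        return records
    return records[records["Variant_Classification"].isin(classes)]


def compute_tmb(
    records: pd.DataFrame,
    samples: Iterable[str] | None = None,
    exome_mb: float = 38.0,
    classes: frozenset[str] | None = None,
) -> pd.Series:
    """Mutations per megabase per sample.

    All deduplicated records count by default (``classes`` restricts).
    Samples named but absent from the records get 0.
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    recs = _qualifying(records, classes)
    counts = recs.groupby("Tumor_Sample_Barcode").size()
    if samples is not None:
        counts = counts.reindex(list(samples), fill_value=0)
    return counts / exome_mb


def hypermutation_filter(
    records: pd.DataFrame,
    samples: Iterable[str],
    tmb_threshold: float = 10.0,
    exome_mb: float = 38.0,
    exclusion_genes: frozenset[str] = MMR_POLYMERASE_GENES,
) -> tuple[list[str], list[dict]]:
    """Exclude hypermutators attributable to MMR/polymerase mutations.

    A sample is removed iff its TMB exceeds ``tmb_threshold`` AND it
    carries a non-silent mutation in any exclusion gene.  Hypermutated
    samples without such mutations are retained.  Returns the retained
    sample list and a per-exclusion report.
    """
    samples = list(samples)
    tmb = compute_tmb(records, samples, exome_mb=exome_mb)
    nonsilent = _qualifying(records, NONSILENT_CLASSES)
    flagged = nonsilent[nonsilent["Hugo_Symbol"].isin(exclusion_genes)]
    carriers = flagged.groupby("Tumor_Sample_Barcode")["Hugo_Symbol"].agg(set)

    retained: list[str] = []
    report: list[dict] = []
    for s in samples:
        hyper = tmb[s] > tmb_threshold
        genes = carriers.get(s, set())
        if hyper and genes:
            report.append(
                {"sample": s, "tmb": float(tmb[s]), "trigger_genes": sorted(genes)}
            )
        else:
            retained.append(s)
    return retained, report


def gene_size_filter(
    records: pd.DataFrame,
    protein_lengths: Mapping[str, int],
    max_aa: int = 5000,
) -> pd.DataFrame:
    """Keep records in genes encoding fewer than ``max_aa`` amino acids.

    Strict: a gene of exactly ``max_aa`` residues is removed.  Genes absent
    from the length table are retained.
    """
    lengths = records["Hugo_Symbol"].map(protein_lengths)
    keep = lengths.isna() | (lengths < max_aa)
    return records[keep].reset_index(drop=True)


def mutation_frequency(
    records: pd.DataFrame,
    samples: Iterable[str],
    classes: frozenset[str] | None = NONSILENT_CLASSES,
) -> pd.Series:
    """Per gene, the fraction of samples carrying >= 1 qualifying record."""
    samples = list(samples)
    if not samples:
        raise ValueError("sample set is empty")
    recs = _qualifying(records, classes)
    recs = recs[recs["Tumor_Sample_Barcode"].isin(samples)]
    carriers = recs.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].nunique()
    return (carriers / len(samples)).sort_values(ascending=False)


def _mutated_samples(records: pd.DataFrame, classes: frozenset[str] | None) -> pd.Series:
    recs = _qualifying(records, classes)
    return recs.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].agg(set)


def fisher_gene_screen(
    records: pd.DataFrame,
    groups: MgGroups,
    alpha: float = 0.05,
    min_mutated: int = 3,
    classes: frozenset[str] | None = NONSILENT_CLASSES,
) -> pd.DataFrame:
    """Per-gene 2x2 Fisher screen of mutation frequency by Mg group.

    For every gene with at least ``min_mutated`` mutated samples overall,
    builds (mutated, wild-type) x (High-Mg, Low-Mg) counts, computes the
    two-sided Fisher exact p, the odds ratio a*d/(b*c) (with a Haldane
    0.5-continuity value reported separately when any cell is zero), the
    per-group mutation fractions, and BH q-values.
    """
    high = set(groups.high)
    low = set(groups.low)
    if not high or not low:
        raise ValueError("both Mg groups must be non-empty")
    cohort = high | low
    per_gene = _mutated_samples(records, classes)

    rows = []
    for gene, carriers in per_gene.items():
        carriers = carriers & cohort
        if len(carriers) < min_mutated:
            continue
        a = len(carriers & high)
        b = len(high) - a
        c = len(carriers & low)
        d = len(low) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        odds_cc = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            {
                "gene": gene,
                "a": a, "b": b, "c": c, "d": d,
                "p": float(p),
                "odds_ratio": odds,
                "odds_ratio_cc": odds_cc,
                "freq_high": a / len(high),
                "freq_low": c / len(low),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "a", "b", "c", "d", "p", "odds_ratio", "odds_ratio_cc",
                     "freq_high", "freq_low", "q", "significant", "direction"]
        ).set_index("gene")
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha
    out["direction"] = np.where(out["freq_high"] >= out["freq_low"], "higher_in_high_mg",
                                "higher_in_low_mg")
    return out.sort_values("p")


def collapse_snv(ref: str, alt: str) -> str | None:
    """Pyrimidine-referenced substitution class; None for ambiguous bases."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    if ref in ("A", "G"):  # purine reference: complement both strands
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def snv_class_summary(
    records: pd.DataFrame,
    samples: Iterable[str] | None = None,
    groups: MgGroups | None = None,
) -> pd.DataFrame:
    """Percentage of each of the six substitution classes among SNVs.

    With ``groups``, one row per Mg group plus an "all" row; otherwise the
    single "all" row.  A ``n_skipped`` column counts SNVs with ambiguous
    bases.  Percentages sum to 100 over classified SNVs.
    """
    snv = records[records["Variant_Type"] == "SNP"]
    if samples is not None:
        snv = snv[snv["Tumor_Sample_Barcode"].isin(set(samples))]
    if snv.empty:
        raise ValueError("no SNP records in the selected samples")

    def summarize(sub: pd.DataFrame) -> dict:
        classes = [collapse_snv(r, a) for r, a in zip(sub["Reference_Allele"], sub["Tumor_Seq_Allele2"])]
        counted = pd.Series([c for c in classes if c is not None])
        skipped = sum(c is None for c in classes)
        pct = counted.value_counts(normalize=True).reindex(SNV_CLASSES, fill_value=0.0) * 100
        row = dict(pct)
        row["n_snv"] = len(counted)
        row["n_skipped"] = skipped
        return row

    rows = {"all": summarize(snv)}
    if groups is not None:
        for label, members in (("High-Mg", groups.high), ("Low-Mg", groups.low)):
            sub = snv[snv["Tumor_Sample_Barcode"].isin(set(members))]
            if not sub.empty:
                rows[label] = summarize(sub)
    return pd.DataFrame(rows).T


def somatic_interactions(
    records: pd.DataFrame,
    samples: Iterable[str],
    top_n: int = 20,
    alpha_strong: float = 0.01,
    alpha_weak: float = 0.05,
    classes: frozenset[str] | None = NONSILENT_CLASSES,
) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual-exclusivity among top mutated genes.

    For every unordered pair of the ``top_n`` most frequently mutated
    genes: counts (both, gene1 only, gene2 only, neither) over the sample
    set, two-sided Fisher exact p, direction by the odds ratio (> 1
    co-occurrence, < 1 mutual exclusivity), and the two significance tiers.
    """
    samples = list(samples)
    freq = mutation_frequency(records, samples, classes=classes)
    top = list(freq.index[:top_n])
    if len(top) < 2:
        raise ValueError("need at least 2 genes after top-n selection")
    per_gene = _mutated_samples(records, classes)
    sample_set = set(samples)
    carrier = {g: per_gene.get(g, set()) & sample_set for g in top}

    rows = []
    n = len(samples)
    for g1, g2 in combinations(top, 2):
        s1, s2 = carrier[g1], carrier[g2]
        both = len(s1 & s2)
        only1 = len(s1) - both
        only2 = len(s2) - both
        neither = n - both - only1 - only2
        odds, p = stats.fisher_exact([[both, only1], [only2, neither]], alternative="two-sided")
        rows.append(
            {
                "gene1": g1, "gene2": g2,
                "both": both, "gene1_only": only1, "gene2_only": only2, "neither": neither,
                "p": float(p),
                "odds_ratio": float(odds),
                "direction": "co-occurrence" if odds > 1 else "mutual_exclusivity",
                "tier": ("strong" if p < alpha_strong
                         else "weak" if p < alpha_weak else "ns"),
            }
        )
    return pd.DataFrame(rows)
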