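"""Isobaric (TMT) quantification ingest and data cleaning.

Implements the multi-batch cleaning pipeline for internal-standard (IS)
bridged TMT experiments:

1.  read per-batch tables (simplified search-output dialect, see README),
    dropping contaminant / reverse decoy rows;
2.  filter features (proteins need >= 2 unique peptides; phosphosites need
    localization probability > 0.75);
3.  scale every channel of a batch so total observed intensity is equal;
4.  divide sample channels by the IS channel, giving sample-to-standard
    (S/S) ratios that are comparable across batches;
5.  concatenate batches, log2-transform;
6.  z-score (column then row by default);
7.  drop features missing in more than half the samples.

A paired/unpaired Wilcoxon rank-sum differential-abundance test with a
median-log2-fold-change effect size rounds out the module.

Table dialect
-------------
Tab-separated, one row per feature.  Columns:

=====================  =====================================================
``feature_id``          protein id, or phosphosite id ``<protein>_<residue>``
``unique_peptides``     (protein tables) unique peptide count
``parent_protein``      (phospho tables) parent protein id
``localization_prob``   (phospho tables) site localization probability
``contaminant``         ``+`` flags a contaminant row, empty otherwise
``reverse``             ``+`` flags a reversed-decoy row
``intensity_<sample>``  reporter intensity for each channel; the IS channel
                        is ``intensity_IS``.  Zero means "not observed".
=====================  =====================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, StageError, as_float_frame

INTENSITY_PREFIX = "intensity_"
IS_CHANNEL = "IS"

PROTEIN_META = ("unique_peptides",)
PHOSPHO_META = ("parent_protein", "localization_prob")
FLAG_COLS = ("contaminant", "reverse")


@dataclass
class QuantTable:
    """One batch of raw (or total-intensity-scaled) quantification data."""

    intensities: pd.DataFrame        # features x channels, IS column included
    meta: pd.DataFrame               # per-feature metadata
    kind: str                        # "protein" | "phospho"
    batch: str
    is_channel: str = IS_CHANNEL
    stage: str = "raw"               # "raw" | "scaled"

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "phospho"):
            raise ValueError(f"kind must be 'protein' or 'phospho', got {self.kind!r}")
        if self.is_channel not in self.intensities.columns:
            raise ValueError(
                f"batch {self.batch!r} has no internal-standard channel "
                f"{self.is_channel!r}"
            )

    @property
    def sample_channels(self) -> list[str]:
        return [c for c in self.intensities.columns if c != self.is_channel]


def read_quant_table(
    path: str | Path,
    kind: str,
    batch: str | None = None,
    is_channel: str = IS_CHANNEL,
) -> QuantTable:
    """Read one batch table, dropping contaminant- and reverse-flagged rows.

    Unknown columns are ignored with a warning; malformed numerics raise
    with the offending row and column named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "feature_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'feature_id'")
    df = df.set_index("feature_id")

    meta_cols = PROTEIN_META if kind == "protein" else PHOSPHO_META
    missing_meta = [c for c in (*meta_cols, *FLAG_COLS) if c not in df.columns]
    if missing_meta:
        raise ValueError(f"{path}: missing required columns {missing_meta}")

    intensity_cols = [c for c in df.columns if c.startswith(INTENSITY_PREFIX)]
    known = set(meta_cols) | set(FLAG_COLS) | set(intensity_cols)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)

    keep = ~(df["contaminant"].eq("+") | df["reverse"].eq("+"))
    df = df.loc[keep]

    intensities = as_float_frame(df[intensity_cols])
    intensities.columns = [c.removeprefix(INTENSITY_PREFIX) for c in intensity_cols]
    if (intensities.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative intensities are not allowed")

    meta = df[list(meta_cols)].copy()
    if kind == "protein":
        meta["unique_peptides"] = pd.to_numeric(meta["unique_peptides"]).astype(int)
    else:
        meta["localization_prob"] = pd.to_numeric(meta["localization_prob"]).astype(float)

    return QuantTable(
        intensities=intensities,
        meta=meta,
        kind=kind,
        batch=batch if batch is not None else path.stem,
        is_channel=is_channel,
    )


def filter_features(
    table: QuantTable,
    min_unique_peptides: int = 2,
    min_localization_prob: float = 0.75,
) -> QuantTable:
    """Identification-quality filter.

    Proteins are kept with ``unique_peptides >= 2``; phosphosites with
    ``localization_prob > 0.75`` (strict: a site at exactly 0.75 is dropped).
    """
    if table.kind == "protein":
        keep = table.meta["unique_peptides"] >= min_unique_peptides
    else:
        keep = table.meta["localization_prob"] > min_localization_prob
    return replace(
        table,
        intensities=table.intensities.loc[keep],
        meta=table.meta.loc[keep],
    )


def scale_total_intensity(table: QuantTable) -> QuantTable:
    """Equalize total observed intensity across channels within a batch.

    Each channel is multiplied by a scalar so that all channel sums (over
    nonzero, i.e. observed, values) equal their pre-scaling mean.  Zeros
    (non-detections) stay zero and do not contribute to the sums.
    """
    if table.stage != "raw":
        raise StageError(f"scale_total_intensity expects raw table, got {table.stage!r}")
    vals = table.intensities.to_numpy(dtype=float)
    sums = np.where(vals > 0, vals, 0.0).sum(axis=0)
    if (sums == 0).any():
        dead = [c for c, s in zip(table.intensities.columns, sums) if s == 0]
        raise ValueError(f"batch {table.batch!r}: all-zero channels {dead}")
    target = sums.mean()
    scaled = pd.DataFrame(
        vals * (target / sums),
        index=table.intensities.index,
        columns=table.intensities.columns,
    )
    return replace(table, intensities=scaled, stage="scaled")


def bridge_to_is(table: QuantTable) -> ExpressionMatrix:
    """Divide sample channels by the internal-standard channel (S/S values).

    Zeros are non-detections and become missing: a sample value of zero is
    ``NaN``, and a row whose IS value is zero is missing for every sample in
    the batch.  The IS channel is dropped from the output.
    """
    if table.stage != "scaled":
        raise StageError(f"bridge_to_is expects scaled table, got {table.stage!r}")
    vals = table.intensities.replace(0.0, np.nan)
    is_col = vals[table.is_channel]
    ss = vals[table.sample_channels].div(is_col, axis=0)
    return ExpressionMatrix(
        values=ss,
        stage="s_over_s",
        batch_map={s: table.batch for s in table.sample_channels},
        note=f"batch {table.batch}: IS-bridged ({table.kind})",
    )


def combine_batches(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Outer-join S/S matrices over feature ids and log2-transform.

    Features absent from a batch are missing for that batch's samples.
    Duplicate sample ids across batches are an error.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    for m in matrices:
        m.require_stage("s_over_s", "log2")
    seen: set[str] = set()
    for m in matrices:
        dup = seen & set(m.values.columns)
        if dup:
            raise ValueError(f"duplicate sample ids across batches: {sorted(dup)[:5]}")
        seen |= set(m.values.columns)

    joined = pd.concat([m.values for m in matrices], axis=1, join="outer")
    batch_map: dict[str, str] = {}
    for m in matrices:
        batch_map.update(m.batch_map)
    if all(m.stage == "s_over_s" for m in matrices):
        with np.errstate(divide="ignore"):
            joined = np.log2(joined)
        stage = "log2"
        note = f"combined {len(matrices)} batches; log2(S/S)"
    else:
        stage = "log2"
        note = f"combined {len(matrices)} batches"
    return ExpressionMatrix(values=joined, stage=stage, batch_map=batch_map, note=note)


def zscore(matrix: ExpressionMatrix, axis: str) -> ExpressionMatrix:
    """Z-score along ``axis`` ("columns" standardizes each sample, "rows"
    each feature) over observed entries.

    Vectors with fewer than two observed values or zero variance cannot be
    standardized and become all-missing.
    """
    matrix.require_stage("log2", "zscore")
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    ax = 1 if axis == "rows" else 0
    vals = matrix.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=ax, keepdims=True)
        sd = np.nanstd(vals, axis=ax, ddof=1, keepdims=True)
        n_obs = np.sum(~np.isnan(vals), axis=ax, keepdims=True)
    bad = (n_obs < 2) | (sd == 0) | np.isnan(sd)
    out = (vals - mean) / np.where(bad, np.nan, sd)
    out = np.where(np.broadcast_to(bad, out.shape), np.nan, out)
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.advance("zscore", df, note=f"z-scored {axis}")


def dual_zscore(matrix: ExpressionMatrix, order: str = "columns_first") -> ExpressionMatrix:
    """Column and row z-scoring in a configurable order.

    The default standardizes samples first (removing residual per-sample
    loading) and features second.
    """
    if order == "columns_first":
        return zscore(zscore(matrix, "columns"), "rows")
    if order == "rows_first":
        return zscore(zscore(matrix, "rows"), "columns")
    raise ValueError("order must be 'columns_first' or 'rows_first'")


def filter_missing(matrix: ExpressionMatrix, max_missing_frac: float = 0.5) -> ExpressionMatrix:
    """Drop features missing in strictly more than ``max_missing_frac`` of samples.

    A feature missing in exactly half the samples is retained.  Idempotent.
    """
    frac = matrix.missing_fraction()
    keep = frac <= max_missing_frac
    out = replace(matrix, values=matrix.values.loc[keep])
    return out


@dataclass
class DifferentialResult:
    """Per-feature two-group comparison (Wilcoxon rank-sum)."""

    feature: str
    p: float
    effect: float       # median log2 fold change
    n_a: int
    n_b: int
    skipped: bool = False
    reason: str = ""


def _ranksum_p(a: np.ndarray, b: np.ndarray, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small untied samples."""
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= exact_max_n and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def differential_abundance(
    matrix: ExpressionMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    paired: bool = False,
) -> list[DifferentialResult]:
    """Wilcoxon rank-sum comparison of two sample groups per feature.

    The effect size is the median log2 fold change: with ``paired=True``
    (samples matched by position in the two group lists) the median of
    per-pair differences of log2 values; otherwise the difference of group
    medians.  Features with fewer than two observed values in either group
    are reported skipped.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if paired and len(group_a) != len(group_b):
        raise ValueError("paired comparison requires equal-length groups")

    va = matrix.values[group_a].to_numpy(dtype=float)
    vb = matrix.values[group_b].to_numpy(dtype=float)
    results: list[DifferentialResult] = []
    for i, feature in enumerate(matrix.values.index):
        a = va[i][~np.isnan(va[i])]
        b = vb[i][~np.isnan(vb[i])]
        if len(a) < 2 or len(b) < 2:
            results.append(
                DifferentialResult(feature, np.nan, np.nan, len(a), len(b),
                                   skipped=True, reason="fewer than 2 observed per group")
            )
            continue
        p = _ranksum_p(a, b)
        if paired:
            both = ~np.isnan(va[i]) & ~np.isnan(vb[i])
            diffs = va[i][both] - vb[i][both]
            effect = float(np.median(diffs)) if diffs.size else float("nan")
        else:
            effect = float(np.median(a) - np.median(b))
        results.append(DifferentialResult(feature, p, effect, len(a), len(b)))
    return results


def flag_differential(
    ratio: float,
    p: float,
    upper: float = 1.2,
    lower: float = 0.83,
    alpha: float = 0.05,
) -> bool:
    """Cell-experiment significance rule: fold-ratio outside [lower, upper]
    and p below alpha."""
    return bool((ratio > upper or ratio < lower) and p < alpha)


def differential_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature, "p": r.p, "effect": r.effect,
                "n_a": r.n_a, "n_b": r.n_b, "skipped": r.skipped, "reason": r.reason,
            }
            for r in results
        ]
    ).set_index("feature")
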