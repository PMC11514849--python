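"""Local gene-set enrichment statistics.

Two complementary procedures replace web-service enrichment:

* :func:`preranked_gsea` — the weighted Kolmogorov–Smirnov running-sum
  enrichment score on a preranked list (e.g. features ordered by their
  Spearman rho against Mg content), with a gene-label permutation null,
  sign-matched normalization (NES), nominal p, and the signed-pooling FDR
  convention;
* :func:`ora_hypergeom` — hypergeometric over-representation of a hit list
  against a background, with Benjamini–Hochberg q-values.

The running sum increments by ``|score|^weight`` (normalized over the
set's hits) at each set member and decrements by ``1/(N - |set|)``
otherwise; the enrichment score (ES) is the signed extreme deviation.
With ``weight=0`` the score reduces to the classic KS statistic and is
invariant under strictly monotone transforms of the ranking scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_qvalues

__all__ = ["read_gmt", "write_gmt", "enrichment_score", "preranked_gsea", "ora_hypergeom"]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set name: member set}``.

    Each line is tab-separated: name, description, then members.  Duplicate
    members are collapsed; malformed lines raise with their line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name = fields[0]
            sets[name] = set(fields[2:]) - {""}
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\tsynthetic\t{members}\n")


def enrichment_score(
    scores: np.ndarray,
    hit_positions: np.ndarray,
    weight: float = 1.0,
) -> float:
    """ES for one set given descending-sorted scores and hit indices.

    ``hit_positions`` are 0-based indices into the sorted list and must be
    sorted ascending.  Only the deviations at hit boundaries need checking:
    the running sum is piecewise linear between hits.
    """
    N = scores.size
    m = hit_positions.size
    if m == 0 or m == N:
        raise ValueError("set must be a proper non-empty subset of the list")
    w = np.abs(scores[hit_positions]) ** weight
    total = w.sum()
    if total == 0:
        # all hit scores are exactly zero: fall back to equal increments
        w = np.ones(m)
        total = float(m)
    cum_hit = np.cumsum(w) / total
    j = np.arange(1, m + 1)
    miss_after = (hit_positions + 1 - j) / (N - m)   # misses seen once hit j is included
    miss_before = (hit_positions - (j - 1)) / (N - m)
    dev_after = cum_hit - miss_after                 # running sum just after hit j
    dev_before = np.concatenate([[0.0], cum_hit[:-1]]) - miss_before  # just before hit j
    candidates = np.concatenate([dev_after, dev_before, [0.0]])
    return float(candidates[np.argmax(np.abs(candidates))])


def _null_es(
    scores: np.ndarray,
    set_size: int,
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene-label permutation null: ES of ``n_perm`` random position sets."""
    N = scores.size
    # random m-subsets via partial permutation, vectorized by row-sorting
    positions = np.argpartition(
        rng.random((n_perm, N)), set_size - 1, axis=1
    )[:, :set_size]
    positions.sort(axis=1)
    out = np.empty(n_perm)
    absw = np.abs(scores) ** weight
    for i in range(n_perm):
        pos = positions[i]
        w = absw[pos]
        total = w.sum()
        if total == 0:
            w = np.ones(set_size)
            total = float(set_size)
        cum_hit = np.cumsum(w) / total
        j = np.arange(1, set_size + 1)
        dev_after = cum_hit - (pos + 1 - j) / (N - set_size)
        dev_before = np.concatenate([[0.0], cum_hit[:-1]]) - (pos - (j - 1)) / (N - set_size)
        cands = np.concatenate([dev_after, dev_before, [0.0]])
        out[i] = cands[np.argmax(np.abs(cands))]
    return out


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    size: int
    leading_edge: list[str]


def preranked_gsea(
    ranked: pd.Series,
    sets: Mapping[str, set[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a score-ordered feature list.

    Parameters
    ----------
    ranked
        Series mapping feature id -> ranking score, sorted (or sortable)
        descending.  Ids must be unique.
    sets
        Gene sets; members outside the ranked list are ignored, and sets
        whose intersection falls outside ``[min_size, max_size]`` are
        skipped.
    weight
        Exponent on |score| for hit increments (0 gives the unweighted KS
        statistic; 1 is the classic weighted form).
    n_perm
        Gene-label permutations for the null distribution.

    Returns a frame with ES, NES (ES divided by the mean |null ES| of the
    same sign), nominal p (same-sign null tail), signed-pooling FDR q,
    set size after intersection, and the leading-edge members.
    """
    if ranked.index.has_duplicates:
        raise ValueError("ranked list contains duplicate ids")
    ranked = ranked.sort_values(ascending=False)
    ids = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    N = scores.size
    id_pos = {g: i for i, g in enumerate(ids)}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows = []
    null_by_size: dict[int, np.ndarray] = {}
    all_nes: list[float] = []
    all_null_nes: list[np.ndarray] = []
    for name, members in sets.items():
        pos = np.array(sorted(id_pos[g] for g in members if g in id_pos), dtype=int)
        size = pos.size
        if size < min_size or size > max_size or size == N:
            continue
        es = enrichment_score(scores, pos, weight=weight)
        if size not in null_by_size:
            null_by_size[size] = _null_es(scores, size, weight, n_perm, rng)
        null = null_by_size[size]
        same_sign = null[null >= 0] if es >= 0 else -null[null < 0]
        if same_sign.size == 0:
            nes = np.nan
            p = 1.0 / (n_perm + 1)
        else:
            denom = same_sign.mean()
            nes = es / denom if es >= 0 else -abs(es) / denom
            p = float(np.mean(same_sign >= abs(es)))
            p = max(p, 1.0 / (n_perm + 1))
        # leading edge: members at or before the extreme of the running sum
        w = np.abs(scores[pos]) ** weight
        total = w.sum() or float(size)
        cum_hit = np.cumsum(w) / total
        j = np.arange(1, size + 1)
        dev = cum_hit - (pos + 1 - j) / (N - size)
        if es >= 0:
            peak = int(np.argmax(dev))
            le = ids[pos[: peak + 1]].tolist()
        else:
            dev_before = np.concatenate([[0.0], cum_hit[:-1]]) - (pos - (j - 1)) / (N - size)
            trough = int(np.argmin(dev_before))
            le = ids[pos[trough:]].tolist()
        with np.errstate(invalid="ignore", divide="ignore"):
            pos_null = null[null >= 0]
            neg_null = null[null < 0]
            null_nes = np.concatenate(
                [
                    pos_null / pos_null.mean() if pos_null.size else pos_null,
                    neg_null / abs(neg_null.mean()) if neg_null.size else neg_null,
                ]
            )
        all_null_nes.append(null_nes)
        all_nes.append(nes)
        rows.append({"name": name, "es": es, "nes": nes, "p": p, "size": size,
                     "leading_edge": le})

    if not rows:
        return pd.DataFrame(columns=["name", "es", "nes", "p", "fdr_q", "size",
                                     "leading_edge"]).set_index("name")

    # FDR: positive and negative NES calibrated against the pooled null NES
    nes_arr = np.array(all_nes)
    pooled = np.concatenate(all_null_nes)
    fdr = np.empty(nes_arr.size)
    for i, nes in enumerate(nes_arr):
        if np.isnan(nes):
            fdr[i] = np.nan
            continue
        if nes >= 0:
            null_frac = np.mean(pooled >= nes) if pooled.size else 1.0
            obs_frac = np.mean(nes_arr[~np.isnan(nes_arr)] >= nes)
        else:
            null_frac = np.mean(pooled <= nes) if pooled.size else 1.0
            obs_frac = np.mean(nes_arr[~np.isnan(nes_arr)] <= nes)
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    out = pd.DataFrame(rows).set_index("name")
    out["fdr_q"] = fdr
    return out[["es", "nes", "p", "fdr_q", "size", "leading_edge"]].sort_values("p")


def ora_hypergeom(
    hits: set[str],
    background: set[str],
    sets: Mapping[str, set[str]],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` within ``background``.

    For each set, the upper-tail probability of drawing at least the
    observed overlap when sampling ``|hits|`` features from the background.
    Sets disjoint from the background are skipped.  Benjamini–Hochberg
    q-values are appended.
    """
    if not hits:
        raise ValueError("empty hit list")
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    M = len(background)
    n_hits = len(hits)
    rows = []
    for name, members in sets.items():
        in_bg = members & background
        if not in_bg:
            continue
        k = len(hits & in_bg)
        p = float(stats.hypergeom.sf(k - 1, M, len(in_bg), n_hits))
        rows.append(
            {
                "name": name, "overlap": k, "set_size": len(in_bg),
                "n_hits": n_hits, "background": M, "p": p,
                "members": sorted(hits & in_bg),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.set_index("name")
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out.sort_values("p")
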