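"""Screens of omics features against tissue magnesium content.

The exposure is the intratumoral Mg content (μg per g of extracted
protein).  Because only the ordering of Mg values is used, every screen in
this module is invariant under strictly monotone transforms of the
exposure:

* :func:`spearman_screen` — per-feature Spearman rank correlation with
  pairwise-complete observations; exact permutation p for tiny n, the usual
  t-approximation otherwise;
* :func:`stratified_screen` — left-/right-sided tumors screened separately
  with a three-way overlap summary per direction;
* :func:`protein_adjusted_phospho_screen` — partial Spearman correlation of
  a phosphosite with Mg controlling for the parent protein, to isolate
  phosphorylation signal not explained by protein abundance;
* :func:`dichotomize_mg` — High-/Low-Mg group labels by maximally selected
  log-rank cutpoint (default), median, or a fixed threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .survival import max_selected_cutpoint

__all__ = [
    "MgGroups",
    "spearman_screen",
    "stratified_screen",
    "protein_adjusted_phospho_screen",
    "dichotomize_mg",
    "spearman_with_p",
]

EXACT_MAX_N = 9


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (NaN-aware)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


_PERM_CACHE: dict[int, np.ndarray] = {}


def _perm_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n), cached (n <= 9)."""
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(list(permutations(range(n))), dtype=np.int8)
    return _PERM_CACHE[n]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all n! pairings (n <= 9).

    Ranking is permutation-equivariant, so permuting the centered x-ranks
    enumerates the same distribution as permuting x itself; each
    permutation's rho is then a single dot product.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    if denom == 0:
        return np.nan
    perms = _perm_matrix(n)
    target = abs(rho_obs) - 1e-12
    count = 0
    chunk = 200_000
    for i in range(0, perms.shape[0], chunk):
        rhos = (rx_c[perms[i : i + chunk].astype(np.intp)] @ ry_c) / denom
        count += int(np.count_nonzero(np.abs(rhos) >= target))
    return count / perms.shape[0]


def spearman_with_p(x, y, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float, int]:
    """Spearman rho and two-sided p on complete pairs.

    Average ranks for ties; exact permutation p when n <= ``exact_max_n``,
    else the t-approximation on rho with n - 2 degrees of freedom.
    Returns (rho, p, n_pairs); rho is NaN when either margin is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2:
        return np.nan, np.nan, n
    rho = _spearman_rho(x, y)
    if np.isnan(rho):
        return np.nan, np.nan, n
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(tstat), n - 2))
    return rho, p, n


def spearman_screen(
    matrix: ExpressionMatrix,
    mg: Mapping[str, float],
    alpha: float = 0.05,
    min_pairs: int = 10,
    stratum: str = "all",
) -> pd.DataFrame:
    """Correlate every feature with Mg content over pairwise-complete samples.

    Returns a frame indexed by feature with columns ``rho, p, q, n,
    direction, significant, tested, reason``.  Features with fewer than
    ``min_pairs`` complete pairs, or a constant margin, are reported
    untested.  ``direction`` is the sign of rho; ``significant`` means
    p < alpha (raw, matching the screening convention; q-values are
    reported alongside).
    """
    samples = [s for s in matrix.values.columns if s in mg and not pd.isna(mg[s])]
    if not samples:
        raise ValueError("no samples with Mg measurements in the matrix")
    mg_vec = np.array([mg[s] for s in samples], dtype=float)
    vals = matrix.values[samples].to_numpy(dtype=float)

    n_feat = vals.shape[0]
    rho = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    npairs = np.zeros(n_feat, dtype=int)
    reason = np.array([""] * n_feat, dtype=object)

    # fast path: features with no missing values share one ranked Mg vector
    complete_rows = ~np.isnan(vals).any(axis=1)
    n = len(samples)
    if complete_rows.any() and n > EXACT_MAX_N:
        sub = vals[complete_rows]
        r_mg = stats.rankdata(mg_vec)
        r_feat = np.apply_along_axis(stats.rankdata, 1, sub)
        r_mg_c = r_mg - r_mg.mean()
        r_feat_c = r_feat - r_feat.mean(axis=1, keepdims=True)
        denom = np.sqrt((r_feat_c**2).sum(axis=1) * (r_mg_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = (r_feat_c @ r_mg_c) / denom
        rr[denom == 0] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = rr * np.sqrt((n - 2) / (1 - rr**2))
        pp = 2 * stats.t.sf(np.abs(tstat), n - 2)
        pp = np.where(np.abs(rr) >= 1.0, 0.0, pp)
        rho[complete_rows] = rr
        p[complete_rows] = pp
        npairs[complete_rows] = n
        slow_rows = np.where(~complete_rows)[0]
    else:
        slow_rows = np.arange(n_feat)

    for i in slow_rows:
        n_ok = int((~np.isnan(vals[i])).sum())
        if n_ok < min_pairs:
            npairs[i] = n_ok  # untested: skip the (possibly exact) p machinery
            continue
        rho[i], p[i], npairs[i] = spearman_with_p(vals[i], mg_vec)

    tested = (npairs >= min_pairs) & ~np.isnan(rho)
    reason[npairs < min_pairs] = "fewer complete pairs than min_pairs"
    reason[(npairs >= min_pairs) & np.isnan(rho)] = "constant feature or Mg over complete pairs"
    p = np.where(tested, p, np.nan)
    rho = np.where(tested, rho, np.nan)

    out = pd.DataFrame(
        {
            "rho": rho,
            "p": p,
            "q": bh_qvalues(p),
            "n": npairs,
            "direction": np.where(np.isnan(rho), "", np.where(rho >= 0, "positive", "negative")),
            "significant": tested & (p < alpha),
            "tested": tested,
            "reason": reason,
            "stratum": stratum,
        },
        index=matrix.values.index,
    )
    return out


def stratified_screen(
    matrix: ExpressionMatrix,
    mg: Mapping[str, float],
    strata: Mapping[str, str],
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> dict:
    """Run the Mg screen separately per stratum (e.g. left/right-sided
    tumors) and summarize the overlap of significant features.

    Returns ``{"results": {stratum: frame}, "overlap": {direction: {...}},
    "skipped": [...]}`` where the overlap holds both counts and id lists
    for each cell of the two-set Venn diagram.
    """
    results: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    for name in sorted(set(strata.values())):
        members = [s for s, st in strata.items() if st == name and s in matrix.values.columns]
        members = [s for s in members if s in mg]
        if len(members) < min_pairs:
            skipped.append(name)
            continue
        sub = matrix.subset_samples(members)
        results[name] = spearman_screen(sub, mg, alpha=alpha, min_pairs=min_pairs, stratum=name)

    overlap: dict[str, dict] = {}
    if len(results) == 2:
        (name_a, res_a), (name_b, res_b) = sorted(results.items())
        for direction in ("positive", "negative"):
            sig_a = set(res_a.index[(res_a["significant"]) & (res_a["direction"] == direction)])
            sig_b = set(res_b.index[(res_b["significant"]) & (res_b["direction"] == direction)])
            overlap[direction] = {
                "both": sorted(sig_a & sig_b),
                f"{name_a}_only": sorted(sig_a - sig_b),
                f"{name_b}_only": sorted(sig_b - sig_a),
                "counts": {
                    "both": len(sig_a & sig_b),
                    f"{name_a}_only": len(sig_a - sig_b),
                    f"{name_b}_only": len(sig_b - sig_a),
                },
            }
    return {"results": results, "overlap": overlap, "skipped": skipped}


def default_parent_map(site_ids) -> dict[str, str]:
    """Derive parent protein ids from ``<protein>_<residue>`` site ids."""
    return {s: s.rsplit("_", 1)[0] for s in site_ids}


def _partial_spearman(site, mg, prot) -> tuple[float, float, int]:
    """Partial Spearman of site vs Mg controlling for protein.

    Rank-transform all three, regress site- and Mg-ranks on protein ranks,
    correlate the residuals; t-test with n - 3 degrees of freedom.
    """
    ok = ~np.isnan(site) & ~np.isnan(mg) & ~np.isnan(prot)
    n = int(ok.sum())
    if n < 4:
        return np.nan, np.nan, n
    rs = stats.rankdata(site[ok])
    rm = stats.rankdata(mg[ok])
    rp = stats.rankdata(prot[ok])
    rp_c = rp - rp.mean()
    denom = (rp_c**2).sum()
    if denom == 0:
        # constant protein: partial reduces to the marginal correlation
        res_s, res_m = rs - rs.mean(), rm - rm.mean()
    else:
        res_s = rs - rs.mean() - rp_c * ((rs - rs.mean()) @ rp_c) / denom
        res_m = rm - rm.mean() - rp_c * ((rm - rm.mean()) @ rp_c) / denom
    norm = np.sqrt((res_s**2).sum() * (res_m**2).sum())
    if norm < 1e-12:
        # no residual variation: the covariate fully explains the site
        return 0.0, 1.0, n
    r = float((res_s @ res_m) / norm)
    if abs(r) >= 1.0:
        return r, 0.0, n
    tstat = r * np.sqrt((n - 3) / (1 - r**2))
    p = float(2 * stats.t.sf(abs(tstat), n - 3))
    return r, p, n


def protein_adjusted_phospho_screen(
    phospho_matrix: ExpressionMatrix,
    protein_matrix: ExpressionMatrix,
    mg: Mapping[str, float],
    alpha: float = 0.05,
    min_pairs: int = 10,
    parent_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Screen phosphosites against Mg independent of parent-protein level.

    A site is called *protein-independent Mg-associated* when the marginal
    Spearman p and the protein-partialled Spearman p are both below alpha
    with the same correlation sign.  Sites whose parent protein is absent
    from ``protein_matrix`` (or missing in more than half of the site's
    complete pairs) are reported marginal-only.
    """
    if parent_map is None:
        parent_map = default_parent_map(phospho_matrix.values.index)
    samples = [s for s in phospho_matrix.values.columns if s in mg]
    mg_vec = np.array([mg[s] for s in samples], dtype=float)
    site_vals = phospho_matrix.values[samples]
    prot_cols = [s for s in samples if s in protein_matrix.values.columns]

    rows = []
    for site in phospho_matrix.values.index:
        sv = site_vals.loc[site].to_numpy(dtype=float)
        m_rho, m_p, m_n = spearman_with_p(sv, mg_vec)
        parent = parent_map.get(site)
        rec = {
            "site": site,
            "parent": parent or "",
            "marginal_rho": m_rho,
            "marginal_p": m_p,
            "n": m_n,
            "partial_rho": np.nan,
            "partial_p": np.nan,
            "marginal_only": True,
            "reason": "",
        }
        if parent is None or parent not in protein_matrix.values.index:
            rec["reason"] = "parent protein not quantified"
        elif m_n < min_pairs:
            rec["reason"] = "fewer complete pairs than min_pairs"
        else:
            pv_full = np.full(len(samples), np.nan)
            pv = protein_matrix.values.loc[parent, prot_cols].to_numpy(dtype=float)
            pv_full[[samples.index(s) for s in prot_cols]] = pv
            site_ok = ~np.isnan(sv) & ~np.isnan(mg_vec)
            prot_missing = np.isnan(pv_full[site_ok]).mean() if site_ok.any() else 1.0
            if prot_missing > 0.5:
                rec["reason"] = "parent protein missing in > 50% of complete pairs"
            else:
                p_rho, p_p, p_n = _partial_spearman(sv, mg_vec, pv_full)
                rec.update(partial_rho=p_rho, partial_p=p_p, marginal_only=False)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("site")
    out["marginal_q"] = bh_qvalues(out["marginal_p"].to_numpy())
    same_sign = np.sign(out["marginal_rho"]) == np.sign(out["partial_rho"])
    out["protein_independent"] = (
        ~out["marginal_only"]
        & (out["marginal_p"] < alpha)
        & (out["partial_p"] < alpha)
        & same_sign
    )
    return out


@dataclass
class MgGroups:
    """High-/Low-Mg dichotomization of the cohort."""

    threshold: float
    labels: dict[str, str]       # sample -> "High-Mg" | "Low-Mg"
    method: str

    @property
    def high(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == "High-Mg"]

    @property
    def low(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == "Low-Mg"]

    def relabel(self, mg: Mapping[str, float]) -> "MgGroups":
        """Apply this threshold to another sample set (e.g. a subcohort)."""
        labels = {
            s: ("Low-Mg" if v < self.threshold else "High-Mg")
            for s, v in mg.items()
            if not pd.isna(v)
        }
        return MgGroups(self.threshold, labels, self.method)


def dichotomize_mg(
    clinical: pd.DataFrame,
    method: str = "max_logrank",
    minprop: float = 0.1,
    threshold: float | None = None,
    mg_col: str = "mg_content",
    time_col: str = "os_months",
    event_col: str = "os_event",
    seed: int = 0,
    n_perm: int = 1000,
) -> MgGroups:
    """Label samples High-/Low-Mg.

    ``max_logrank`` picks the survival-optimal cutpoint on Mg content
    (see :func:`mgomics.survival.max_selected_cutpoint`); ``median`` splits
    at the median; ``fixed`` uses the supplied ``threshold``.  Low-Mg means
    Mg content strictly below the threshold.
    """
    mg = clinical[mg_col]
    if mg.isna().any():
        raise ValueError("Mg content missing for some samples")
    if method == "max_logrank":
        cp = max_selected_cutpoint(
            clinical[time_col].to_numpy(),
            clinical[event_col].to_numpy(),
            mg.to_numpy(),
            minprop=minprop,
            p_method="none" if n_perm == 0 else "permutation",
            n_perm=n_perm,
            seed=seed,
        )
        thr = cp.threshold
    elif method == "median":
        thr = float(mg.median())
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method 'fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = {s: ("Low-Mg" if v < thr else "High-Mg") for s, v in mg.items()}
    return MgGroups(threshold=thr, labels=labels, method=method)
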