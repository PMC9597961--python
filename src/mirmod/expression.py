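"""Normalization, expressed-feature filtering, and differential expression.

Contrasts are NaCl vs control within one (genotype, timepoint) cell of the
48-library design, three replicates per arm.

* miRNAs: counts-per-million (CPM), equal-variance two-sample t-test on the
  normalized values, significant at p < 0.05 (no fold-change condition).
* transcripts: FPKM, Welch t-test on log2(FPKM + 1), significant at
  p < 0.05 and |log2FC| > 1.

Raw p-values are thresholded directly; a Benjamini-Hochberg column is
emitted for information only. Fold changes use a pseudocount of one
normalized unit to keep zero means finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GENOTYPES, TIMEPOINTS_H, ExpressionMatrix

DE_STATUSES = ("up", "down", "ns", "not_expressed")


@dataclass
class NormalizedMatrix:
    """Features x libraries normalized abundances (CPM or FPKM)."""

    values: pd.DataFrame
    design: list
    method: str                     # "CPM" | "FPKM"
    feature_lengths: dict[str, int] | None = None

    def libraries(self, **kw) -> list[str]:
        return ExpressionMatrix(self.values, self.design).libraries(**kw)


def normalize_cpm(raw: ExpressionMatrix) -> NormalizedMatrix:
    """Counts per million: count * 1e6 / library total."""
    vals = raw.values.astype(float)
    totals = vals.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero libraries left as zeros: {list(totals.index[zero])}")
        totals = totals.replace(0, np.nan)
    cpm = vals * 1e6 / totals
    return NormalizedMatrix(cpm.fillna(0.0), list(raw.design), "CPM")


def tmm_factors(raw: ExpressionMatrix, logratio_trim: float = 0.3,
                abundance_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors (one per library).

    Plain library-total scaling is compositionally biased: a handful of
    abundant features moving in one condition shifts every other feature's
    CPM in that condition. TMM estimates a robust per-library correction
    from the doubly trimmed, precision-weighted mean of the log count
    ratios against a reference library (the one whose count sum is closest
    to the median), and rescales factors to geometric mean 1.
    """
    counts = raw.values.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("TMM undefined for all-zero libraries")
    ref_idx = int(np.argmin(np.abs(totals - np.median(totals))))
    ref, n_ref = counts[:, ref_idx], totals[ref_idx]

    factors = np.ones(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref_idx:
            continue
        obs, n_obs = counts[:, k], totals[k]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 10:
            continue
        p_obs, p_ref = obs[ok] / n_obs, ref[ok] / n_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
        n = m.size
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abundance_trim, 1 - abundance_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            continue
        factors[k] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=raw.values.columns)


def normalize_tmm(raw: ExpressionMatrix) -> NormalizedMatrix:
    """CPM on TMM-corrected effective library sizes (count sum x TMM factor)."""
    vals = raw.values.astype(float)
    eff = vals.sum(axis=0) * tmm_factors(raw)
    out = vals * 1e6 / eff
    return NormalizedMatrix(out.fillna(0.0), list(raw.design), "TMM")


def normalize_fpkm(raw: ExpressionMatrix, lengths: Mapping[str, int]) -> NormalizedMatrix:
    """Fragments per kilobase per million mapped: count * 1e9 / (total * length_nt)."""
    missing = [f for f in raw.features if f not in lengths]
    if missing:
        raise ValueError(f"missing feature lengths for {missing[:5]}...")
    lens = pd.Series({f: float(lengths[f]) for f in raw.features})
    if (lens <= 0).any():
        raise ValueError("feature lengths must be positive")
    vals = raw.values.astype(float)
    totals = vals.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero libraries left as zeros: {list(totals.index[zero])}")
        totals = totals.replace(0, np.nan)
    fpkm = (vals * 1e9).div(totals, axis=1).div(lens, axis=0)
    return NormalizedMatrix(fpkm.fillna(0.0), list(raw.design), "FPKM",
                            feature_lengths={f: int(lengths[f]) for f in raw.features})


def expressed_filter(norm: NormalizedMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Per-genotype expressed calls.

    A feature is expressed in a genotype when its normalized value is
    >= ``threshold`` in at least one of that genotype's libraries (the
    "FPKM >= 1 in at least one sample" rule, applied per genotype).
    Returns a features x [ST, SS, genotype_specific] frame.
    """
    out = pd.DataFrame(index=norm.values.index)
    for g in GENOTYPES:
        libs = norm.libraries(genotype=g)
        out[g] = (norm.values[libs] >= threshold).any(axis=1)
    out["genotype_specific"] = out["ST"] ^ out["SS"]
    return out


def _t_equal_var(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    return res.statistic, res.pvalue


def _t_welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return res.statistic, res.pvalue


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (informational column)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def _de_table(norm: NormalizedMatrix, genotype: str, timepoint_h: float,
              expressed: pd.DataFrame | None, *, log_transform: bool,
              equal_var: bool, alpha: float, min_abs_log2fc: float,
              pseudocount: float) -> pd.DataFrame:
    ct_libs = norm.libraries(genotype=genotype, timepoint_h=timepoint_h, condition="CT")
    nacl_libs = norm.libraries(genotype=genotype, timepoint_h=timepoint_h, condition="NaCl")
    if len(ct_libs) < 2 or len(nacl_libs) < 2:
        raise ValueError(
            f"contrast ({genotype}, {timepoint_h} h) needs >= 2 replicates per arm; "
            f"found {len(ct_libs)} CT / {len(nacl_libs)} NaCl")
    ct = norm.values[ct_libs].to_numpy(dtype=float)
    nacl = norm.values[nacl_libs].to_numpy(dtype=float)

    mean_ct = ct.mean(axis=1)
    mean_nacl = nacl.mean(axis=1)
    log2fc = np.log2((mean_nacl + pseudocount) / (mean_ct + pseudocount))

    test_ct = np.log2(ct + 1.0) if log_transform else ct
    test_nacl = np.log2(nacl + 1.0) if log_transform else nacl
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            t, p = _t_equal_var(test_ct, test_nacl)
        else:
            t, p = _t_welch(test_ct, test_nacl)

    status = np.where(
        np.isnan(p) | (p >= alpha) | (np.abs(log2fc) <= min_abs_log2fc),
        "ns",
        np.where(log2fc > 0, "up", "down"),
    ).astype(object)
    # a zero fold change can never be called in either direction
    status[log2fc == 0] = "ns"
    if expressed is not None:
        not_expr = ~expressed[genotype].reindex(norm.values.index).fillna(False).to_numpy()
        status[not_expr] = "not_expressed"

    return pd.DataFrame(
        {
            "feature_id": norm.values.index,
            "genotype": genotype,
            "timepoint_h": float(timepoint_h),
            "mean_CT": mean_ct,
            "mean_NaCl": mean_nacl,
            "log2fc": log2fc,
            "t": t,
            "p_value": p,
            "p_bh": bh_adjust(p),
            "status": status,
        }
    ).reset_index(drop=True)


def de_mirna(norm: NormalizedMatrix, genotype: str, timepoint_h: float,
             expressed: pd.DataFrame | None = None, alpha: float = 0.05,
             pseudocount: float = 1.0) -> pd.DataFrame:
    """miRNA differential expression at one (genotype, timepoint) contrast.

    Equal-variance Student t-test on CPM; up/down when p < alpha with the
    sign of log2((mean_NaCl + c) / (mean_CT + c)), c = 1 CPM.
    """
    return _de_table(norm, genotype, timepoint_h, expressed,
                     log_transform=False, equal_var=True, alpha=alpha,
                     min_abs_log2fc=0.0, pseudocount=pseudocount)


def de_mrna(norm: NormalizedMatrix, genotype: str, timepoint_h: float,
            expressed: pd.DataFrame | None = None, alpha: float = 0.05,
            min_abs_log2fc: float = 1.0, pseudocount: float = 1.0) -> pd.DataFrame:
    """Transcript differential expression at one contrast.

    Welch t-test on log2(FPKM + 1); up/down requires p < alpha AND
    |log2FC| > ``min_abs_log2fc``.
    """
    return _de_table(norm, genotype, timepoint_h, expressed,
                     log_transform=True, equal_var=False, alpha=alpha,
                     min_abs_log2fc=min_abs_log2fc, pseudocount=pseudocount)


def de_all_contrasts(norm: NormalizedMatrix, kind: str,
                     expressed: pd.DataFrame | None = None, **kw) -> pd.DataFrame:
    """DE table over every (genotype, timepoint) contrast, concatenated."""
    fn = {"mirna": de_mirna, "mrna": de_mrna}[kind]
    frames = [fn(norm, g, t, expressed, **kw) for g in GENOTYPES for t in TIMEPOINTS_H]
    return pd.concat(frames, ignore_index=True)


def retained_mirnas(norm: NormalizedMatrix, min_mean_cpm: float = 1.0) -> list[str]:
    """miRNAs with middle-or-high expression: mean CPM >= threshold over all libraries."""
    means = norm.values.mean(axis=1)
    return list(means.index[means >= min_mean_cpm])


def ddct(ct_target_treat: Sequence[float], ct_ref_treat: Sequence[float],
         ct_target_ctrl: Sequence[float], ct_ref_ctrl: Sequence[float]) -> dict:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per replicate; ddCt is the mean dCt of the
    treated group minus the mean dCt of the calibrator (control) group, and
    relative expression is 2^-ddCt. Group difference is assessed with a
    Student t-test on the replicate dCt values.
    """
    dct_treat = np.asarray(ct_target_treat, float) - np.asarray(ct_ref_treat, float)
    dct_ctrl = np.asarray(ct_target_ctrl, float) - np.asarray(ct_ref_ctrl, float)
    if dct_treat.size != np.asarray(ct_ref_treat).size:
        raise ValueError("unmatched Ct replicate vectors")
    ddct_val = dct_treat.mean() - dct_ctrl.mean()
    if dct_treat.size >= 2 and dct_ctrl.size >= 2:
        p = float(stats.ttest_ind(dct_treat, dct_ctrl, equal_var=True).pvalue)
    else:
        p = float("nan")
    return {
        "ddct": float(ddct_val),
        "relative_expression": float(2.0 ** (-ddct_val)),
        "p_value": p,
    }
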