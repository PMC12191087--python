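"""Acquisition-parameter statistics over the metadata table.

For each header parameter and modality: a Kruskal-Wallis rank test across
the 3-point quality scale, a two-sample Kolmogorov-Smirnov test between
passing and failing scans (exact p for small samples), and a piecewise
logistic threshold scan. Categorical parameters (phase-encoding direction)
use a 2x2 Fisher exact test instead of KS. P-value families are adjusted
independently per test type. Missingness is reported, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fusion import collapse_to_binary
from .rectal import fit_piecewise_logistic

log = logging.getLogger(__name__)

NUMERIC_PARAMS = (
    "repetition_time_ms", "echo_time_ms", "fov_h_mm", "fov_v_mm",
    "resolution_h_px", "resolution_v_px",
)
CATEGORICAL_PARAMS = ("phase_encoding_direction",)
MIN_N = 10


@dataclass
class ParamAnalysis:
    parameter: str
    modality: str
    n_present: int
    n_missing: int
    tested: bool
    reason: str = ""
    kruskal_H: float = float("nan")
    kruskal_p: float = float("nan")
    ks_D: float = float("nan")
    ks_p: float = float("nan")
    fisher_odds: float = float("nan")
    fisher_p: float = float("nan")
    threshold: float = float("nan")
    threshold_auc: float = float("nan")
    kruskal_p_adj: float = float("nan")
    ks_p_adj: float = float("nan")


def adjust_pvalues(pvalues, method: str = "holm_sidak") -> list:
    """Family-wise multiplicity adjustment.

    ``holm_sidak``: step-down Holm-Sidak (1-(1-p)^m sequence with running
    maxima). ``dunn_family``: classical Bonferroni over the pairwise
    family. Adjusted values are clipped to [0, 1] and never smaller than
    the raw p.
    """
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return []
    if method == "holm_sidak":
        adj = multipletests(p, method="holm-sidak")[1]
    elif method == "dunn_family":
        adj = np.clip(p * len(p), 0.0, 1.0)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return [float(x) for x in np.maximum(adj, p)]


def two_sample_ks(x, y) -> tuple[float, float]:
    """Two-sample KS; exact p when both samples have n <= 25."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    method = "exact" if max(len(x), len(y)) <= 25 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def analyze_parameter(values, quality_labels, name: str = "",
                      modality: str = "", *, categorical: bool = False,
                      threshold_scan: bool = True) -> ParamAnalysis:
    """Run the multi-pronged test battery for one parameter.

    ``values`` may contain NaN/None for missing header entries; these are
    reported and excluded. Parameters with fewer than 10 observed values
    are reported untested.
    """
    vals = pd.Series(list(values))
    labs = np.asarray(quality_labels)
    present = vals.notna().to_numpy()
    n_present, n_missing = int(present.sum()), int((~present).sum())
    out = ParamAnalysis(parameter=name, modality=modality,
                        n_present=n_present, n_missing=n_missing, tested=False)
    if n_present == 0:
        out.reason = "all values missing"
        return out
    if n_present < MIN_N:
        out.reason = f"only {n_present} observed values (< {MIN_N})"
        return out
    v = vals[present]
    q = labs[present]
    passing = q >= 2
    out.tested = True

    if categorical:
        cats = sorted(v.unique())
        if len(cats) < 2 or passing.all() or (~passing).all():
            out.reason = "degenerate categorical table"
            out.tested = False
            return out
        table = np.array([
            [int(((v == cats[0]) & passing).sum()), int(((v == cats[0]) & ~passing).sum())],
            [int(((v != cats[0]) & passing).sum()), int(((v != cats[0]) & ~passing).sum())],
        ])
        odds, p = stats.fisher_exact(table)
        out.fisher_odds, out.fisher_p = float(odds), float(p)
        return out

    vnum = v.astype(float).to_numpy()
    groups = [vnum[q == g] for g in (1, 2, 3) if np.sum(q == g) > 0]
    if len(groups) >= 2 and np.ptp(vnum) > 0:
        H, p = stats.kruskal(*groups)
        out.kruskal_H, out.kruskal_p = float(H), float(p)
    else:
        out.kruskal_H, out.kruskal_p = 0.0, 1.0

    if passing.any() and (~passing).any():
        if np.ptp(vnum) == 0:
            out.ks_D, out.ks_p = 0.0, 1.0
        else:
            out.ks_D, out.ks_p = two_sample_ks(vnum[passing], vnum[~passing])

    if np.ptp(vnum) == 0:
        out.threshold = float("nan")  # non-identifiable for a constant
    elif threshold_scan and n_present >= 20 and passing.any() and (~passing).any():
        try:
            bp = fit_piecewise_logistic(vnum, (~passing).astype(int))
            out.threshold, out.threshold_auc = bp.breakpoint, bp.auc
        except Exception as e:  # pragma: no cover - degenerate scans
            log.warning("threshold scan failed for %s: %s", name, e)
    return out


def analyze_table(metadata_df: pd.DataFrame, labels_df: pd.DataFrame) -> pd.DataFrame:
    """Analyze every parameter for every modality; one row per pair.

    ``metadata_df`` follows the phantom metadata schema; ``labels_df``
    carries patient_id / site_id / quality_t2 / quality_adc. Adjusted
    p-values are computed per test family (Kruskal-Wallis and KS
    separately), per the package's multiplicity policy.
    """
    merged = metadata_df.merge(labels_df, on=["patient_id", "site_id"], how="left")
    rows = []
    for modality in ("t2", "adc"):
        sub = merged[merged.modality == modality]
        q = sub[f"quality_{modality}"].to_numpy()
        for p in NUMERIC_PARAMS:
            rows.append(analyze_parameter(sub[p], q, name=p, modality=modality))
        for p in CATEGORICAL_PARAMS:
            rows.append(analyze_parameter(sub[p], q, name=p, modality=modality,
                                          categorical=True))
        if modality == "adc" and "b_values" in sub.columns:
            parsed = sub["b_values"].map(
                lambda s: None if (pd.isna(s) or str(s) == "")
                else max(float(x) for x in str(s).split(";"))
            )
            rows.append(analyze_parameter(parsed, q, name="max_b_value",
                                          modality=modality))
            counts = sub["b_values"].map(
                lambda s: None if (pd.isna(s) or str(s) == "")
                else len(str(s).split(";"))
            )
            rows.append(analyze_parameter(counts, q, name="n_b_values",
                                          modality=modality))
    df = pd.DataFrame([r.__dict__ for r in rows])
    for col, adj_col in (("kruskal_p", "kruskal_p_adj"), ("ks_p", "ks_p_adj")):
        mask = df[col].notna() & df["tested"]
        if mask.any():
            df.loc[mask, adj_col] = adjust_pvalues(df.loc[mask, col].tolist())
    return df


def check_adherence(record, rules: dict) -> dict:
    """Check one metadata record against user-supplied min/max rules.

    ``rules`` maps field name -> {"min": x} and/or {"max": y}. Missing
    fields yield "indeterminate" and are excluded from the overall verdict;
    overall passes iff every determinate rule passes.
    """
    rec = record.__dict__ if hasattr(record, "__dict__") else dict(record)
    results = {}
    for fieldname, bounds in rules.items():
        if fieldname not in rec:
            raise KeyError(f"adherence rule references unknown field {fieldname!r}")
        v = rec[fieldname]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            results[fieldname] = "indeterminate"
            continue
        if fieldname == "b_values":
            v = max(v) if len(v) else None
            if v is None:
                results[fieldname] = "indeterminate"
                continue
        ok = True
        if "min" in bounds and v < bounds["min"]:
            ok = False
        if "max" in bounds and v > bounds["max"]:
            ok = False
        results[fieldname] = "pass" if ok else "fail"
    determinate = [r for r in results.values() if r != "indeterminate"]
    results["overall"] = "pass" if all(r == "pass" for r in determinate) else "fail"
    return results
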