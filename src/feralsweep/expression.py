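"""Relative qPCR expression by the 2^-ddCt method.

Technical replicates are averaged first; dCt = Ct_target - Ct_control per
sample; ddCt subtracts the calibrator dCt (a single sample's, or the mean dCt
of a calibrator group); relative expression is 2^-ddCt, so the calibrator
reports exactly 1.0.  Group differences use Welch's t-test on the 2^-ddCt
scale and expression-phenotype trends use Pearson correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def replicate_mean(replicates) -> tuple[float, int]:
    """Mean of available Ct replicates and how many were used."""
    vals = np.asarray([r for r in replicates if r is not None], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("all replicates missing")
    return float(vals.mean()), int(vals.size)


def _sample_ct(ct: pd.DataFrame, gene: str) -> pd.Series:
    """Replicate-averaged Ct per sample for one gene."""
    sub = ct[ct["gene"] == gene]
    return sub.groupby("sample_id")["ct"].apply(
        lambda v: replicate_mean(v.tolist())[0]
    )


def ddct(ct: pd.DataFrame, target_gene: str, control_gene: str,
         calibrator: str | None = None,
         calibrator_group: str | None = None) -> pd.DataFrame:
    """Per-sample dCt, ddCt and 2^-ddCt.

    ``ct`` columns: sample_id, group, gene, ct (one row per technical
    replicate).  Exactly one of ``calibrator`` (a sample id) or
    ``calibrator_group`` (ddCt referenced to that group's mean dCt) must be
    given.  Samples missing the control gene are flagged and skipped.
    """
    if (calibrator is None) == (calibrator_group is None):
        raise ValueError("give exactly one of calibrator / calibrator_group")
    target = _sample_ct(ct, target_gene)
    control = _sample_ct(ct, control_gene)
    groups = ct.drop_duplicates("sample_id").set_index("sample_id")["group"]

    skipped = [s for s in target.index if s not in control.index]
    samples = [s for s in target.index if s in control.index]
    dct = target[samples] - control[samples]

    if calibrator is not None:
        if calibrator not in dct.index:
            raise ValueError(f"calibrator sample {calibrator!r} has no dCt")
        ref = float(dct[calibrator])
    else:
        members = [s for s in samples if groups.get(s) == calibrator_group]
        if not members:
            raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
        ref = float(dct[members].mean())

    out = pd.DataFrame({
        "sample_id": samples,
        "group": [groups.get(s) for s in samples],
        "gene": target_gene,
        "delta_ct": dct.values,
        "delta_delta_ct": dct.values - ref,
    })
    out["rel_expr"] = 2.0 ** (-out["delta_delta_ct"])
    if skipped:
        skip_rows = pd.DataFrame({
            "sample_id": skipped,
            "group": [groups.get(s) for s in skipped],
            "gene": target_gene,
            "delta_ct": np.nan, "delta_delta_ct": np.nan, "rel_expr": np.nan,
        })
        out = pd.concat([out, skip_rows], ignore_index=True)
    return out


def group_compare(results: pd.DataFrame, group_a: str, group_b: str,
                  column: str = "rel_expr") -> dict:
    """Welch two-sample t-test between two groups' relative expression."""
    a = results.loc[results["group"] == group_a, column].dropna().to_numpy()
    b = results.loc[results["group"] == group_b, column].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1)) \
        if (va + vb) > 0 else float(len(a) + len(b) - 2)
    return {"group_a": group_a, "group_b": group_b,
            "mean_diff": float(a.mean() - b.mean()),
            "t": float(t), "df": float(df), "p_value": float(p)}


def expr_phenotype_correlation(results: pd.DataFrame,
                               phenotype: pd.Series,
                               column: str = "rel_expr") -> dict:
    """Pearson correlation between relative expression and a per-sample
    phenotype (e.g. horn length), plus the least-squares trend line."""
    expr = results.set_index("sample_id")[column]
    common = [s for s in expr.index if s in phenotype.index]
    x = expr[common].to_numpy(dtype=float)
    y = phenotype[common].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {"r": float(r), "p_value": float(p), "n": int(len(x)),
            "slope": float(slope), "intercept": float(intercept)}
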