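"""Candidate-SNP association with horn phenotypes.

Genotypes (unordered allele pairs, e.g. ``TT``/``TC``/``CC``) are coded under
three genetic models relative to the cohort's major allele A:

* additive:  AA -> 2, Aa -> 1, aa -> 0
* recessive: AA -> 1, Aa -> 0, aa -> 0
* dominant:  AA -> 1, Aa -> 1, aa -> 0

Horn size (length in cm, polled = 0) is analysed by OLS; horn shape by
logistic regression on SHE (spiral, horizontally extended) vs TCF (tightly
close to the face), excluding polled/scurred/uncertain animals.  Age and sex
enter as optional covariates.  Fits are delegated to statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

MODELS = ("additive", "recessive", "dominant")
SHAPE_CATEGORIES = ("polled", "scurred", "TCF", "SHE", "uncertain")
MISSING_GT = {"", ".", "..", "NA", "./.", None}


@dataclass
class AssocResult:
    snp: str
    model: str
    outcome: str  # "size" or "shape"
    beta: float
    se: float
    p_value: float
    n_used: int
    covariates: tuple[str, ...] = ()
    error: str | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["covariates"] = ",".join(self.covariates)
        return d


def validate_phenotypes(table: pd.DataFrame) -> None:
    bad = set(table["horn_shape"].dropna()) - set(SHAPE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown horn_shape categories: {sorted(bad)}")
    if (table["horn_length"].dropna() < 0).any():
        raise ValueError("horn_length must be >= 0")


def _split_genotype(gt) -> tuple[str, str] | None:
    if gt is None or (isinstance(gt, float) and np.isnan(gt)) or gt in MISSING_GT:
        return None
    s = str(gt).replace("/", "")
    if len(s) != 2:
        raise ValueError(f"cannot parse genotype {gt!r}")
    return s[0], s[1]


def major_allele(genotypes: pd.Series, reference: str | None = None) -> str:
    """Most frequent allele in the analysed cohort; ties broken by the
    reference allele when given, else lexicographically."""
    counts: dict[str, int] = {}
    for gt in genotypes:
        pair = _split_genotype(gt)
        if pair:
            for a in pair:
                counts[a] = counts.get(a, 0) + 1
    if not counts:
        raise ValueError("no called genotypes")
    top = max(counts.values())
    tied = sorted(a for a, c in counts.items() if c == top)
    if len(tied) > 1 and reference in tied:
        return reference
    return tied[0]


def encode_genotype(genotype, model: str, major: str) -> float:
    """Numeric genotype code under one genetic model; missing propagates."""
    pair = _split_genotype(genotype)
    if pair is None:
        return float("nan")
    n_major = sum(a == major for a in pair)
    other = {a for a in pair if a != major}
    if len(other) > 1:
        raise ValueError(f"genotype {genotype!r} has >1 non-major allele kind")
    if model == "additive":
        return float(n_major)
    if model == "recessive":
        return 1.0 if n_major == 2 else 0.0
    if model == "dominant":
        return 1.0 if n_major >= 1 else 0.0
    raise ValueError(f"unknown model {model!r}")


def drop_monomorphic(table: pd.DataFrame, snps: list[str]) -> list[str]:
    """Remove SNPs with a single observed allele in the cohort."""
    kept = []
    for snp in snps:
        alleles = set()
        for gt in table[snp]:
            pair = _split_genotype(gt)
            if pair:
                alleles.update(pair)
        if len(alleles) >= 2:
            kept.append(snp)
        else:
            logger.info("SNP %s dropped: no variation observed", snp)
    return kept


def _design(table: pd.DataFrame, snp: str, model: str,
            covariates: tuple[str, ...],
            major: str | None = None) -> tuple[pd.DataFrame, pd.Series]:
    if major is None:
        major = major_allele(table[snp])
    code = table[snp].map(lambda g: encode_genotype(g, model, major))
    x = pd.DataFrame({"code": code})
    for cov in covariates:
        if cov == "sex":
            x["sex"] = table["sex"].map({"M": 1.0, "F": 0.0})
        elif cov == "age":
            x["age"] = pd.to_numeric(table["age"], errors="coerce")
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return x, code


def linear_assoc(table: pd.DataFrame, snp: str, model: str = "additive",
                 covariates: tuple[str, ...] = (),
                 major: str | None = None) -> AssocResult:
    """OLS of horn length on the genotype code (+ covariates); listwise
    deletion of rows with any missing field.  ``major`` overrides the
    cohort-derived major allele."""
    x, _ = _design(table, snp, model, covariates, major)
    y = pd.to_numeric(table["horn_length"], errors="coerce")
    data = x.assign(y=y).dropna()
    n_params = x.shape[1] + 1
    if len(data) < n_params + 2:
        raise ValueError(f"only {len(data)} complete rows for {snp}/{model}")
    X = sm.add_constant(data.drop(columns="y"), has_constant="add")
    for col in X.columns:
        if col != "const" and X[col].nunique() <= 1:
            raise ValueError(f"column {col!r} is constant after listwise deletion")
    fit = sm.OLS(data["y"], X).fit()
    return AssocResult(snp, model, "size", float(fit.params["code"]),
                       float(fit.bse["code"]), float(fit.pvalues["code"]),
                       int(fit.nobs), covariates)


def logistic_assoc(table: pd.DataFrame, snp: str, model: str = "recessive",
                   covariates: tuple[str, ...] = (),
                   major: str | None = None) -> AssocResult:
    """Logistic regression of SHE (1) vs TCF (0) on the genotype code.

    Other shape categories are excluded; complete separation raises."""
    sub = table[table["horn_shape"].isin(["SHE", "TCF"])]
    if sub.empty or sub["horn_shape"].nunique() < 2:
        raise ValueError("need both SHE and TCF animals")
    x, _ = _design(sub, snp, model, covariates, major)
    y = (sub["horn_shape"] == "SHE").astype(float)
    data = x.assign(y=y.values).dropna()
    if data["y"].nunique() < 2:
        raise ValueError("one outcome class left after listwise deletion")
    X = sm.add_constant(data.drop(columns="y"), has_constant="add")
    try:
        fit = sm.Logit(data["y"], X).fit(disp=0, maxiter=50, tol=1e-8)
    except Exception as e:  # PerfectSeparationError and friends
        raise ValueError(f"logistic fit failed for {snp}/{model}: {e}") from e
    if not np.isfinite(fit.bse["code"]) or abs(fit.params["code"]) > 30:
        raise ValueError(f"complete separation for {snp}/{model}: no ML optimum")
    return AssocResult(snp, model, "shape", float(fit.params["code"]),
                       float(fit.bse["code"]), float(fit.pvalues["code"]),
                       int(fit.nobs), covariates)


def assoc_scan(table: pd.DataFrame, snps: list[str],
               models: tuple[str, ...] = MODELS,
               outcomes: tuple[str, ...] = ("size", "shape"),
               covariates: tuple[str, ...] = (),
               add_bh_column: bool = False) -> pd.DataFrame:
    """Full SNP x model x outcome grid; failed fits become rows with an
    ``error`` message instead of estimates.  Dominant-model fits are skipped
    with a reason when the aa (no-major) class is absent.  Row order is
    (snp, model, outcome)."""
    validate_phenotypes(table)
    rows = []
    for snp in snps:
        major = major_allele(table[snp])
        codes_add = table[snp].map(lambda g: encode_genotype(g, "additive", major))
        for model in models:
            if model == "dominant" and not (codes_add == 0).any():
                rows.append(AssocResult(snp, model, "all", np.nan, np.nan,
                                        np.nan, 0, covariates,
                                        error="aa homozygote class absent"))
                continue
            for outcome in outcomes:
                fn = linear_assoc if outcome == "size" else logistic_assoc
                try:
                    rows.append(fn(table, snp, model, covariates))
                except ValueError as e:
                    rows.append(AssocResult(snp, model, outcome, np.nan, np.nan,
                                            np.nan, 0, covariates, error=str(e)))
    df = pd.DataFrame([r.to_dict() for r in rows])
    if add_bh_column and len(df):
        # Benjamini-Hochberg across successful fits; an extra convenience
        # column, not part of the primary report
        ok = df["p_value"].notna()
        from statsmodels.stats.multitest import multipletests
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"],
                                               method="fdr_bh")[1]
        df["p_bh"] = adj
    return df
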