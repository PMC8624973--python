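"""Single-study association of log-transformed traits on genotype dosages.

The model is the additive one: per variant, ordinary least squares of the
(log-)trait on the expected dosage plus covariates, with two-sided p-values
from the t distribution on n - k - 1 degrees of freedom. Sex is never a
covariate in sex-stratified runs. A pre-meta variant QC applies the standard
single-study filters (MAF, imputation info, MAC, allele-frequency deviation
from a reference, allele/position mismatch) with a fixed reason precedence so
exclusion ledgers are reproducible.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, ConfigError
from .io import SUMSTATS_COLUMNS, Stratum

VALID_COVARIATES = ("age", "log_bmi", "sex")

# QC reason codes, in precedence order (first failing rule wins)
QC_LOW_MAF = "LOW_MAF"
QC_LOW_INFO = "LOW_INFO"
QC_LOW_MAC = "LOW_MAC"
QC_AF_DEVIATION = "AF_DEVIATION"
QC_MISMATCH = "MISMATCH"


@dataclass
class TraitSpec:
    """An analyte and how it enters the regression."""

    name: str
    transform: str = "log"  # {"log", "none"}
    covariates: tuple[str, ...] = ("age", "log_bmi", "sex")

    def __post_init__(self) -> None:
        if self.transform not in ("log", "none"):
            raise ConfigError(f"unknown transform {self.transform!r}")
        bad = [c for c in self.covariates if c not in VALID_COVARIATES]
        if bad:
            raise ConfigError(f"unknown covariates {bad}; allowed: {VALID_COVARIATES}")


def prepare_trait(values: Sequence[float] | pd.Series,
                  spec: TraitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Transform raw analyte values; return (trait, inclusion mask).

    Under ``log`` the natural log is taken; non-positive or missing values are
    masked out with a warning rather than raising, mirroring per-sample
    exclusions at the measurement-QC stage.
    """
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    if spec.transform == "log":
        bad = mask & (x <= 0)
        if bad.any():
            warnings.warn(f"{spec.name}: {int(bad.sum())} non-positive values "
                          "excluded before log transform", stacklevel=2)
        mask &= x > 0
        out = np.full_like(x, np.nan)
        out[mask] = np.log(x[mask])
        return out, mask
    return x.copy(), mask


def _stratum_mask(cohort: pd.DataFrame, stratum: Stratum) -> np.ndarray:
    stratum = Stratum.coerce(stratum)
    if stratum is Stratum.COMBINED:
        return np.ones(len(cohort), dtype=bool)
    return (cohort["SEX"] == stratum.value).to_numpy()


def _design_covariates(cohort: pd.DataFrame, covariates: Iterable[str],
                       stratum: Stratum) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the covariate block; sex is dropped in sex-stratified runs."""
    cols = []
    stratum = Stratum.coerce(stratum)
    mask = np.ones(len(cohort), dtype=bool)
    for c in covariates:
        if c == "age":
            v = cohort["AGE"].to_numpy(dtype=float)
        elif c == "log_bmi":
            bmi = cohort["BMI"].to_numpy(dtype=float)
            v = np.where(bmi > 0, np.log(np.where(bmi > 0, bmi, 1.0)), np.nan)
        elif c == "sex":
            if stratum is not Stratum.COMBINED:
                continue  # invariant: never a covariate when stratified
            v = (cohort["SEX"] == "male").to_numpy(dtype=float)
        cols.append(v)
        mask &= np.isfinite(v)
    block = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    return block, mask


def run_association(cohort: pd.DataFrame, trait: TraitSpec,
                    variants: Sequence[str], stratum: Stratum | str = Stratum.COMBINED,
                    variant_info: pd.DataFrame | None = None,
                    min_cases: int = 30) -> pd.DataFrame:
    """Per-variant OLS of the transformed trait on dosage + covariates.

    Parameters
    ----------
    cohort : individual-level table with ID, SEX, AGE, BMI, trait and dosage columns
    trait : TraitSpec naming the analyte column
    variants : dosage column names to test
    stratum : combined / male / female
    variant_info : optional frame indexed by variant id with CHR, BP, EA, OA
        metadata; synthetic defaults are used when absent.

    Returns a canonical summary-statistics frame. Monomorphic variants are
    skipped with a warning. Complete-case analysis is applied per variant.
    """
    stratum = Stratum.coerce(stratum)
    sub = cohort.loc[_stratum_mask(cohort, stratum)].reset_index(drop=True)
    y_all, y_mask = prepare_trait(sub[trait.name], trait)
    cov_block, cov_mask = _design_covariates(sub, trait.covariates, stratum)
    base_mask = y_mask & cov_mask

    rows = []
    for j, vid in enumerate(variants):
        g = sub[vid].to_numpy(dtype=float)
        m = base_mask & np.isfinite(g)
        n = int(m.sum())
        if n < min_cases:
            raise ConfigError(f"{vid}: only {n} complete cases (< {min_cases})")
        gm, ym = g[m], y_all[m]
        if np.ptp(gm) == 0:
            warnings.warn(f"{vid}: monomorphic dosage, skipped", stacklevel=2)
            continue
        X = np.column_stack([np.ones(n), gm, cov_block[m]])
        beta_hat, se_hat, p = _ols_slope(X, ym, slope_index=1)
        dose_sum = float(gm.sum())
        mac = int(round(min(dose_sum, 2 * n - dose_sum)))
        eaf = dose_sum / (2 * n)
        if variant_info is not None and vid in variant_info.index:
            vi = variant_info.loc[vid]
            chrom, bp, ea, oa = str(vi["CHR"]), int(vi["BP"]), str(vi["EA"]), str(vi["OA"])
        else:
            chrom, bp, ea, oa = "1", j + 1, "A", "G"
        rows.append((vid, chrom, bp, ea, oa, eaf, 1.0, beta_hat, se_hat, p, n, mac))
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)


def _ols_slope(X: np.ndarray, y: np.ndarray, slope_index: int = 1
               ) -> tuple[float, float, float]:
    """OLS fit returning (coefficient, SE, two-sided t-test p) for one column."""
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    df = n - k
    if df <= 0:
        raise ConfigError("not enough residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * XtX_inv[slope_index, slope_index]))
    b = float(coef[slope_index])
    if se == 0:
        return b, se, 0.0 if b != 0 else 1.0
    t = b / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return b, se, float(min(p, 1.0)) if p > 0 else float(np.nextafter(0, 1))


def variant_qc(records: pd.DataFrame, reference: pd.DataFrame,
               config: AnalysisConfig | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pre-meta variant filters against a reference allele/position/frequency table.

    Exclusion rules, in precedence order (one reason code per excluded variant):

    1. ``LOW_MAF``       minor allele frequency < ``maf_min`` (default 1%)
    2. ``LOW_INFO``      imputation info < ``info_single_min`` (default 0.5)
    3. ``LOW_MAC``       minor allele count <= ``mac_min_exclusive`` (default 6)
    4. ``AF_DEVIATION``  |EAF - reference AF| > ``af_dev_max`` (default 0.2, strict)
    5. ``MISMATCH``      alleles or position disagree with the reference, or
       the variant is absent from it

    Reference columns: SNP, BP, EA, OA, AF (frequency of the reference's EA).
    Returns (kept frame, ledger frame with SNP and REASON).
    """
    cfg = config or AnalysisConfig()
    ref = reference.set_index("SNP")
    keep_rows, ledger = [], []
    for t in records.itertuples(index=False):
        maf = min(t.EAF, 1.0 - t.EAF)
        reason = None
        if maf < cfg.maf_min:
            reason = QC_LOW_MAF
        elif t.INFO < cfg.info_single_min:
            reason = QC_LOW_INFO
        elif t.MAC <= cfg.mac_min_exclusive:
            reason = QC_LOW_MAC
        else:
            if t.SNP in ref.index:
                r = ref.loc[t.SNP]
                same = {t.EA, t.OA} == {str(r["EA"]), str(r["OA"])} and int(r["BP"]) == t.BP
                if same:
                    ref_af = float(r["AF"]) if t.EA == str(r["EA"]) else 1.0 - float(r["AF"])
                    if abs(t.EAF - ref_af) > cfg.af_dev_max:
                        reason = QC_AF_DEVIATION
                else:
                    reason = QC_MISMATCH
            else:
                reason = QC_MISMATCH
        if reason is None:
            keep_rows.append(t)
        else:
            ledger.append((t.SNP, reason))
    kept = pd.DataFrame(keep_rows, columns=records.columns)
    ledger_df = pd.DataFrame(ledger, columns=["SNP", "REASON"])
    return kept, ledger_df
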