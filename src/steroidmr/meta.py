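"""Fixed-effect inverse-variance meta-analysis with heterogeneity QC.

Per variant, study effects are pooled with weights :math:`w_i = 1/SE_i^2`:

.. math::

    \\hat\\beta = \\frac{\\sum w_i \\beta_i}{\\sum w_i}, \\qquad
    SE(\\hat\\beta) = \\frac{1}{\\sqrt{\\sum w_i}}, \\qquad
    Q = \\sum w_i (\\beta_i - \\hat\\beta)^2, \\qquad
    I^2 = \\max\\!\\left(0, \\frac{Q - (k-1)}{Q}\\right).

Post-meta filters drop variants with :math:`I^2 \\ge 0.9`, minimum
imputation info across studies below 0.8, or sample-size-weighted MAF below
1%. Genomic inflation λ is the median association χ² over the null median
of the one-degree-of-freedom χ² distribution.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, ConfigError
from .io import harmonize_frames

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.45493642...

META_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P",
                "Q", "I2", "N_STUDIES", "MIN_INFO", "W_MAF", "N"]

# post-meta ledger reason codes
META_HIGH_HET = "HIGH_HET"
META_LOW_INFO = "LOW_INFO"
META_LOW_MAF = "LOW_MAF"

TIER_GW = "genome-wide"
TIER_SUGGESTIVE = "suggestive"
TIER_NONE = "none"


@dataclass
class MetaResult:
    """Pooled effect for one variant across studies."""

    beta: float
    se: float
    p: float
    q_stat: float
    i2: float
    n_studies: int

    def __post_init__(self) -> None:
        if not 0 <= self.i2 < 1:
            raise ValueError(f"I2 must lie in [0, 1), got {self.i2}")


def fixed_effect_meta(betas: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study estimates."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ConfigError("fixed_effect_meta requires at least one study")
    if np.any(s <= 0):
        raise ConfigError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if b.size == 1:
        q = 0.0  # a single study carries no heterogeneity information
    else:
        q = float(np.sum(w * (b - beta) ** 2))
    i2 = 0.0 if q == 0 else max(0.0, (q - (b.size - 1)) / q)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(beta=beta, se=se, p=max(p, np.nextafter(0, 1)),
                      q_stat=q, i2=i2, n_studies=int(b.size))


def meta_analyze(studies: Sequence[pd.DataFrame],
                 ambiguous_eaf_window: tuple[float, float] = (0.4, 0.6)) -> pd.DataFrame:
    """Meta-analyze canonical per-study frames (intersection of variants).

    Study frames are harmonized to the first study's effect alleles; variants
    flagged ambiguous or mismatching during harmonization are dropped, as are
    variants absent from any study.
    """
    if len(studies) == 0:
        raise ConfigError("meta_analyze requires at least one study")
    aligned = [studies[0].reset_index(drop=True)]
    for other in studies[1:]:
        a2, b2 = harmonize_frames(aligned[0], other, ambiguous_eaf_window)
        keep = set(a2["SNP"])
        aligned = [df[df["SNP"].isin(keep)].reset_index(drop=True) for df in aligned]
        aligned.append(b2[b2["SNP"].isin(keep)].reset_index(drop=True))
    aligned = [df.set_index("SNP").loc[aligned[0]["SNP"]] for df in aligned]

    rows = []
    snps = aligned[0].index
    for snp in snps:
        b = [df.loc[snp, "BETA"] for df in aligned]
        s = [df.loc[snp, "SE"] for df in aligned]
        res = fixed_effect_meta(b, s)
        ns = np.array([df.loc[snp, "N"] for df in aligned], dtype=float)
        mafs = np.array([min(df.loc[snp, "EAF"], 1 - df.loc[snp, "EAF"]) for df in aligned])
        eafs = np.array([df.loc[snp, "EAF"] for df in aligned])
        w_maf = float(np.sum(ns * mafs) / np.sum(ns))
        w_eaf = float(np.sum(ns * eafs) / np.sum(ns))
        min_info = float(min(df.loc[snp, "INFO"] for df in aligned))
        first = aligned[0].loc[snp]
        rows.append((snp, first["CHR"], int(first["BP"]), first["EA"], first["OA"],
                     w_eaf, res.beta, res.se, res.p, res.q_stat, res.i2,
                     res.n_studies, min_info, w_maf, int(np.sum(ns))))
    return pd.DataFrame(rows, columns=META_COLUMNS)


def post_meta_filter(results: pd.DataFrame, config: AnalysisConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Post-meta exclusions with a reproducible reason precedence.

    1. ``HIGH_HET``  I² >= 0.9 (inclusive bound: exactly 0.9 is excluded)
    2. ``LOW_INFO``  minimum per-study info < 0.8 (exactly 0.8 is kept)
    3. ``LOW_MAF``   sample-size-weighted MAF < 1%

    Returns (kept frame, ledger frame with SNP and REASON).
    """
    cfg = config or AnalysisConfig()
    reasons = np.full(len(results), None, dtype=object)
    i2 = results["I2"].to_numpy(dtype=float)
    info = results["MIN_INFO"].to_numpy(dtype=float)
    wmaf = results["W_MAF"].to_numpy(dtype=float)
    reasons[wmaf < cfg.weighted_maf_min] = META_LOW_MAF
    reasons[info < cfg.info_meta_min] = META_LOW_INFO
    reasons[i2 >= cfg.i2_max_exclusive] = META_HIGH_HET
    keep = pd.isna(reasons)
    ledger = pd.DataFrame({"SNP": results.loc[~keep, "SNP"].to_numpy(),
                           "REASON": reasons[~keep]})
    return results.loc[keep].reset_index(drop=True), ledger


def genomic_inflation(p_values: Sequence[float]) -> float:
    """λ = median observed χ²₁ / median null χ²₁ (≈ 0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ConfigError("genomic_inflation requires at least one p-value")
    if p.size < 100:
        warnings.warn(f"genomic inflation computed from only {p.size} p-values; "
                      "the median is unstable", stacklevel=2)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def declare_significance(results: pd.DataFrame, config: AnalysisConfig | None = None
                         ) -> pd.DataFrame:
    """Attach a TIER column: genome-wide (p < 5e-8), suggestive (p < 5e-6), none.

    Both thresholds are strict inequalities: boundary p-values do not qualify.
    """
    cfg = config or AnalysisConfig()
    p = results["P"].to_numpy(dtype=float)
    tier = np.where(p < cfg.alpha_gw, TIER_GW,
                    np.where(p < cfg.alpha_suggestive, TIER_SUGGESTIVE, TIER_NONE))
    out = results.copy()
    out["TIER"] = tier
    return out
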