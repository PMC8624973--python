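"""HLA subtype dosage QC, association models, dosage correlation, asymmetric LD.

HLA subtype dosages are expected allele copy numbers in [0, 2] estimated from
genotype data, each with a per-sample combined probability score (product of
the two per-haplotype scores). QC keeps samples with combined probability
>= 0.7 per subtype and drops subtypes rarer than 1% in a study. Associations
enter the dosage as a continuous 0–2 covariate (linear models for hormones
and anthropometry, logistic for CAD), and per-study estimates are pooled by
the fixed-effect meta model.

Asymmetric LD (aLD) extends r² to multi-allelic loci: the association of
locus A conditional on locus B,

.. math::

    ALD_{A|B} = \\sqrt{\\frac{\\sum_{a,b} f_{ab}^2 / f_b - \\sum_a f_a^2}
                            {1 - \\sum_a f_a^2}},

need not equal :math:`ALD_{B|A}`; for a pair of bi-allelic loci both reduce
to |r|.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .config import AnalysisConfig, ConfigError
from .io import Stratum
from .meta import MetaResult, fixed_effect_meta

HLA_RARE = "RARE_SUBTYPE"
HLA_LOW_PROB = "LOW_PROBABILITY"


@dataclass
class HLADosageMatrix:
    """Subjects x subtypes dosage matrix with per-sample probability scores."""

    dosage: pd.DataFrame           # index: sample ID, columns: subtype labels
    prob: pd.DataFrame             # same shape; combined probability in [0, 1]
    study_id: str = "study"

    def __post_init__(self) -> None:
        if not self.dosage.columns.equals(self.prob.columns):
            self.prob = self.prob.reindex(columns=self.dosage.columns, fill_value=1.0)
        d = self.dosage.to_numpy(dtype=float)
        if np.nanmin(d, initial=0.0) < 0 or np.nanmax(d, initial=0.0) > 2:
            raise ConfigError("dosages must lie in [0, 2]")

    def subtype_frequency(self) -> pd.Series:
        """Allele frequency per subtype: mean dosage / 2 over non-missing samples."""
        return self.dosage.mean(axis=0) / 2.0

    @property
    def n_subtypes(self) -> int:
        return self.dosage.shape[1]


def hla_qc(matrices: Mapping[str, HLADosageMatrix] | HLADosageMatrix,
           config: AnalysisConfig | None = None,
           prob_min: float = 0.7, rare_freq: float = 0.01,
           rare_rule: str = "any") -> tuple[dict[str, HLADosageMatrix], pd.DataFrame]:
    """Filter dosage matrices on probability scores and subtype frequency.

    Samples with combined probability below ``prob_min`` (exactly 0.7 is
    kept) have their dosage masked per subtype. Subtypes with post-masking
    frequency below ``rare_freq`` in ANY study (``rare_rule="any"``,
    conservative so every retained subtype supports meta-analysis) or in ALL
    studies (``rare_rule="all"``) are dropped from every study.

    Returns (filtered matrices, ledger). The ledger records dropped subtypes
    (one row per subtype, reason ``RARE_SUBTYPE``) and per-study counts of
    masked sample entries (reason ``LOW_PROBABILITY``).
    """
    if isinstance(matrices, HLADosageMatrix):
        matrices = {matrices.study_id: matrices}
    if rare_rule not in ("any", "all"):
        raise ConfigError(f"rare_rule must be 'any' or 'all', got {rare_rule!r}")

    masked: dict[str, HLADosageMatrix] = {}
    ledger_rows = []
    for sid, m in matrices.items():
        low = m.prob < prob_min
        n_masked = int(low.to_numpy().sum())
        if n_masked:
            ledger_rows.append((sid, "", HLA_LOW_PROB, n_masked))
        masked[sid] = HLADosageMatrix(m.dosage.mask(low), m.prob, study_id=sid)

    freqs = pd.DataFrame({sid: m.subtype_frequency() for sid, m in masked.items()})
    rare_any = (freqs < rare_freq).any(axis=1)
    rare_all = (freqs < rare_freq).all(axis=1)
    rare = rare_any if rare_rule == "any" else rare_all
    for subtype in freqs.index[rare]:
        ledger_rows.append(("*", subtype, HLA_RARE, 1))

    keep = freqs.index[~rare]
    out = {sid: HLADosageMatrix(m.dosage[keep], m.prob[keep], study_id=sid)
           for sid, m in masked.items()}
    ledger = pd.DataFrame(ledger_rows, columns=["STUDY", "SUBTYPE", "REASON", "COUNT"])
    return out, ledger


@dataclass
class HLAAssocResult:
    beta: float
    se: float
    p: float
    n: int
    model: str
    flagged: str | None = None  # e.g. "separation"


def hla_association(dosage: Sequence[float] | pd.Series,
                    trait: Sequence[float] | pd.Series,
                    covariates: pd.DataFrame | None = None,
                    model: str = "linear") -> HLAAssocResult:
    """Association of one subtype dosage with a trait.

    ``model="linear"`` fits OLS of the trait on dosage + covariates;
    ``model="logistic"`` fits a logit model for a binary outcome (IRLS;
    complete separation is flagged and the estimate withheld as NaN).
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(trait, dtype=float)
    cov = (covariates.to_numpy(dtype=float) if covariates is not None
           else np.empty((d.size, 0)))
    mask = np.isfinite(d) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    d, y, cov = d[mask], y[mask], cov[mask]
    n = int(mask.sum())
    if np.ptp(d) == 0:
        raise ConfigError("dosage has zero variance")
    X = np.column_stack([np.ones(n), d, cov])
    if model == "linear":
        from .assoc import _ols_slope

        beta, se, p = _ols_slope(X, y, slope_index=1)
        return HLAAssocResult(beta, se, p, n, model)
    if model != "logistic":
        raise ConfigError(f"unknown model {model!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=50, tol=1e-8)
    except (PerfectSeparationError, RuntimeWarning, np.linalg.LinAlgError):
        return HLAAssocResult(np.nan, np.nan, np.nan, n, model, flagged="separation")
    if not fit.mle_retvals.get("converged", True) or not np.isfinite(fit.bse[1]):
        return HLAAssocResult(np.nan, np.nan, np.nan, n, model, flagged="separation")
    return HLAAssocResult(float(fit.params[1]), float(fit.bse[1]),
                          float(fit.pvalues[1]), n, model)


def hla_meta_association(per_study: Sequence[HLAAssocResult]) -> MetaResult:
    """Pool per-study subtype associations with the fixed-effect meta model."""
    usable = [r for r in per_study if r.flagged is None]
    if not usable:
        raise ConfigError("no usable per-study estimates")
    return fixed_effect_meta([r.beta for r in usable], [r.se for r in usable])


def dosage_correlation(d1: Sequence[float], d2: Sequence[float]) -> float:
    """Squared Pearson correlation between two subtype dosage vectors."""
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("dosage vectors must cover the same subjects")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("dosage_correlation undefined for a constant vector", stacklevel=2)
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class HaplotypeFreqTable:
    """Joint haplotype frequencies across two multi-allelic loci."""

    alleles_a: tuple[str, ...]
    alleles_b: tuple[str, ...]
    f: np.ndarray  # shape (len(alleles_a), len(alleles_b)), sums to 1

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (len(self.alleles_a), len(self.alleles_b)):
            raise ConfigError("frequency table shape does not match allele labels")
        if np.any(self.f < 0):
            raise ConfigError("haplotype frequencies must be non-negative")
        if not np.isclose(self.f.sum(), 1.0, atol=1e-8):
            raise ConfigError(f"haplotype frequencies must sum to 1, got {self.f.sum()}")

    @property
    def f_a(self) -> np.ndarray:
        return self.f.sum(axis=1)

    @property
    def f_b(self) -> np.ndarray:
        return self.f.sum(axis=0)


@dataclass
class ALDResult:
    locus_a: str
    locus_b: str
    ald_a_given_b: float
    ald_b_given_a: float


def _ald_conditional(f: np.ndarray, f_target: np.ndarray, f_cond: np.ndarray) -> float:
    """ALD of the target locus conditional on the other (f rows = target alleles)."""
    homozygosity = float(np.sum(f_target**2))
    if homozygosity >= 1.0 - 1e-15:
        raise ConfigError("asymmetric LD undefined for a monomorphic locus")
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(f_cond > 0, (f**2).sum(axis=0) / np.where(f_cond > 0, f_cond, 1.0), 0.0)
    num = float(cond.sum()) - homozygosity
    val = num / (1.0 - homozygosity)
    return float(np.sqrt(min(max(val, 0.0), 1.0)))


def asymmetric_ld(freqs: HaplotypeFreqTable,
                  locus_a: str = "A", locus_b: str = "B") -> ALDResult:
    """Asymmetric LD in both directions from a joint haplotype frequency table."""
    ald_a_b = _ald_conditional(freqs.f, freqs.f_a, freqs.f_b)
    ald_b_a = _ald_conditional(freqs.f.T, freqs.f_b, freqs.f_a)
    return ALDResult(locus_a, locus_b, ald_a_b, ald_b_a)
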