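"""Sex-interaction testing and two-level hierarchical FDR.

Male and female strata are disjoint samples, so the effect-size difference
test uses

.. math::

    z = \\frac{\\beta_m - \\beta_f}{\\sqrt{SE_m^2 + SE_f^2}}

with a two-sided normal reference (the t reference would differ only in the
far decimals at GWAS sample sizes).

Hierarchical FDR controls discovery over grouped hypotheses (variants within
a phenotype, phenotypes over the experiment): families are first screened by
Benjamini–Hochberg on a per-family combined p-value, and hypotheses inside
the selected families are then tested by within-family BH against the
proportionally tightened threshold ``alpha * k / n`` where ``k`` of ``n``
families were selected.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ConfigError

CLASS_MALE = "male-specific"
CLASS_FEMALE = "female-specific"
CLASS_RELATED = "sex-related"
CLASS_UNSPECIFIC = "unspecific"
CLASS_NONE = "none"


def interaction_test(beta_m: float, se_m: float,
                     beta_f: float, se_f: float) -> tuple[float, float]:
    """Male-vs-female effect difference; returns (z, two-sided p)."""
    if not (se_m > 0 and se_f > 0):
        raise ConfigError("interaction_test requires positive SEs in both strata")
    se_diff = math.sqrt(se_m**2 + se_f**2)
    z = (beta_m - beta_f) / se_diff
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _simes(p: np.ndarray) -> float:
    """Simes combined p of one family: min_i (m * p_(i) / i)."""
    p_sorted = np.sort(p)
    m = p_sorted.size
    return float(np.min(m * p_sorted / np.arange(1, m + 1)))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def hierarchical_fdr(p_values: Sequence[float], families: Sequence[str],
                     alpha: float = 0.05, combiner: str = "simes") -> pd.DataFrame:
    """Two-level FDR over hypotheses grouped into families.

    Level 2 applies BH across families to each family's combined p-value
    (``combiner``: "simes", the default, or "bonferroni"); the ``k``
    families with adjusted p <= alpha are selected. Level 1 applies BH
    within every family and calls a hypothesis significant when it belongs
    to a selected family and its within-family q-value is at most
    ``alpha * k / n`` (n = number of families). With a single family the
    procedure reduces to plain BH at level alpha.

    Returns a frame with columns P, FAMILY, Q (within-family BH q-value),
    FAMILY_Q (level-2 adjusted family p) and SIGNIFICANT.
    """
    p = np.asarray(p_values, dtype=float)
    fam = np.asarray(families, dtype=object)
    if p.size == 0:
        raise ConfigError("hierarchical_fdr requires at least one hypothesis")
    if p.size != fam.size:
        raise ConfigError("p_values and families must have equal length")
    if np.any((p <= 0) | (p > 1)):
        raise ConfigError("p-values must lie in (0, 1]")
    if combiner not in ("simes", "bonferroni"):
        raise ConfigError(f"unknown combiner {combiner!r}")

    fam_names = list(dict.fromkeys(fam))  # stable order
    n_fam = len(fam_names)
    fam_p = {}
    for name in fam_names:
        pf = p[fam == name]
        fam_p[name] = _simes(pf) if combiner == "simes" else float(min(1.0, pf.min() * pf.size))
    fam_q_arr = _bh_adjust(np.array([fam_p[name] for name in fam_names]))
    fam_q = dict(zip(fam_names, fam_q_arr))
    selected = {name for name in fam_names if fam_q[name] <= alpha}
    k = len(selected)

    q = np.empty_like(p)
    for name in fam_names:
        idx = fam == name
        q[idx] = _bh_adjust(p[idx])
    threshold = alpha * k / n_fam
    significant = np.array([f in selected and qi <= threshold
                            for f, qi in zip(fam, q)])
    return pd.DataFrame({"P": p, "FAMILY": fam, "Q": q,
                         "FAMILY_Q": [fam_q[f] for f in fam],
                         "SIGNIFICANT": significant})


def classify_sex_effect(beta_m: float, p_m: float, beta_f: float, p_f: float,
                        q_ia: float, alpha_gw: float = 5e-8,
                        alpha_nominal: float = 0.05,
                        fdr_alpha: float = 0.05) -> str:
    """Label a locus from its stratum significances and interaction q-value.

    - no significant interaction (q_ia >= fdr_alpha) → ``unspecific``
    - interaction + genome-wide significance in exactly one sex with the
      other sex not even nominally significant → ``male-specific`` /
      ``female-specific``
    - interaction + both sexes at least nominally significant in the same
      direction → ``sex-related``
    - anything else (no stratum supporting the effect, or conflicting
      directions) → ``none``
    """
    if q_ia >= fdr_alpha:
        return CLASS_UNSPECIFIC
    gw_m, gw_f = p_m < alpha_gw, p_f < alpha_gw
    nom_m, nom_f = p_m < alpha_nominal, p_f < alpha_nominal
    if gw_m and not gw_f and not nom_f:
        return CLASS_MALE
    if gw_f and not gw_m and not nom_m:
        return CLASS_FEMALE
    if nom_m and nom_f and np.sign(beta_m) == np.sign(beta_f):
        return CLASS_RELATED
    return CLASS_NONE


@dataclass
class InteractionResult:
    """Effect-size difference between sexes for one variant/subtype and phenotype."""

    key: str
    phenotype: str
    beta_m: float
    se_m: float
    beta_f: float
    se_f: float
    z: float
    p_ia: float
    q_ia: float | None = None
    label: str | None = None

    @property
    def diff(self) -> float:
        return self.beta_m - self.beta_f

    @property
    def se_diff(self) -> float:
        return math.sqrt(self.se_m**2 + self.se_f**2)


def interaction_scan(leads: pd.DataFrame, alpha: float = 0.05,
                     combiner: str = "simes") -> pd.DataFrame:
    """Test a table of lead variants and apply hierarchical FDR per phenotype.

    ``leads`` columns: SNP, PHENOTYPE, BETA_M, SE_M, BETA_F, SE_F and
    optionally P_M, P_F (needed for classification). Families at level one
    are the variants per phenotype; level two runs over phenotypes.
    """
    z_p = [interaction_test(t.BETA_M, t.SE_M, t.BETA_F, t.SE_F)
           for t in leads.itertuples(index=False)]
    out = leads.copy()
    out["Z"] = [zp[0] for zp in z_p]
    out["P_IA"] = [zp[1] for zp in z_p]
    fdr = hierarchical_fdr(out["P_IA"], out["PHENOTYPE"], alpha=alpha, combiner=combiner)
    out["Q_IA"] = fdr["Q"].to_numpy()
    out["IA_SIGNIFICANT"] = fdr["SIGNIFICANT"].to_numpy()
    if {"P_M", "P_F"}.issubset(out.columns):
        out["CLASS"] = [
            classify_sex_effect(t.BETA_M, t.P_M, t.BETA_F, t.P_F,
                                t.Q_IA if t.IA_SIGNIFICANT else 1.0,
                                fdr_alpha=alpha)
            for t in out.itertuples(index=False)
        ]
    return out
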