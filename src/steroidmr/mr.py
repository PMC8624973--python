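"""Two-sample Mendelian randomization: instruments, ratio/IVW estimators, FDR.

With a single instrument the causal effect of exposure X on outcome Y is the
Wald ratio :math:`\\hat\\theta = \\beta_{Y}/\\beta_{X}` with the first-order
delta standard error :math:`SE = SE_{Y}/|\\beta_{X}|` (the uncertainty of the
instrument-exposure association is neglected, appropriate for strong
instruments). Multiple independent instruments are combined by
inverse-variance weighting of the per-instrument ratios, which is exactly the
fixed-effect meta model applied to the ratio set.

External mediator-on-outcome estimates reported as odds ratios are converted
to liability-scale effect sizes by dividing the log-OR by 1.81.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, ConfigError
from .interaction import hierarchical_fdr, interaction_test
from .io import HarmonizeStatus, frame_to_records, harmonize_alleles
from .meta import fixed_effect_meta

Z_95 = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass
class Instrument:
    """A selected instrument with stratum-matched exposure and outcome effects."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    p_exposure: float
    locus: str = ""
    gene: str = ""
    gene_dist_kb: float = 0.0
    eaf: float | None = None


@dataclass
class CausalEstimate:
    """An MR causal-effect estimate for one exposure/outcome/stratum cell."""

    exposure: str
    outcome: str
    stratum: str
    method: str            # "ratio" (1 instrument) or "ivw" (>1)
    estimate: float
    se: float
    p: float
    n_instruments: int
    q: float | None = None

    def __post_init__(self) -> None:
        if self.n_instruments >= 1 and not self.se > 0:
            raise ConfigError("causal estimate requires a positive SE")
        expected = "ratio" if self.n_instruments == 1 else "ivw"
        if self.method != expected:
            raise ConfigError(
                f"method {self.method!r} inconsistent with {self.n_instruments} instruments")

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = float(stats.norm.ppf(0.5 + level / 2))
        return self.estimate - z * self.se, self.estimate + z * self.se


def _as_canonical(df: pd.DataFrame) -> pd.DataFrame:
    """Accept either a single-study or a meta-level frame as MR input."""
    out = df.copy()
    if "INFO" not in out.columns:
        out["INFO"] = out["MIN_INFO"] if "MIN_INFO" in out.columns else 1.0
    if "MAC" not in out.columns:
        maf = np.minimum(out["EAF"], 1 - out["EAF"])
        out["MAC"] = (2 * out["N"] * maf).round().astype(int)
    return out


def explained_variance(eaf: float, beta: float) -> float:
    """Trait variance explained by a SNP on a standardized trait: 2 p (1-p) beta^2."""
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def select_instruments(exposure: pd.DataFrame, outcome: pd.DataFrame,
                       loci: Mapping[str, str] | pd.Series,
                       ld_r2: pd.DataFrame | None = None,
                       config: AnalysisConfig | None = None,
                       plausible_genes: Mapping[str, tuple[str, float]] | None = None,
                       p_cutoff: float | None = None,
                       mode: str = "suggestive") -> list[Instrument]:
    """Select instruments for one exposure-outcome pair in one stratum.

    Parameters
    ----------
    exposure, outcome : canonical summary-statistics frames, stratum-matched
        for the exposure (strata use only SNPs significant in that stratum);
        the outcome frame is harmonized to the exposure's effect alleles.
    loci : mapping variant id -> locus label (a gene region or a cytoband for
        the reverse-direction analyses).
    ld_r2 : optional long frame SNP_A, SNP_B, R2 of pairwise LD; instruments
        are pruned greedily by exposure p, dropping any SNP with r2 >=
        ``ld_prune_r2`` to an already kept SNP.
    plausible_genes : optional mapping variant id -> (gene, distance kb);
        with ``mode="plausible-gene"`` only SNPs within ``gene_dist_kb`` of a
        listed gene are eligible.
    p_cutoff : exposure p-value threshold; defaults to the liberal 1e-6.
    mode : "suggestive" (default), "plausible-gene", or "strong" (additionally
        requires explained variance >= ``explained_var_min``).

    Per locus the best-associated SNP with available outcome statistics is
    kept; an empty return means the estimate is not computable.
    """
    cfg = config or AnalysisConfig()
    cutoff = p_cutoff if p_cutoff is not None else cfg.alpha_instrument
    loci = dict(loci) if not isinstance(loci, pd.Series) else loci.to_dict()

    exp_recs = {r.variant_id: r for r in frame_to_records(_as_canonical(exposure))}
    out_recs = {r.variant_id: r for r in frame_to_records(_as_canonical(outcome))}

    candidates = []
    for vid, er in exp_recs.items():
        if not er.p < cutoff:
            continue
        if mode == "plausible-gene":
            if plausible_genes is None or vid not in plausible_genes:
                continue
            gene, dist = plausible_genes[vid]
            if dist > cfg.gene_dist_kb:
                continue
        else:
            gene, dist = (plausible_genes.get(vid, ("", 0.0))
                          if plausible_genes else ("", 0.0))
        if mode == "strong" and explained_variance(er.eaf, er.beta) < cfg.explained_var_min:
            continue
        if vid not in out_recs:
            continue
        orr, status = harmonize_alleles(er, out_recs[vid], cfg.palindromic_eaf_window)
        if status in (HarmonizeStatus.AMBIGUOUS, HarmonizeStatus.MISMATCH):
            continue
        candidates.append(Instrument(
            variant_id=vid, beta_exposure=er.beta, se_exposure=er.se,
            beta_outcome=orr.beta, se_outcome=orr.se, p_exposure=er.p,
            locus=str(loci.get(vid, vid)), gene=gene, gene_dist_kb=float(dist),
            eaf=er.eaf))

    # best p per locus (ties broken by variant id for reproducibility)
    best: dict[str, Instrument] = {}
    for inst in sorted(candidates, key=lambda i: (i.p_exposure, i.variant_id)):
        best.setdefault(inst.locus, inst)
    selected = sorted(best.values(), key=lambda i: (i.p_exposure, i.variant_id))

    if ld_r2 is not None and len(selected) > 1:
        r2 = {}
        for t in ld_r2.itertuples(index=False):
            r2[frozenset((t.SNP_A, t.SNP_B))] = float(t.R2)
        kept: list[Instrument] = []
        for inst in selected:  # greedy by ascending p
            if all(r2.get(frozenset((inst.variant_id, k.variant_id)), 0.0) < cfg.ld_prune_r2
                   for k in kept):
                kept.append(inst)
        selected = kept
    return selected


def ratio_estimate(beta_exp: float, se_exp: float,
                   beta_out: float, se_out: float) -> tuple[float, float]:
    """Wald ratio and its first-order delta SE: (beta_out/beta_exp, se_out/|beta_exp|)."""
    if beta_exp == 0:
        raise ConfigError("ratio estimate undefined for beta_exposure = 0 (weak instrument)")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def ivw_combine(ratios: Sequence[float], ses: Sequence[float],
                exposure: str = "", outcome: str = "",
                stratum: str = "combined") -> CausalEstimate:
    """Fixed-effect inverse-variance pooling of per-instrument ratio estimates."""
    res = fixed_effect_meta(ratios, ses)
    method = "ratio" if res.n_studies == 1 else "ivw"
    return CausalEstimate(exposure=exposure, outcome=outcome, stratum=stratum,
                          method=method, estimate=res.beta, se=res.se, p=res.p,
                          n_instruments=res.n_studies)


def estimate_causal_effect(instruments: Sequence[Instrument],
                           exposure: str = "", outcome: str = "",
                           stratum: str = "combined") -> CausalEstimate | None:
    """Ratio (single instrument) or IVW (several) causal estimate; None if empty."""
    if not instruments:
        return None
    pairs = [ratio_estimate(i.beta_exposure, i.se_exposure, i.beta_outcome, i.se_outcome)
             for i in instruments]
    return ivw_combine([p[0] for p in pairs], [p[1] for p in pairs],
                       exposure=exposure, outcome=outcome, stratum=stratum)


def or_to_beta(or_value: float, ci_low: float, ci_high: float,
               or_scale: float = 1.81) -> tuple[float, float]:
    """Convert an odds ratio with 95% CI to a liability-scale effect and SE.

    beta = ln(OR) / 1.81; SE = (ln(CI_high) - ln(CI_low)) / (2 * 1.96 * 1.81).
    """
    if not (0 < ci_low <= or_value <= ci_high):
        raise ConfigError("require 0 < ci_low <= OR <= ci_high")
    beta = math.log(or_value) / or_scale
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95 * or_scale)
    return beta, se


def causal_interaction_test(est_m: CausalEstimate | None,
                            est_f: CausalEstimate | None) -> float | None:
    """Sex-interaction p for a pair of causal estimates; None when untestable."""
    if est_m is None or est_f is None:
        return None
    _, p = interaction_test(est_m.estimate, est_m.se, est_f.estimate, est_f.se)
    return p


def mr_fdr(estimates: Sequence[CausalEstimate], alpha: float = 0.05,
           combiner: str = "simes") -> pd.DataFrame:
    """Hierarchical FDR over causal estimates grouped by exposure.

    FDR is computed within each exposure (level 1), then across exposures on
    each exposure's best outcome (level 2); level-1 calls use the tightened
    threshold ``alpha * k / n`` with k of n exposures significant. Returns a
    frame aligned with ``estimates`` (EXPOSURE, OUTCOME, STRATUM, P, Q,
    SIGNIFICANT) and writes each estimate's q-value back onto it.
    """
    if not estimates:
        raise ConfigError("mr_fdr requires at least one estimate")
    p = [e.p for e in estimates]
    fams = [e.exposure for e in estimates]
    fdr = hierarchical_fdr(p, fams, alpha=alpha, combiner=combiner)
    out = pd.DataFrame({
        "EXPOSURE": fams,
        "OUTCOME": [e.outcome for e in estimates],
        "STRATUM": [e.stratum for e in estimates],
        "P": p,
        "Q": fdr["Q"].to_numpy(),
        "SIGNIFICANT": fdr["SIGNIFICANT"].to_numpy(),
    })
    for e, q in zip(estimates, out["Q"]):
        e.q = float(q)
    return out
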