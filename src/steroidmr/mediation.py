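"""Mediation decomposition of a total causal effect into direct and indirect parts.

For a hormone whose causal pull on an obesity trait is alpha and whose total
effect on CAD is tau, with the obesity-trait-on-CAD effect beta taken from an
external source:

    indirect = alpha * beta
    SE(indirect) = sqrt(alpha^2 SE(beta)^2 + beta^2 SE(alpha)^2)
    direct = tau - indirect
    SE(direct) = sqrt(SE(tau)^2 + SE(indirect)^2)

The indirect-effect SE is the first-order delta approximation for a product
of independent estimates (an alternative "literal" mode computes the
unsquared sum ``alpha^2 SE(beta) + beta^2 SE(alpha)``, kept only for audit —
it is dimensionally inconsistent and not used by default). All p-values are
two-sided Wald tests. direct + indirect = tau holds to machine precision by
construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .config import ConfigError
from .mr import CausalEstimate, or_to_beta

VERDICT_MEDIATED = "mediated"
VERDICT_BOTH = "direct + indirect"
VERDICT_NEITHER = "neither"


def _wald_p(est: float, se: float) -> float:
    if se == 0:
        return 1.0 if est == 0 else 0.0
    return float(min(2.0 * stats.norm.sf(abs(est) / se), 1.0))


def indirect_effect(alpha: float, se_alpha: float, beta_med: float, se_beta: float,
                    mode: str = "delta") -> tuple[float, float]:
    """Indirect (mediated) effect alpha*beta with its delta-method SE."""
    if se_alpha < 0 or se_beta < 0:
        raise ConfigError("standard errors must be non-negative")
    ind = alpha * beta_med
    if mode == "delta":
        se = math.sqrt(alpha**2 * se_beta**2 + beta_med**2 * se_alpha**2)
    elif mode == "literal":
        se = alpha**2 * se_beta + beta_med**2 * se_alpha
    else:
        raise ConfigError(f"unknown SE mode {mode!r}")
    return ind, se


def direct_effect(tau: float, se_tau: float, indirect: float, se_indirect: float
                  ) -> tuple[float, float, float]:
    """Direct effect tau - indirect, its root-sum-square SE, and Wald p."""
    if se_tau < 0 or se_indirect < 0:
        raise ConfigError("standard errors must be non-negative")
    direct = tau - indirect
    se = math.sqrt(se_tau**2 + se_indirect**2)
    return direct, se, _wald_p(direct, se)


@dataclass
class MediationResult:
    """The (alpha, beta, tau, indirect, direct) quintuple for one eligible pair."""

    exposure: str
    mediator: str
    stratum: str
    alpha: float
    se_alpha: float
    p_alpha: float
    beta_med: float
    se_beta: float
    tau: float
    se_tau: float
    p_tau: float
    indirect: float
    se_indirect: float
    p_indirect: float
    direct: float
    se_direct: float
    p_direct: float
    verdict: str

    def __post_init__(self) -> None:
        if abs((self.direct + self.indirect) - self.tau) > 1e-12 * max(
                1.0, abs(self.tau)):
            raise ConfigError("direct + indirect must equal tau exactly")
        for name in ("se_alpha", "se_tau", "se_indirect", "se_direct"):
            if not getattr(self, name) >= 0:
                raise ConfigError(f"{name} must be non-negative")


def _verdict(p_indirect: float, p_direct: float, alpha: float = 0.05) -> str:
    sig_ind, sig_dir = p_indirect < alpha, p_direct < alpha
    if sig_ind and sig_dir:
        return VERDICT_BOTH
    if sig_ind and not sig_dir:
        return VERDICT_MEDIATED
    return VERDICT_NEITHER


def run_mediation(alpha_estimates: Sequence[CausalEstimate],
                  tau_estimates: Sequence[CausalEstimate],
                  mediator_effects: Mapping[tuple[str, str], tuple[float, float]],
                  eligible: Sequence[tuple[str, str, str]] | None = None,
                  se_mode: str = "delta", sig_alpha: float = 0.05
                  ) -> tuple[list[MediationResult], pd.DataFrame]:
    """Decompose total effects for every eligible (exposure, mediator, stratum).

    Parameters
    ----------
    alpha_estimates : hormone -> mediator causal estimates (outcome = mediator)
    tau_estimates : hormone -> CAD total causal estimates
    mediator_effects : (mediator, stratum) -> (beta, se) on the CAD scale
        (use :func:`steroidmr.mr.or_to_beta` for OR + CI inputs); a
        ``(mediator, "combined")`` entry backstops missing strata.
    eligible : restriction to pairs whose alpha passed the MR FDR; defaults
        to every (exposure, mediator, stratum) with a significant alpha
        (q <= 0.05 when q-values are set, else p < 0.05).
    se_mode : "delta" (default) or "literal" for the indirect-effect SE.

    Returns the result list plus a ledger of skipped eligible pairs.
    """
    alpha_by = {(e.exposure, e.outcome, e.stratum): e for e in alpha_estimates}
    tau_by = {(e.exposure, e.stratum): e for e in tau_estimates}

    if eligible is None:
        eligible = []
        for key, e in alpha_by.items():
            sig = (e.q is not None and e.q <= sig_alpha) or (e.q is None and e.p < sig_alpha)
            if sig:
                eligible.append(key)

    results, skipped = [], []
    for exposure, mediator, stratum in eligible:
        a = alpha_by.get((exposure, mediator, stratum))
        t = tau_by.get((exposure, stratum))
        b = mediator_effects.get((mediator, stratum),
                                 mediator_effects.get((mediator, "combined")))
        if a is None or t is None or b is None:
            missing = "alpha" if a is None else ("tau" if t is None else "mediator effect")
            skipped.append((exposure, mediator, stratum, f"missing {missing}"))
            continue
        beta_med, se_beta = b
        ind, se_ind = indirect_effect(a.estimate, a.se, beta_med, se_beta, mode=se_mode)
        p_ind = _wald_p(ind, se_ind)
        direct, se_dir, p_dir = direct_effect(t.estimate, t.se, ind, se_ind)
        results.append(MediationResult(
            exposure=exposure, mediator=mediator, stratum=stratum,
            alpha=a.estimate, se_alpha=a.se, p_alpha=a.p,
            beta_med=beta_med, se_beta=se_beta,
            tau=t.estimate, se_tau=t.se, p_tau=t.p,
            indirect=ind, se_indirect=se_ind, p_indirect=p_ind,
            direct=direct, se_direct=se_dir, p_direct=p_dir,
            verdict=_verdict(p_ind, p_dir, sig_alpha)))
    ledger = pd.DataFrame(skipped, columns=["EXPOSURE", "MEDIATOR", "SET", "REASON"])
    return results, ledger


def mediation_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Result table with one row per (exposure, mediator, stratum)."""
    rows = [(r.exposure, r.mediator, r.stratum, r.alpha, r.p_alpha,
             r.tau, r.p_tau, r.indirect, r.p_indirect, r.direct, r.p_direct,
             r.verdict) for r in results]
    return pd.DataFrame(rows, columns=["EXPOSURE", "MEDIATOR", "SET", "ALPHA", "P_ALPHA",
                                       "TAU", "P_TAU", "INDIR", "P_INDIR",
                                       "DIR", "P_DIR", "VERDICT"])
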