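"""Synthetic cohorts, summary statistics, and HLA dosages with known ground truth.

The generator emulates the study design the pipeline targets: two independent
cohorts with log-normal hormone traits, additive genetic effects with optional
sex-specific multipliers, covariates age/BMI/sex, an obesity-trait mediator
and a CAD-liability outcome wired into a user-specified causal network

    hormone --alpha--> mediator --beta--> CAD,   hormone --direct--> CAD,

so that the total effect is tau = direct + sum_m alpha_m * beta_m (computed,
never stored). Two summary-statistic modes are provided: ``exact`` simulates
individuals and runs the single-study association engine (slow, exact), and
``fast`` draws effect estimates directly from their asymptotic sampling
distributions (the per-SNP slope is Normal(truth, sigma^2 / (2 p q n))).
All generators are pure functions of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import TraitSpec, run_association
from .config import ConfigError
from .hla import HaplotypeFreqTable, HLADosageMatrix
from .io import SUMSTATS_COLUMNS, Stratum

STRATA = (Stratum.COMBINED, Stratum.MALE, Stratum.FEMALE)


@dataclass
class InstrumentSpec:
    """One causal variant for the exposure."""

    variant_id: str
    eaf: float
    beta_exposure: float          # effect on log-hormone per allele copy (combined scale)
    chrom: str = "1"
    pos: int = 0
    effect_allele: str = "A"
    other_allele: str = "G"
    locus: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.eaf < 1:
            raise ConfigError(f"{self.variant_id}: EAF must lie in (0, 1)")
        if not self.locus:
            self.locus = self.variant_id


@dataclass
class MediatorSpec:
    """A mediator trait: its causal pull from the hormone and its push on CAD."""

    name: str
    alpha: float | Mapping[str, float]   # hormone -> mediator, scalar or per-stratum
    beta: float                          # mediator -> CAD (liability/log-odds scale)
    beta_se: float = 0.0                 # SE of the external mediator->CAD estimate
    noise_sd: float = 1.0

    def alpha_for(self, stratum: Stratum | str) -> float:
        stratum = Stratum.coerce(stratum)
        if isinstance(self.alpha, Mapping):
            return float(self.alpha[stratum.value])
        return float(self.alpha)


@dataclass
class CausalNetworkSpec:
    """Ground-truth network and study conditions for the synthetic experiment."""

    instruments: tuple[InstrumentSpec, ...] = (
        InstrumentSpec("rs_sim_1", 0.30, 0.15, pos=1_000_000, locus="L1"),
        InstrumentSpec("rs_sim_2", 0.25, 0.12, chrom="2", pos=2_000_000, locus="L2"),
        InstrumentSpec("rs_sim_3", 0.40, 0.10, chrom="3", pos=3_000_000, locus="L3"),
    )
    mediators: tuple[MediatorSpec, ...] = (
        MediatorSpec("WHR", alpha=0.06, beta=0.17, beta_se=0.018, noise_sd=1.0),
    )
    direct: float | Mapping[str, float] = -0.118  # hormone -> CAD bypassing mediators
    exposure_name: str = "hormone"
    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"studyA": 4000, "studyB": 4000})
    female_fraction: float = 0.5
    exposure_noise_sd: float = 1.0     # residual SD of log-hormone
    outcome_noise_sd: float = 1.0      # residual SD of the CAD liability
    sex_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.0, "female": 1.0})
    age_slope: float = 0.005           # covariate effect of age on log-hormone
    log_bmi_slope: float = 0.3         # covariate effect of log-BMI on log-hormone

    def __post_init__(self) -> None:
        for name in ("exposure_noise_sd", "outcome_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for m in self.mediators:
            if m.noise_sd <= 0:
                raise ConfigError(f"mediator {m.name}: noise_sd must be positive")
        if not 0 < self.female_fraction < 1:
            raise ConfigError("female_fraction must lie in (0, 1)")
        names = [m.name for m in self.mediators]
        if len(set(names)) != len(names):
            raise ConfigError("mediator names must be unique")

    # -- derived truths ----------------------------------------------------
    def direct_for(self, stratum: Stratum | str) -> float:
        stratum = Stratum.coerce(stratum)
        if isinstance(self.direct, Mapping):
            return float(self.direct[stratum.value])
        return float(self.direct)

    def tau(self, stratum: Stratum | str = Stratum.COMBINED) -> float:
        """Total hormone -> CAD effect: direct + sum over mediators of alpha*beta."""
        return self.direct_for(stratum) + sum(
            m.alpha_for(stratum) * m.beta for m in self.mediators)

    def snp_effect(self, inst: InstrumentSpec, stratum: Stratum | str) -> float:
        stratum = Stratum.coerce(stratum)
        mult = {Stratum.MALE: self.sex_multiplier.get("male", 1.0),
                Stratum.FEMALE: self.sex_multiplier.get("female", 1.0)}
        if stratum is Stratum.COMBINED:
            ff = self.female_fraction
            m = ff * mult[Stratum.FEMALE] + (1 - ff) * mult[Stratum.MALE]
        else:
            m = mult[stratum]
        return inst.beta_exposure * m

    def variant_info(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"CHR": [i.chrom for i in self.instruments],
             "BP": [i.pos if i.pos else j + 1 for j, i in enumerate(self.instruments)],
             "EA": [i.effect_allele for i in self.instruments],
             "OA": [i.other_allele for i in self.instruments],
             "LOCUS": [i.locus for i in self.instruments]},
            index=[i.variant_id for i in self.instruments])

    def truth(self) -> dict:
        """Ground-truth sidecar of all structural parameters."""
        return {
            "alpha": {m.name: {s.value: m.alpha_for(s) for s in STRATA}
                      for m in self.mediators},
            "beta_mediator": {m.name: m.beta for m in self.mediators},
            "direct": {s.value: self.direct_for(s) for s in STRATA},
            "tau": {s.value: self.tau(s) for s in STRATA},
            "instruments": {i.variant_id: {s.value: self.snp_effect(i, s) for s in STRATA}
                            for i in self.instruments},
        }


def simulate_cohort(spec: CausalNetworkSpec, study_id: str, seed: int,
                    n: int | None = None) -> pd.DataFrame:
    """Simulate one individual-level cohort table.

    Genotypes are binomial(2, EAF) dosages; log-hormone is the additive
    genetic signal (sex-multiplied per stratum) plus age and log-BMI slopes
    plus Gaussian noise; each mediator is ``alpha * log-hormone`` plus noise
    on top of a sex-specific anthropometric baseline; the CAD liability adds
    the direct path and all mediator paths, and a binary CAD label is drawn
    from a logistic model of the liability.
    """
    if n is None:
        if study_id not in spec.cohort_sizes:
            raise ConfigError(f"unknown study {study_id!r}; spec has {list(spec.cohort_sizes)}")
        n = int(spec.cohort_sizes[study_id])
    if n <= 0:
        raise ConfigError("cohort size must be positive")
    rng = np.random.default_rng(seed)

    sex = np.where(rng.random(n) < spec.female_fraction, "female", "male")
    is_f = sex == "female"
    age = rng.normal(63.0, 8.0, n).clip(40, 85)
    bmi = np.exp(rng.normal(np.log(28.0), 0.15, n))

    mediator_names = {m.name for m in spec.mediators}
    geno = {i.variant_id: rng.binomial(2, i.eaf, n).astype(float)
            for i in spec.instruments}
    mult = np.where(is_f, spec.sex_multiplier.get("female", 1.0),
                    spec.sex_multiplier.get("male", 1.0))
    genetic = sum(g * i.beta_exposure for i, g in
                  ((i, geno[i.variant_id]) for i in spec.instruments))
    log_h = genetic * mult + spec.age_slope * age
    if "BMI" not in mediator_names:
        # BMI is a hormone covariate only when it is not itself a mediator
        log_h = log_h + spec.log_bmi_slope * np.log(bmi)
    log_h = log_h + rng.normal(0.0, spec.exposure_noise_sd, n)

    cohort = pd.DataFrame({
        "ID": [f"{study_id}_{k:06d}" for k in range(n)],
        "SEX": sex, "AGE": age, "BMI": bmi,
        "WHR": np.where(is_f, rng.normal(0.89, 0.06, n), rng.normal(1.01, 0.06, n)),
    })

    liability = np.full(n, 0.0)
    for m in spec.mediators:
        a = np.where(is_f, m.alpha_for(Stratum.FEMALE), m.alpha_for(Stratum.MALE))
        med = a * log_h + rng.normal(0.0, m.noise_sd, n)
        if m.name in ("WHR", "BMI"):
            base = cohort["WHR"].to_numpy() if m.name == "WHR" else np.log(bmi)
            cohort[m.name] = base + med
        else:
            cohort[m.name] = med
        liability = liability + m.beta * med
    direct = np.where(is_f, spec.direct_for(Stratum.FEMALE), spec.direct_for(Stratum.MALE))
    liability = liability + direct * log_h + rng.normal(0.0, spec.outcome_noise_sd, n)

    cohort["CAD_LIABILITY"] = liability
    cohort["CAD"] = rng.binomial(1, 1.0 / (1.0 + np.exp(-(liability - liability.mean()))))
    cohort[spec.exposure_name] = np.exp(log_h)
    for i in spec.instruments:
        cohort[i.variant_id] = geno[i.variant_id]
    return cohort


@dataclass
class SumstatsBundle:
    """Per-stratum, per-table lists of per-study canonical summary statistics."""

    tables: dict[tuple[str, str], list[pd.DataFrame]]
    truth: dict
    spec: CausalNetworkSpec

    def get(self, stratum: Stratum | str, table: str) -> list[pd.DataFrame]:
        return self.tables[(Stratum.coerce(stratum).value, table)]


def _fast_table(rng: np.random.Generator, spec: CausalNetworkSpec,
                true_effects: Sequence[float], total_sd: float, n: int) -> pd.DataFrame:
    from scipy import stats

    rows = []
    vi = spec.variant_info()
    for inst, b_true in zip(spec.instruments, true_effects):
        p_allele = inst.eaf
        eaf_hat = rng.binomial(2 * n, p_allele) / (2 * n)
        se = total_sd / np.sqrt(2 * p_allele * (1 - p_allele) * n)
        beta_hat = b_true if se == 0 else rng.normal(b_true, se)
        se_out = max(se, 1e-12)
        z = beta_hat / se_out
        p = max(float(2 * stats.norm.sf(abs(z))), float(np.nextafter(0, 1)))
        mac = int(round(min(eaf_hat, 1 - eaf_hat) * 2 * n))
        rows.append((inst.variant_id, inst.chrom, int(vi.loc[inst.variant_id, "BP"]),
                     inst.effect_allele, inst.other_allele,
                     float(np.clip(eaf_hat, 1e-6, 1 - 1e-6)), 1.0,
                     float(beta_hat), float(se_out), p, n, mac))
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)


def _stratum_n(n: int, stratum: Stratum, female_fraction: float) -> int:
    if stratum is Stratum.COMBINED:
        return n
    if stratum is Stratum.FEMALE:
        return max(int(round(n * female_fraction)), 1)
    return max(int(round(n * (1 - female_fraction))), 1)


def simulate_sumstats_pair(spec: CausalNetworkSpec, seed: int, mode: str = "fast",
                           strata: Sequence[Stratum | str] = (Stratum.COMBINED,),
                           ) -> SumstatsBundle:
    """Generate exposure, mediator and outcome summary statistics per stratum.

    ``mode="fast"`` draws each per-study SNP effect from its asymptotic
    sampling distribution; ``mode="exact"`` simulates the cohorts and runs
    the association engine. Tables per stratum: ``exposure``,
    ``mediator:<name>`` (one per mediator), ``outcome``.
    """
    if mode not in ("fast", "exact"):
        raise ConfigError(f"unknown mode {mode!r}")
    strata = [Stratum.coerce(s) for s in strata]
    tables: dict[tuple[str, str], list[pd.DataFrame]] = {}

    if mode == "exact":
        ss = np.random.SeedSequence(seed)
        study_seeds = ss.generate_state(len(spec.cohort_sizes))
        vi = spec.variant_info()
        variants = [i.variant_id for i in spec.instruments]
        for stratum in strata:
            covs = ("age", "log_bmi", "sex") if stratum is Stratum.COMBINED \
                else ("age", "log_bmi")
            if "BMI" in {m.name for m in spec.mediators}:
                covs = tuple(c for c in covs if c != "log_bmi")
            for key in ["exposure", *[f"mediator:{m.name}" for m in spec.mediators],
                        "outcome"]:
                tables[(stratum.value, key)] = []
        for sid, sseed in zip(spec.cohort_sizes, study_seeds):
            cohort = simulate_cohort(spec, sid, int(sseed) % (2**31))
            for stratum in strata:
                covs = ("age", "log_bmi", "sex") if stratum is Stratum.COMBINED \
                    else ("age", "log_bmi")
                if "BMI" in {m.name for m in spec.mediators}:
                    covs = tuple(c for c in covs if c != "log_bmi")
                specs = [("exposure", TraitSpec(spec.exposure_name, "log", covs))]
                specs += [(f"mediator:{m.name}", TraitSpec(m.name, "none", covs))
                          for m in spec.mediators]
                specs += [("outcome", TraitSpec("CAD_LIABILITY", "none", covs))]
                for key, tspec in specs:
                    df = run_association(cohort, tspec, variants, stratum,
                                         variant_info=vi)
                    tables[(stratum.value, key)].append(df)
        return SumstatsBundle(tables, spec.truth(), spec)

    # fast mode
    rng = np.random.default_rng(seed)
    sigma_h = spec.exposure_noise_sd
    for stratum in strata:
        b_exp = [spec.snp_effect(i, stratum) for i in spec.instruments]
        tau = spec.tau(stratum)
        med_sds = {}
        out_var = spec.outcome_noise_sd**2
        for m in spec.mediators:
            a = m.alpha_for(stratum)
            med_sds[m.name] = float(np.sqrt(a**2 * sigma_h**2 + m.noise_sd**2))
            out_var += (m.beta * m.noise_sd) ** 2
        out_sd = float(np.sqrt(out_var + (tau * sigma_h) ** 2))
        for key in ["exposure", *[f"mediator:{m.name}" for m in spec.mediators],
                    "outcome"]:
            tables[(stratum.value, key)] = []
        for n_cohort in spec.cohort_sizes.values():
            n = _stratum_n(int(n_cohort), stratum, spec.female_fraction)
            tables[(stratum.value, "exposure")].append(
                _fast_table(rng, spec, b_exp, sigma_h, n))
            for m in spec.mediators:
                a = m.alpha_for(stratum)
                tables[(stratum.value, f"mediator:{m.name}")].append(
                    _fast_table(rng, spec, [a * b for b in b_exp], med_sds[m.name], n))
            tables[(stratum.value, "outcome")].append(
                _fast_table(rng, spec, [tau * b for b in b_exp], out_sd, n))
    return SumstatsBundle(tables, spec.truth(), spec)


# ---------------------------------------------------------------------------
# HLA haplotype simulation
# ---------------------------------------------------------------------------

def synthetic_hla_freqs() -> HaplotypeFreqTable:
    """A small synthetic two-locus haplotype frequency table (not measured data).

    Loci mimic an HLA-B x HLA-C style pair: strong coupling between one
    allele pair, moderate elsewhere, with a rare haplotype to exercise the
    rare-subtype filter.
    """
    f = np.array([
        [0.28, 0.02, 0.01],
        [0.03, 0.33, 0.02],
        [0.01, 0.02, 0.28],
    ])
    return HaplotypeFreqTable(
        alleles_a=("B*14*02", "B*07*02", "B*08*01"),
        alleles_b=("C*08*02", "C*07*02", "C*07*01"),
        f=f / f.sum())


def simulate_hla(freqs: HaplotypeFreqTable, n: int, qc_noise: float,
                 seed: int, study_id: str = "study") -> HLADosageMatrix:
    """Draw two haplotypes per subject from the joint frequency table.

    The dosage of each subtype (an allele at either locus) is its copy count
    over the two haplotypes. Each subtype carries a per-sample combined
    probability score: with ``qc_noise = 0`` all scores are exactly 1 (no
    subject filtered); larger values corrupt scores downwards to exercise
    the >= 0.7 QC threshold.
    """
    if qc_noise < 0:
        raise ConfigError("qc_noise must be non-negative")
    rng = np.random.default_rng(seed)
    n_a, n_b = freqs.f.shape
    flat = freqs.f.ravel()
    draws = rng.choice(flat.size, size=(n, 2), p=flat / flat.sum())
    a_idx, b_idx = draws // n_b, draws % n_b

    cols = {}
    for j, label in enumerate(freqs.alleles_a):
        cols[label] = (a_idx == j).sum(axis=1).astype(float)
    for j, label in enumerate(freqs.alleles_b):
        cols[label] = (b_idx == j).sum(axis=1).astype(float)
    dose = pd.DataFrame(cols, index=[f"{study_id}_{k:06d}" for k in range(n)])
    dose.index.name = "ID"
    if qc_noise == 0:
        prob = pd.DataFrame(1.0, index=dose.index, columns=dose.columns)
    else:
        s1 = np.clip(1.0 - np.abs(rng.normal(0, qc_noise, dose.shape)), 0.0, 1.0)
        s2 = np.clip(1.0 - np.abs(rng.normal(0, qc_noise, dose.shape)), 0.0, 1.0)
        prob = pd.DataFrame(s1 * s2, index=dose.index, columns=dose.columns)
    return HLADosageMatrix(dose, prob, study_id=study_id)
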