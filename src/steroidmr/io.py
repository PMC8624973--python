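"""Domain records and tabular IO for GWAS summary statistics, cohorts, and HLA dosages.

Canonical summary-statistics columns (tab-separated):
``SNP CHR BP EA OA EAF INFO BETA SE P N MAC`` — effect sizes are on the
log-trait scale per copy of the effect allele ``EA``. Coordinates are 1-based.
Missing values are written as ``NA``; p-values are written in scientific
notation with 4 significant digits.
"""
from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import ConfigError

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "INFO", "BETA", "SE", "P", "N", "MAC"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Stratum(str, enum.Enum):
    """Analysis stratum: all samples, or one sex."""

    COMBINED = "combined"
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def coerce(cls, value: "Stratum | str") -> "Stratum":
        return value if isinstance(value, cls) else cls(str(value).lower())


class RowValidationError(ValueError):
    """A data row violates a record invariant; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass
class VariantAssoc:
    """One variant's association record in one study and stratum."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    info: float
    beta: float
    se: float
    p: float
    n: int
    mac: int

    def validate(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.variant_id}: eaf must lie in (0, 1), got {self.eaf}")
        if not 0 <= self.info <= 1:
            raise ValueError(f"{self.variant_id}: info must lie in [0, 1], got {self.info}")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele must differ")
        if not 0 < self.p <= 1:
            raise ValueError(f"{self.variant_id}: p must lie in (0, 1], got {self.p}")

    @property
    def key(self) -> tuple[str, int, tuple[str, str]]:
        """Variant identity: (chrom, pos, sorted allele pair)."""
        a, b = sorted((self.effect_allele, self.other_allele))
        return (self.chrom, self.pos, (a, b))

    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


def records_to_frame(records: Iterable[VariantAssoc]) -> pd.DataFrame:
    rows = [
        (r.variant_id, r.chrom, r.pos, r.effect_allele, r.other_allele,
         r.eaf, r.info, r.beta, r.se, r.p, r.n, r.mac)
        for r in records
    ]
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[VariantAssoc]:
    return [
        VariantAssoc(str(t.SNP), str(t.CHR), int(t.BP), str(t.EA), str(t.OA),
                     float(t.EAF), float(t.INFO), float(t.BETA), float(t.SE),
                     float(t.P), int(t.N), int(t.MAC))
        for t in df.itertuples(index=False)
    ]


def read_sumstats(path: str | Path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a summary-statistics TSV into the canonical column layout.

    Parameters
    ----------
    path : file path
    dialect : optional mapping from the file's column names to canonical
        names, e.g. ``{"NEA": "OA", "FREQ1": "EAF"}``. Columns already named
        canonically pass through.

    Every row is validated against the record invariants; the first violating
    row raises :class:`RowValidationError` with its 1-based file line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "EA": str, "OA": str},
                     na_values=["NA"], keep_default_na=False)
    if dialect:
        df = df.rename(columns=dict(dialect))
        df = df.astype({c: str for c in ("SNP", "CHR", "EA", "OA") if c in df.columns})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required columns {missing}")
    df = df[SUMSTATS_COLUMNS].copy()
    for col in ("BP", "EAF", "INFO", "BETA", "SE", "P", "N", "MAC"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2 if bad.any() else 0
            raise RowValidationError(line, f"non-numeric value in column {col}") from exc
    df["BP"] = df["BP"].astype(int)
    df["N"] = df["N"].astype(int)
    df["MAC"] = df["MAC"].round().astype(int)
    for i, rec in enumerate(frame_to_records(df)):
        try:
            rec.validate()
        except ValueError as exc:
            raise RowValidationError(i + 2, str(exc)) from exc
    return df


def _format_p(x: float) -> str:
    return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.3e}"


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write canonical summary statistics as TSV (``NA`` missing, P as %.3e)."""
    out = df[SUMSTATS_COLUMNS].copy()
    out["P"] = out["P"].map(_format_p)
    out["MAC"] = out["MAC"].round().astype("Int64")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read an individual-level cohort TSV (ID, SEX, AGE, BMI, WHR, CAD, traits, dosages)."""
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "SEX": str},
                     na_values=["NA"], keep_default_na=False)
    for col in ("ID", "SEX"):
        if col not in df.columns:
            raise ConfigError(f"{path}: cohort table missing column {col}")
    bad_sex = ~df["SEX"].isin(["male", "female"])
    if bad_sex.any():
        raise ConfigError(f"{path}: SEX must be 'male'/'female'; "
                          f"offending rows {list(np.flatnonzero(bad_sex)[:5] + 2)}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an HLA dosage TSV into (dosage, probability) frames indexed by sample ID.

    Subtype columns are named ``GENE*FIELD1*FIELD2`` (e.g. ``B*14*02``); each
    may carry a companion ``<subtype>__prob`` column with the per-sample
    combined probability score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ID": str}, na_values=["NA"], keep_default_na=False)
    if "ID" not in df.columns:
        raise ConfigError(f"{path}: dosage matrix missing ID column")
    df = df.set_index("ID")
    prob_cols = [c for c in df.columns if c.endswith("__prob")]
    dose = df[[c for c in df.columns if not c.endswith("__prob")]].astype(float)
    prob = df[prob_cols].astype(float)
    prob.columns = [c[: -len("__prob")] for c in prob_cols]
    prob = prob.reindex(columns=dose.columns, fill_value=1.0)
    if ((dose < 0) | (dose > 2)).any().any():
        raise ConfigError(f"{path}: dosages must lie in [0, 2]")
    return dose, prob


def write_dosage_matrix(dose: pd.DataFrame, prob: pd.DataFrame, path: str | Path) -> None:
    out = dose.copy()
    for c in dose.columns:
        out[f"{c}__prob"] = prob[c]
    out.index.name = "ID"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

class HarmonizeStatus(str, enum.Enum):
    OK = "ok"                  # already on the same effect allele
    FLIPPED = "flipped"        # b's orientation flipped (beta, eaf)
    AMBIGUOUS = "ambiguous"    # palindromic with uninformative allele frequency
    MISMATCH = "mismatch"      # allele sets irreconcilable


def _flip(b: VariantAssoc) -> VariantAssoc:
    return dataclasses.replace(
        b, effect_allele=b.other_allele, other_allele=b.effect_allele,
        beta=-b.beta, eaf=1.0 - b.eaf)


def _strand_complement(b: VariantAssoc) -> VariantAssoc | None:
    try:
        return dataclasses.replace(
            b, effect_allele=_COMPLEMENT[b.effect_allele],
            other_allele=_COMPLEMENT[b.other_allele])
    except KeyError:
        return None


def harmonize_alleles(
    a: VariantAssoc,
    b: VariantAssoc,
    ambiguous_eaf_window: tuple[float, float] = (0.4, 0.6),
) -> tuple[VariantAssoc, HarmonizeStatus]:
    """Align ``b`` to the effect allele of ``a``.

    If b's effect allele equals a's other allele, b is flipped
    (``beta := -beta``, ``eaf := 1 - eaf``). Alleles on the opposite strand
    are complemented first. Palindromic variants (A/T, C/G) whose allele
    frequency in either record falls inside ``ambiguous_eaf_window`` are
    flagged ambiguous (strand cannot be resolved) and should be excluded.
    Returns the (possibly flipped) copy of ``b`` and a status flag.
    """
    if a.key[:2] != b.key[:2]:
        raise ValueError("harmonize_alleles requires records at the same chrom/pos")

    if a.is_palindromic() or b.is_palindromic():
        lo, hi = ambiguous_eaf_window
        if lo <= a.eaf <= hi or lo <= b.eaf <= hi:
            return b, HarmonizeStatus.AMBIGUOUS

    if {b.effect_allele, b.other_allele} != {a.effect_allele, a.other_allele}:
        # A strand complement is accepted only when it aligns without an
        # additional allele swap: complement-plus-swap cannot be told apart
        # from a genuinely different allele pair, so it is a mismatch.
        comp = _strand_complement(b)
        if comp is None or comp.effect_allele != a.effect_allele \
                or comp.other_allele != a.other_allele:
            return b, HarmonizeStatus.MISMATCH
        b = comp

    if b.effect_allele == a.effect_allele:
        return b, HarmonizeStatus.OK
    return _flip(b), HarmonizeStatus.FLIPPED


def harmonize_frames(a: pd.DataFrame, b: pd.DataFrame,
                     ambiguous_eaf_window: tuple[float, float] = (0.4, 0.6),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join two canonical frames on SNP and align ``b`` to ``a``'s alleles.

    Ambiguous and mismatching variants are dropped from both outputs.
    """
    a_idx = a.set_index("SNP")
    b_idx = b.set_index("SNP")
    shared = a_idx.index.intersection(b_idx.index)
    keep_a, keep_b = [], []
    for snp in shared:
        ra = frame_to_records(a_idx.loc[[snp]].reset_index())[0]
        rb = frame_to_records(b_idx.loc[[snp]].reset_index())[0]
        rb2, status = harmonize_alleles(ra, rb, ambiguous_eaf_window)
        if status in (HarmonizeStatus.OK, HarmonizeStatus.FLIPPED):
            keep_a.append(ra)
            keep_b.append(rb2)
    return records_to_frame(keep_a), records_to_frame(keep_b)
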