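"""Read and harmonise GWAS summary statistics, reference panels, and results.

Internal conventions: positions are 1-based everywhere inside the package
(BED input is converted at read time); effect sizes are stored as odds
ratios (beta = log OR on demand); a variant is keyed by chromosome,
position, and its unordered allele pair, so the key is strand-naive but
allele-aware.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: logical column -> default file column for summary-statistics text files
DEFAULT_DIALECT: dict[str, str] = {
    "chrom": "CHR",
    "pos": "BP",
    "variant_id": "SNP",
    "allele_effect": "A1",
    "allele_other": "A2",
    "odds_ratio": "OR",
    "beta": "BETA",
    "p_value": "P",
    "se": "SE",
}

REQUIRED_LOGICAL = ("chrom", "pos", "variant_id", "allele_effect", "allele_other", "p_value")

STATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "allele_effect",
    "allele_other",
    "odds_ratio",
    "p_value",
    "se",
    "key",
]

ENHANCED_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "input_p",
    "deepgwas_prob",
    "input_significant",
    "enhanced",
]

PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


class ConfigError(ValueError):
    """A configuration problem (missing column, bad dialect, bad schema)."""


@dataclass
class SkipReport:
    """Accounting of rows dropped while reading or harmonising."""

    n_input: int = 0
    n_bad_p: int = 0
    n_bad_or: int = 0
    n_duplicate: int = 0
    n_absent: int = 0
    n_allele_mismatch: int = 0
    n_ambiguous_palindromic: int = 0
    dropped: list = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return self.n_bad_p + self.n_bad_or + self.n_duplicate


def variant_key(chrom, pos, a1: str, a2: str) -> str:
    """Canonical variant key: chrom:pos:sorted allele pair (strand-naive)."""
    a, b = sorted((str(a1).upper(), str(a2).upper()))
    return f"{chrom}:{int(pos)}:{a}:{b}"


def _keys(df: pd.DataFrame, effect="allele_effect", other="allele_other") -> pd.Series:
    a1 = df[effect].astype(str).str.upper()
    a2 = df[other].astype(str).str.upper()
    lo = np.minimum(a1, a2)
    hi = np.maximum(a1, a2)
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str) + ":" + lo + ":" + hi
    )


def is_palindromic(a1: str, a2: str) -> bool:
    return {str(a1).upper(), str(a2).upper()} in PALINDROMIC_PAIRS


def read_summary_stats(
    path: str | os.PathLike,
    dialect: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, SkipReport]:
    """Read a whitespace/tab-delimited GWAS summary-statistics file.

    ``dialect`` maps logical columns (``chrom``, ``pos``, ``variant_id``,
    ``allele_effect``, ``allele_other``, ``p_value``, and one of
    ``odds_ratio`` / ``beta``, optionally ``se``) to file column names;
    omitted entries fall back to the conventional CHR/BP/SNP/A1/A2/OR/P
    names. Rows with unparsable or out-of-range p-values or effect sizes
    are dropped and counted in the returned :class:`SkipReport`; duplicate
    variant keys keep the first occurrence with a warning.
    """
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, comment=None)
    if raw.empty:
        raise ConfigError(f"{path}: empty summary-statistics file")

    for logical in REQUIRED_LOGICAL:
        if dia[logical] not in raw.columns:
            raise ConfigError(
                f"{path}: required column {dia[logical]!r} (logical {logical!r}) not found; "
                f"available: {list(raw.columns)}"
            )
    has_or = dia["odds_ratio"] in raw.columns
    has_beta = dia["beta"] in raw.columns
    if not has_or and not has_beta:
        raise ConfigError(
            f"{path}: need an effect-size column, either {dia['odds_ratio']!r} (OR) "
            f"or {dia['beta']!r} (beta)"
        )

    report = SkipReport(n_input=len(raw))
    df = pd.DataFrame(
        {
            "variant_id": raw[dia["variant_id"]],
            "chrom": raw[dia["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[dia["pos"]], errors="coerce"),
            "allele_effect": raw[dia["allele_effect"]].astype(str).str.upper(),
            "allele_other": raw[dia["allele_other"]].astype(str).str.upper(),
            "p_value": pd.to_numeric(raw[dia["p_value"]], errors="coerce"),
        }
    )
    if has_or:
        df["odds_ratio"] = pd.to_numeric(raw[dia["odds_ratio"]], errors="coerce")
    else:
        df["odds_ratio"] = np.exp(pd.to_numeric(raw[dia["beta"]], errors="coerce"))
    df["se"] = (
        pd.to_numeric(raw[dia["se"]], errors="coerce") if dia["se"] in raw.columns else np.nan
    )

    bad_p = ~(df["p_value"] > 0) | ~(df["p_value"] <= 1) | df["pos"].isna()
    report.n_bad_p = int(bad_p.sum())
    df = df[~bad_p]
    bad_or = ~(df["odds_ratio"] > 0) | ~np.isfinite(df["odds_ratio"])
    report.n_bad_or = int(bad_or.sum())
    df = df[~bad_or]
    if df.empty:
        raise ConfigError(f"{path}: no parsable rows remain")

    df = df.assign(pos=df["pos"].astype(np.int64))
    df["key"] = _keys(df)
    dup = df["key"].duplicated(keep="first")
    if dup.any():
        report.n_duplicate = int(dup.sum())
        logger.warning("%s: dropped %d duplicated variant keys", path, report.n_duplicate)
        df = df[~dup]
    df = df.reset_index(drop=True)[STATS_COLUMNS]
    return df, report


def beta_from_or(odds_ratio) -> np.ndarray:
    """Effect on the log-odds scale, beta = log(OR)."""
    return np.log(np.asarray(odds_ratio, dtype=float))


def harmonize(stats: pd.DataFrame, panel) -> tuple[pd.DataFrame, SkipReport]:
    """Align a summary-statistics table to a reference panel's allele coding.

    Variants absent from the panel (by key) are dropped; when the study's
    effect allele is the panel's reference allele the OR is inverted
    (OR -> 1/OR) and the allele columns swapped, so every retained effect
    refers to the panel's alternate allele. A/T and C/G (palindromic)
    variants are matched by position and allele pair without strand
    flipping; they are counted in the report, not resolved. Idempotent.
    """
    report = SkipReport(n_input=len(stats))
    pv = panel.variants
    chrom_overlap = set(stats["chrom"].astype(str)) & set(pv["chrom"].astype(str))
    merged = stats.merge(
        pv[["key", "ref", "alt"]], on="key", how="left", validate="one_to_one"
    )
    present = merged["ref"].notna()
    if not present.any():
        raise ValueError(
            "harmonize: zero overlapping variants between study and panel "
            f"(shared chromosomes: {sorted(chrom_overlap) or 'NONE - check genome build'})"
        )
    absent = merged.loc[~present]
    if len(absent):
        pos_keys = set(zip(pv["chrom"].astype(str), pv["pos"].astype(int)))
        for _, row in absent.iterrows():
            reason = (
                "allele_mismatch"
                if (str(row["chrom"]), int(row["pos"])) in pos_keys
                else "absent"
            )
            report.dropped.append((row["key"], reason))
            if reason == "absent":
                report.n_absent += 1
            else:
                report.n_allele_mismatch += 1

    out = merged.loc[present].copy()
    flip = out["allele_effect"] == out["ref"]
    out.loc[flip, "odds_ratio"] = 1.0 / out.loc[flip, "odds_ratio"]
    eff = out["allele_effect"].copy()
    out.loc[flip, "allele_effect"] = out.loc[flip, "allele_other"]
    out.loc[flip, "allele_other"] = eff[flip]
    pal = out.apply(lambda r: is_palindromic(r["allele_effect"], r["allele_other"]), axis=1)
    report.n_ambiguous_palindromic = int(pal.sum())
    if report.n_ambiguous_palindromic:
        logger.warning(
            "harmonize: %d palindromic (A/T or C/G) variants matched without strand "
            "resolution",
            report.n_ambiguous_palindromic,
        )
    out = out.drop(columns=["ref", "alt"]).reset_index(drop=True)
    return out, report


def write_enhanced_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the per-variant enhancement table as TSV with a stable header.

    Columns: variant_id, chrom, pos, input_p, deepgwas_prob,
    input_significant, enhanced. Round-trips losslessly through
    :func:`read_enhanced_results`.
    """
    missing = [c for c in ENHANCED_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"write_enhanced_results: missing columns {missing}")
    prob = np.asarray(table["deepgwas_prob"], dtype=float)
    if len(prob) and (np.nanmin(prob) < 0 or np.nanmax(prob) > 1):
        raise ValueError("deepgwas_prob outside [0, 1]")
    out = table[ENHANCED_COLUMNS].copy()
    out["input_significant"] = out["input_significant"].astype(bool)
    out["enhanced"] = out["enhanced"].astype(bool)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_enhanced_results(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("input_significant", "enhanced"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False})
    return df[ENHANCED_COLUMNS]


def read_panel(path: str | os.PathLike, max_missing: float = 0.10):
    """Load a genotype reference panel from a VCF (optionally bgzipped).

    Keeps biallelic records; genotypes become alternate-allele dosages in
    {0, 1, 2} with NaN for missing. Variants with more than ``max_missing``
    missingness are excluded at load and logged.
    """
    from cyvcf2 import VCF

    from deepgwas.popgen import GenotypePanel

    vcf = VCF(str(path))
    rows = []
    geno_cols = []
    n_excluded = 0
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dosage = np.choose(gt.astype(int), [0.0, 1.0, np.nan, 2.0])
        if np.isnan(dosage).mean() > max_missing:
            n_excluded += 1
            continue
        rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "variant_id": var.ID or variant_key(var.CHROM, var.POS, var.REF, var.ALT[0]),
                "ref": str(var.REF).upper(),
                "alt": str(var.ALT[0]).upper(),
            }
        )
        geno_cols.append(dosage)
    if n_excluded:
        logger.warning("read_panel: excluded %d variants with >%.0f%% missing genotypes",
                       n_excluded, 100 * max_missing)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic variants")
    variants = pd.DataFrame(rows)
    variants["key"] = _keys(variants, effect="alt", other="ref")
    genotypes = np.column_stack(geno_cols)
    return GenotypePanel(variants=variants, genotypes=genotypes)
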