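"""Cohort summary-statistic I/O, harmonisation, QC and genomic control.

Cohort-level GWAS results arrive as tab-delimited tables with one row per
variant (effect estimate, standard error, Z, allele frequency, imputation
quality).  This module parses them into :class:`CohortSummary` objects,
applies study- and variant-level quality filters, aligns alleles across
cohorts into a :class:`MergedVariantTable`, applies genomic-control
correction to low-frequency variants and enforces the meta-analysis
inclusion filters.

Positions are 1-based (VCF convention); chromosome names are normalised by
stripping a leading ``chr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: median of the 1-df chi-square distribution, used to convert a median
#: test statistic into a genomic-control lambda.
CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))

DEFAULT_COLUMN_MAP: dict[str, str] = {
    "chrom": "CHR",
    "pos": "POS",
    "ref": "REF",
    "alt": "ALT",
    "freq": "AF",
    "beta": "BETA",
    "se": "SE",
    "z": "Z",
    "rsq": "RSQ",
    "n": "N",
}

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: maximum allele-frequency discrepancy tolerated when aligning a
#: strand-ambiguous (A/T or C/G) variant across cohorts.
PALINDROMIC_FREQ_TOL = 0.2


class ConfigurationError(ValueError):
    """Invalid configuration (missing columns, unknown analysis kind...)."""


class InputError(ValueError):
    """Malformed or empty input data."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class VariantRecord:
    """One variant's association summary in a single study."""

    chrom: str
    pos: int
    ref: str
    alt: str
    freq: float
    beta: float
    se: float
    z: float
    rsq: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortSummary:
    """Per-variant association records plus study metadata for one cohort."""

    study_id: str
    n: int
    lambda_gc: float
    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError(f"{self.study_id}: sample size must be >= 1")
        if self.lambda_gc <= 0:
            raise InputError(f"{self.study_id}: lambda_gc must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "ref": [r.ref for r in self.records],
                "alt": [r.alt for r in self.records],
                "freq": [r.freq for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "z": [r.z for r in self.records],
                "rsq": [r.rsq for r in self.records],
            }
        )


@dataclass
class MergedVariantTable:
    """Variants × studies arrays of allele-aligned summary statistics.

    ``variants`` carries one row per harmonised variant (chrom, pos, ref,
    alt, n_studies, pooled alt-allele frequency, MAF and effective sample
    size Σ N_k·R²_jk).  The per-study matrices use NaN for studies in which
    a variant is absent.
    """

    variants: pd.DataFrame
    study_ids: list[str]
    n_per_study: np.ndarray  # (K,)
    beta: np.ndarray  # (J, K)
    se: np.ndarray
    z: np.ndarray
    freq: np.ndarray
    rsq: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    def variant_keys(self) -> pd.Series:
        v = self.variants
        return (
            v["chrom"].astype(str)
            + ":"
            + v["pos"].astype(str)
            + ":"
            + v["ref"]
            + ":"
            + v["alt"]
        )

    def subset(self, mask: np.ndarray) -> "MergedVariantTable":
        idx = np.asarray(mask)
        return MergedVariantTable(
            variants=self.variants.loc[idx].reset_index(drop=True),
            study_ids=list(self.study_ids),
            n_per_study=self.n_per_study,
            beta=self.beta[idx],
            se=self.se[idx],
            z=self.z[idx],
            freq=self.freq[idx],
            rsq=self.rsq[idx],
        )

    def write(self, path) -> None:
        """Write the merged table as TSV (wide: one block per study)."""
        out = self.variants.copy()
        for k, sid in enumerate(self.study_ids):
            out[f"beta__{sid}"] = self.beta[:, k]
            out[f"se__{sid}"] = self.se[:, k]
            out[f"z__{sid}"] = self.z[:, k]
            out[f"freq__{sid}"] = self.freq[:, k]
            out[f"rsq__{sid}"] = self.rsq[:, k]
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reading and writing cohort files
# ---------------------------------------------------------------------------

def read_cohort_summary(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    study_id: str | None = None,
    n: int | None = None,
    lambda_gc: float | None = None,
) -> CohortSummary:
    """Parse one cohort's tab-delimited summary statistics.

    Rows with unparseable numeric fields are dropped (and counted in the
    log).  A missing Z column is reconstructed as beta/se; missing beta/se
    are reconstructed from Z via the standardised-trait approximation
    ``beta = z / sqrt(2·N·p·(1−p)·rsq)`` when frequency and N are present.

    Parameters
    ----------
    column_map
        Mapping from the standard field names (``chrom, pos, ref, alt,
        freq, beta, se, z, rsq, n``) to the file's column names.  Defaults
        to ``CHR, POS, REF, ALT, AF, BETA, SE, Z, RSQ, N``.
    n, lambda_gc
        Study sample size and genomic-control value.  If omitted, ``n`` is
        taken as the maximum of the file's N column and ``lambda_gc`` as
        ``median(z²)/0.4549`` over parsed records.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise InputError(f"{path}: empty summary-statistics file")
    required = ["chrom", "pos", "ref", "alt", "freq"]
    for fld in required:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(f"{path}: required column {cmap[fld]!r} missing")
    has = {f: cmap[f] in df.columns for f in cmap}
    if not (has["z"] or (has["beta"] and has["se"])):
        raise ConfigurationError(f"{path}: need Z or BETA+SE columns")

    work = pd.DataFrame(
        {
            "chrom": df[cmap["chrom"]].map(normalize_chrom),
            "ref": df[cmap["ref"]].str.upper(),
            "alt": df[cmap["alt"]].str.upper(),
        }
    )
    numeric = ["pos", "freq"]
    for f in ("beta", "se", "z", "rsq", "n"):
        if has[f]:
            numeric.append(f)
    def _coerce(col: pd.Series) -> pd.Series:
        # float() round-trips repr output exactly, unlike pd.to_numeric
        def parse(x):
            try:
                return float(x)
            except (TypeError, ValueError):
                return np.nan
        return col.map(parse)

    for f in numeric:
        work[f] = _coerce(df[cmap[f]])
    if "rsq" not in work:
        work["rsq"] = 1.0
    study_n = n if n is not None else (int(np.nanmax(work["n"])) if has["n"] else None)
    if study_n is None:
        raise ConfigurationError(f"{path}: sample size not given and no N column")

    # reconstruct missing statistics where possible
    if "z" not in work:
        work["z"] = np.nan
    if "beta" not in work:
        work["beta"] = np.nan
        work["se"] = np.nan
    need_z = work["z"].isna() & work["beta"].notna() & work["se"].notna()
    work.loc[need_z, "z"] = work.loc[need_z, "beta"] / work.loc[need_z, "se"]
    need_b = work["beta"].isna() & work["z"].notna()
    if need_b.any():
        p = work.loc[need_b, "freq"]
        denom = np.sqrt(2.0 * study_n * p * (1 - p) * work.loc[need_b, "rsq"])
        work.loc[need_b, "se"] = 1.0 / denom
        work.loc[need_b, "beta"] = work.loc[need_b, "z"] / denom
        logger.info("%s: reconstructed beta/se from z for %d rows", path, int(need_b.sum()))

    ok = (
        work[["pos", "freq", "beta", "se", "z", "rsq"]].notna().all(axis=1)
        & (work["freq"] > 0)
        & (work["freq"] < 1)
        & (work["se"] > 0)
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.info("%s: dropped %d unparseable/invalid rows", path, dropped)
    work = work[ok]
    if lambda_gc is None:
        lambda_gc = float(np.median(work["z"] ** 2) / CHI2_MEDIAN) if len(work) else 1.0

    records = [
        VariantRecord(
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            freq=float(r.freq),
            beta=float(r.beta),
            se=float(r.se),
            z=float(r.z),
            rsq=float(r.rsq),
        )
        for r in work.itertuples()
    ]
    sid = study_id if study_id is not None else str(path)
    cohort = CohortSummary(study_id=sid, n=study_n, lambda_gc=lambda_gc, records=records)
    cohort.n_dropped_rows = dropped  # type: ignore[attr-defined]
    return cohort


def write_cohort_summary(cohort: CohortSummary, path) -> None:
    """Write a cohort back out in the default column layout."""
    df = cohort.to_frame()
    df.columns = [DEFAULT_COLUMN_MAP[c] for c in df.columns]
    df["N"] = cohort.n
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_study_qc(
    cohorts: Sequence[CohortSummary],
    *,
    min_n: int = 100,
    lambda_bounds: tuple[float, float] = (0.9, 1.1),
    lambda_exempt_n: int = 10_000,
    min_rsq: float = 0.3,
) -> tuple[list[CohortSummary], pd.DataFrame]:
    """Apply study- and variant-level QC.

    Studies with fewer than ``min_n`` individuals are removed; studies with
    a genomic-control value outside ``lambda_bounds`` are removed unless
    their sample size reaches ``lambda_exempt_n``.  Within kept studies,
    variant records with imputation quality below ``min_rsq`` are dropped.

    Returns the kept cohorts and a drop log (study_id, variant, reason);
    study-level drops carry an empty variant field.
    """
    kept: list[CohortSummary] = []
    log_rows: list[tuple[str, str, str]] = []
    lo, hi = lambda_bounds
    for c in cohorts:
        if c.n < min_n:
            log_rows.append((c.study_id, "", f"N<{min_n}"))
            continue
        if (c.lambda_gc < lo or c.lambda_gc > hi) and c.n < lambda_exempt_n:
            log_rows.append((c.study_id, "", f"lambda outside [{lo},{hi}] and N<{lambda_exempt_n}"))
            continue
        records = []
        for r in c.records:
            if r.rsq < min_rsq:
                log_rows.append((c.study_id, f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}", f"rsq<{min_rsq}"))
            else:
                records.append(r)
        kept.append(CohortSummary(c.study_id, c.n, c.lambda_gc, records))
    drop_log = pd.DataFrame(log_rows, columns=["study_id", "variant", "reason"])
    return kept, drop_log


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def _is_palindromic(ref: str, alt: str) -> bool:
    return (ref, alt) in _PALINDROMIC


def harmonize_variants(cohorts: Sequence[CohortSummary]) -> MergedVariantTable:
    """Align variants across cohorts to a common alt allele.

    Variants are matched on (chrom, pos).  The orientation of the first
    study carrying a variant is the reference orientation: an exact
    ref/alt match is kept as-is; a swapped pair flips the sign of beta and
    z and maps freq to 1−freq; any other allele pair is dropped as a
    mismatch.  Strand-ambiguous (A/T, C/G) variants are kept only when the
    per-study frequency agrees with the reference orientation within
    ``PALINDROMIC_FREQ_TOL``.
    """
    if not cohorts:
        raise InputError("no cohorts to harmonize")
    K = len(cohorts)
    frames = []
    for k, c in enumerate(cohorts):
        df = c.to_frame()
        if df.duplicated(subset=["chrom", "pos", "ref", "alt"]).any():
            raise InputError(f"{c.study_id}: duplicate variant keys")
        df["study_idx"] = k
        frames.append(df)
    allrec = pd.concat(frames, ignore_index=True)

    # reference orientation: first study (lowest study_idx) per (chrom,pos)
    allrec = allrec.sort_values(["chrom", "pos", "study_idx"], kind="stable")
    first = allrec.drop_duplicates(subset=["chrom", "pos"], keep="first")
    ref_orient = first.set_index(["chrom", "pos"])[["ref", "alt", "freq"]]

    orient = ref_orient.loc[pd.MultiIndex.from_frame(allrec[["chrom", "pos"]])]
    r0 = orient["ref"].to_numpy()
    a0 = orient["alt"].to_numpy()
    f0 = orient["freq"].to_numpy()
    r = allrec["ref"].to_numpy()
    a = allrec["alt"].to_numpy()
    exact = (r == r0) & (a == a0)
    swapped = (r == a0) & (a == r0) & ~exact
    pal = np.array([_is_palindromic(x, y) for x, y in zip(r, a)])
    # palindromic: strand flips make exact/swapped indistinguishable — keep
    # only when the string-aligned frequency agrees with the reference
    freq = allrec["freq"].to_numpy().astype(float)
    aligned_freq = np.where(swapped, 1.0 - freq, freq)
    pal_freq_ok = np.abs(aligned_freq - f0) < PALINDROMIC_FREQ_TOL
    keep = (exact | swapped) & (~pal | pal_freq_ok)
    flip = swapped & keep

    n_mismatch = int((~keep).sum())
    if n_mismatch:
        logger.info("harmonize: dropped %d allele-mismatch records", n_mismatch)

    rec = allrec[keep].copy()
    fl = flip[keep]
    rec.loc[fl, "beta"] = -rec.loc[fl, "beta"]
    rec.loc[fl, "z"] = -rec.loc[fl, "z"]
    rec.loc[fl, "freq"] = 1.0 - rec.loc[fl, "freq"]
    ori = ref_orient.loc[pd.MultiIndex.from_frame(rec[["chrom", "pos"]])]
    rec["ref"] = ori["ref"].to_numpy()
    rec["alt"] = ori["alt"].to_numpy()

    keys = rec.drop_duplicates(subset=["chrom", "pos"])[["chrom", "pos", "ref", "alt"]]
    keys = keys.sort_values(["chrom", "pos"]).reset_index(drop=True)
    key_index = {(c_, p_): j for j, (c_, p_) in enumerate(zip(keys["chrom"], keys["pos"]))}
    J = len(keys)
    mats = {f: np.full((J, K), np.nan) for f in ("beta", "se", "z", "freq", "rsq")}
    rows = np.fromiter(
        (key_index[(c_, p_)] for c_, p_ in zip(rec["chrom"], rec["pos"])),
        dtype=int,
        count=len(rec),
    )
    cols = rec["study_idx"].to_numpy()
    for f in mats:
        mats[f][rows, cols] = rec[f].to_numpy()

    n_per_study = np.array([c.n for c in cohorts], dtype=float)
    present = ~np.isnan(mats["beta"])
    eff_n = np.nansum(mats["rsq"] * n_per_study[None, :] * present, axis=1)
    pooled = np.nansum(mats["freq"] * n_per_study[None, :] * present, axis=1) / np.nansum(
        n_per_study[None, :] * present, axis=1
    )
    variants = keys.copy()
    variants["n_studies"] = present.sum(axis=1)
    variants["pooled_freq"] = pooled
    variants["maf"] = np.minimum(pooled, 1 - pooled)
    variants["effective_n"] = eff_n
    return MergedVariantTable(
        variants=variants,
        study_ids=[c.study_id for c in cohorts],
        n_per_study=n_per_study,
        beta=mats["beta"],
        se=mats["se"],
        z=mats["z"],
        freq=mats["freq"],
        rsq=mats["rsq"],
    )


# ---------------------------------------------------------------------------
# genomic control and meta-analysis filters
# ---------------------------------------------------------------------------

def genomic_control_correct(
    merged: MergedVariantTable,
    chisq: np.ndarray,
    maf_threshold: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Genomic-control correct low-frequency variants only.

    λ is the median chi-square over variants with MAF < ``maf_threshold``
    divided by the 1-df chi-square median (0.4549...); statistics of those
    variants are divided by max(λ, 1).  Common variants are untouched, and
    λ < 1 never inflates statistics.

    Returns the corrected statistics and the estimated λ.
    """
    chisq = np.asarray(chisq, dtype=float)
    maf = merged.variants["maf"].to_numpy()
    low = maf < maf_threshold
    if not low.any():
        logger.warning("genomic control: no variants with MAF < %g; returning input", maf_threshold)
        return chisq.copy(), 1.0
    lam = float(np.median(chisq[low]) / CHI2_MEDIAN)
    corrected = chisq.copy()
    corrected[low] = chisq[low] / max(lam, 1.0)
    return corrected, lam


ANALYSIS_KINDS = ("multi", "EUR", "AFR", "AMR", "EAS")


def apply_meta_filters(
    merged: MergedVariantTable,
    analysis_kind: str,
    *,
    min_studies: int = 3,
    min_eff_ratio: float = 0.1,
) -> MergedVariantTable:
    """Meta-analysis inclusion filters.

    Retains variants present in at least ``min_studies`` studies, with an
    effective-sample-size to maximum effective-sample-size ratio of at
    least ``min_eff_ratio``, and with MAF above 0.001 for the
    multi-ancestry and EUR-stratified analyses or above 0.01 for the
    AFR/AMR/EAS-stratified analyses.
    """
    if analysis_kind not in ANALYSIS_KINDS:
        raise ConfigurationError(f"unknown analysis kind {analysis_kind!r}")
    maf_floor = 0.001 if analysis_kind in ("multi", "EUR") else 0.01
    v = merged.variants
    eff = v["effective_n"].to_numpy()
    mask = (
        (v["n_studies"].to_numpy() >= min_studies)
        & (eff / eff.max() >= min_eff_ratio)
        & (v["maf"].to_numpy() > maf_floor)
    )
    return merged.subset(mask)
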