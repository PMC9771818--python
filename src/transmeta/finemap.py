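"""Bayes-factor fine-mapping, credible sets, gene mapping and enrichment.

Within each locus an approximate Bayes factor per variant,
``Λ_j = exp[(X_j − (T+1)·log K)/2]``, converts the joint Wald chi-square
X_j of the selected meta-regression model (T ancestry components, K
contributing studies) into relative evidence of causality under a
one-causal-variant assumption.  Normalising within the locus gives
posterior inclusion probabilities π_j = Λ_j/Σ_i Λ_i, and the 90% credible
set is the smallest PIP-ranked subset of cumulative mass ≥ 0.90.
Single-ancestry fine-mapping uses the same machinery with T forced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp


def log_bayes_factor(X, T, K) -> np.ndarray:
    """log Λ_j = (X_j − (T+1)·log K) / 2, vectorised."""
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(X < 0):
        raise ValueError("chi-square statistics must be nonnegative")
    if np.any(np.asarray(K) < 1):
        raise ValueError("K must be a positive study count")
    return (X - (T + 1) * np.log(K)) / 2.0


def bayes_factor(X, T, K) -> np.ndarray:
    """Approximate Bayes factor Λ_j (computed in log space)."""
    return np.exp(log_bayes_factor(X, T, K))


def posterior_inclusion(lambdas=None, log_lambdas=None) -> np.ndarray:
    """PIPs π_j = Λ_j / Σ_i Λ_i within one locus (log-space normalised)."""
    if log_lambdas is None:
        lam = np.asarray(lambdas, dtype=float)
        if lam.size == 0:
            raise ValueError("empty locus")
        if not np.all(np.isfinite(lam)):
            raise ValueError("non-finite Bayes factor")
        log_lambdas = np.log(lam)
    logl = np.asarray(log_lambdas, dtype=float)
    return np.exp(logl - logsumexp(logl))


@dataclass
class CredibleSet:
    """PIP-ranked credible set for one locus."""

    locus: str
    order: np.ndarray  # variant indices ranked by decreasing PIP
    pip: np.ndarray  # PIPs in original variant order
    members: np.ndarray  # ranked indices inside the credible set
    cumulative: float
    level: float

    @property
    def size(self) -> int:
        return len(self.members)


def credible_set(pips: np.ndarray, level: float = 0.90, locus: str = "") -> CredibleSet:
    """Smallest PIP-ranked variant set of cumulative mass ≥ ``level``.

    Variants are ranked by decreasing PIP and included until the
    cumulative mass reaches the level; the threshold-crossing variant is
    included.
    """
    pips = np.asarray(pips, dtype=float)
    if pips.size == 0:
        raise ValueError("empty locus")
    order = np.argsort(-pips, kind="stable")
    cum = np.cumsum(pips[order])
    k = int(np.searchsorted(cum, level - 1e-12)) + 1
    k = min(k, len(pips))
    return CredibleSet(
        locus=locus,
        order=order,
        pip=pips,
        members=order[:k],
        cumulative=float(cum[k - 1]),
        level=level,
    )


# ---------------------------------------------------------------------------
# gene mapping
# ---------------------------------------------------------------------------

def read_gene_annotation(path, fmt: str | None = None) -> pd.DataFrame:
    """Load gene intervals from BED (chrom start end name) or GFF3.

    BED starts are converted to 1-based; GFF3 rows of type ``gene`` are
    used with the gene identifier taken from ID=/gene_id=/Name= attributes.
    Returns a frame with columns chrom, start, end, gene.
    """
    path = str(path)
    if fmt is None:
        fmt = "gff" if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")) else "bed"
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
        )
        df["start"] = df["start"].astype(int) + 1
    else:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "source", "type", "start", "end", "score", "strand",
                   "phase", "attributes"],
        )
        raw = raw[raw["type"] == "gene"]

        def _gid(attrs: str) -> str:
            for fieldname in ("ID", "gene_id", "Name"):
                for part in attrs.split(";"):
                    k, _, v = part.strip().partition("=")
                    if k == fieldname and v:
                        return v
            return attrs
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"].astype(str),
                "start": raw["start"].astype(int),
                "end": raw["end"].astype(int),
                "gene": raw["attributes"].map(_gid),
            }
        )
    df["chrom"] = df["chrom"].astype(str).str.replace(r"^chr", "", regex=True)
    return df.sort_values(["chrom", "start"], ignore_index=True)


def map_nearest_gene(variants: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Nearest gene per variant (closed intervals, 1-based).

    A variant inside a gene body maps to that gene; otherwise to the gene
    whose nearer boundary is closest.  Ties break to the gene with the
    smaller start.  Variants on chromosomes absent from the annotation map
    to NA.
    """
    out = []
    ann_by_chrom = {c: g.sort_values(["start", "end"]) for c, g in annotation.groupby("chrom")}
    for _, v in variants.iterrows():
        chrom = str(v["chrom"])
        pos = int(v["pos"])
        genes = ann_by_chrom.get(chrom)
        if genes is None or genes.empty:
            out.append(pd.NA)
            continue
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        dist = np.where(
            (pos >= start) & (pos <= end),
            0,
            np.minimum(np.abs(pos - start), np.abs(pos - end)),
        )
        best = np.flatnonzero(dist == dist.min())
        # tie rule: smallest start (frame already sorted by start)
        out.append(genes["gene"].iloc[best[0]])
    return pd.Series(out, index=variants.index, name="gene")


def high_priority_genes(
    credible_sets: list[CredibleSet],
    variants: pd.DataFrame,
    annotation: pd.DataFrame,
    max_set_size: int = 4,
) -> set:
    """Genes mapped from variants in credible sets with ≤ ``max_set_size``
    members (the strict reading of "fewer than five variants")."""
    genes: set = set()
    for cs in credible_sets:
        if cs.size <= max_set_size:
            sub = variants.iloc[cs.members]
            genes |= set(map_nearest_gene(sub, annotation).dropna())
    return genes


def control_genes(
    credible_sets: list[CredibleSet],
    variants_per_locus: list[pd.DataFrame],
    annotation: pd.DataFrame,
    pip_threshold: float = 0.01,
) -> set:
    """Genes mapped from low-PIP (< ``pip_threshold``) variants within
    associated loci — the background set for enrichment."""
    genes: set = set()
    for cs, vdf in zip(credible_sets, variants_per_locus):
        low = np.flatnonzero(cs.pip < pip_threshold)
        if low.size:
            genes |= set(map_nearest_gene(vdf.iloc[low], annotation).dropna())
    return genes


def enrichment_relative_risk(
    high_priority: set,
    control: set,
    category: set,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """Relative risk of annotation-category membership, high-priority vs
    control genes, with a 95% bootstrap CI (genes resampled with
    replacement).

    RR = (h_in/h_total)/(c_in/c_total).  A zero control proportion makes
    the RR undefined (NaN point estimate).
    """
    if not high_priority or not control:
        raise ValueError("both gene sets must be nonempty")
    hp = sorted(high_priority)
    ct = sorted(control)
    h_in = np.array([g in category for g in hp], dtype=float)
    c_in = np.array([g in category for g in ct], dtype=float)

    def _rr(h, c):
        ph, pc = h.mean(), c.mean()
        return np.nan if pc == 0 else ph / pc

    point = _rr(h_in, c_in)
    rng = rng if rng is not None else np.random.default_rng()
    boots = []
    for _ in range(n_boot):
        hb = h_in[rng.integers(0, len(hp), len(hp))]
        cb = c_in[rng.integers(0, len(ct), len(ct))]
        boots.append(_rr(hb, cb))
    boots = np.asarray(boots, dtype=float)
    finite = boots[np.isfinite(boots)]
    if finite.size == 0:
        return float(point), (np.nan, np.nan)
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return float(point), (float(lo), float(hi))
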