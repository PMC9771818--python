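"""Synthetic cohorts, LD panels and expression weights for pipeline testing.

The generators emulate the statistical structure the analysis assumes:

* ancestry-cline allele frequencies via the Balding–Nichols model (per
  ancestry a, ``f_ja ~ Beta(f_j(1−F_a)/F_a, (1−f_j)(1−F_a)/F_a)`` around a
  shared base frequency), with per-study frequencies as mixtures over each
  study's ancestry proportions;
* per-study effect estimates drawn from the mixed-effects meta-regression
  generative model ``b_jk = Σ_l C_lk γ_jl + e_jk + ε_jk`` with the
  standardised-trait standard error ``s_jk = 1/sqrt(2 N_k p_jk (1−p_jk)
  R²_jk)``, so analytic power calculations close exactly;
* haplotype reference panels with tunable AR(1) linkage disequilibrium;
* sparse expression-prediction weights for TWAS checks.

Everything is deterministic given a seed; defaults mirror a consortium of
60 cohorts drawn from four continental ancestry clines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .loci import LDPanel
from .summary_io import CohortSummary, MergedVariantTable, VariantRecord
from .twas import TwasWeights


@dataclass
class SimulationConfig:
    """Knobs of the synthetic consortium.

    Defaults describe the emulated study conditions: 60 cohorts spanning
    four ancestry clines with continental-scale differentiation
    (F ≈ 0.1), cohort sizes log-uniform between 1,000 and 50,000,
    imputation quality centred near 0.9, and an AR(1) LD panel.
    """

    seed: int = 0
    n_ancestries: int = 4
    fst: tuple = (0.1, 0.1, 0.1, 0.1)
    n_studies: int = 60
    n_min: int = 1_000
    n_max: int = 50_000
    dirichlet_alpha: float = 0.2  # small → mostly single-ancestry cohorts
    rsq_beta: tuple = (20.0, 2.0)  # imputation quality ~ Beta(20, 2)
    n_variants: int = 1_000
    base_freq_range: tuple = (0.05, 0.95)
    ld_rho: float = 0.7
    panel_size: int = 1_000
    chrom: str = "1"
    pos_start: int = 10_000
    pos_step: int = 1_000

    def __post_init__(self) -> None:
        if len(self.fst) != self.n_ancestries:
            raise ValueError("need one Fst per ancestry")
        if not all(0 < f < 1 for f in self.fst):
            raise ValueError("Fst must be in (0,1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("AR(1) rho must be in [0,1)")

    def positions(self) -> np.ndarray:
        return self.pos_start + self.pos_step * np.arange(self.n_variants)

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions(),
                "ref": "A",
                "alt": "G",
            }
        )


@dataclass
class FreqSet:
    """Base / per-ancestry / per-study allele frequencies plus the true
    study cline positions that generated them."""

    base: np.ndarray  # (J,)
    ancestry: np.ndarray  # (A, J)
    study: np.ndarray  # (K, J)
    proportions: np.ndarray  # (K, A)
    cline: np.ndarray  # (K, 4) raw study positions on the generative axes


@dataclass
class GroundTruth:
    """The generative draw behind a set of cohort summaries."""

    gamma: np.ndarray  # (J, 5) true γ_j0..γ_j4
    tau: np.ndarray  # (J,)
    causal: np.ndarray  # (J,) bool
    C: np.ndarray  # (K, 5) standardized design used for generation
    cline: np.ndarray  # (K, 4)
    proportions: np.ndarray  # (K, A)
    ancestry_maf: np.ndarray  # (A, J)


def _standardize_columns(U: np.ndarray) -> np.ndarray:
    out = np.zeros_like(U, dtype=float)
    for l in range(U.shape[1]):
        col = U[:, l].astype(float)
        sd = col.std()
        out[:, l] = (col - col.mean()) / sd if sd > 0 else 0.0
    return out


def simulate_ancestry_freqs(config: SimulationConfig, rng: np.random.Generator | None = None) -> FreqSet:
    """Draw Balding–Nichols ancestry frequencies and study mixtures.

    Per-study frequencies are the ancestry-proportion-weighted mixture of
    ancestry frequencies, plus a small within-ancestry cline perturbation
    along the fourth generative axis (emulating, for example, a
    north–south gradient inside one continental group).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    J, A, K = config.n_variants, config.n_ancestries, config.n_studies
    lo, hi = config.base_freq_range
    base = rng.uniform(lo, hi, size=J)
    ancestry = np.empty((A, J))
    for a in range(A):
        F = config.fst[a]
        alpha = base * (1 - F) / F
        beta = (1 - base) * (1 - F) / F
        ancestry[a] = rng.beta(alpha, beta)
    proportions = rng.dirichlet(np.full(A, config.dirichlet_alpha), size=K)

    n_prop_axes = min(A - 1, 4)
    cline = np.zeros((K, 4))
    cline[:, :n_prop_axes] = proportions[:, 1 : 1 + n_prop_axes]
    for l in range(n_prop_axes, 4):
        cline[:, l] = rng.uniform(-1.0, 1.0, size=K)

    study = proportions @ ancestry
    # extra-axis frequency gradients so MDS can recover all four axes
    for l in range(n_prop_axes, 4):
        delta = rng.normal(0.0, 0.02, size=J)
        study = study + np.outer(cline[:, l], delta)
    study = np.clip(study, 0.01, 0.99)
    return FreqSet(base=base, ancestry=ancestry, study=study, proportions=proportions, cline=cline)


def true_components(freqs: FreqSet) -> np.ndarray:
    """Intercept + standardised generative cline axes (K × 5)."""
    K = freqs.study.shape[0]
    return np.column_stack([np.ones(K), _standardize_columns(freqs.cline)])


def simulate_cohort_summaries(
    config: SimulationConfig,
    freqs: FreqSet | None = None,
    rng: np.random.Generator | None = None,
    gamma: np.ndarray | None = None,
    tau: np.ndarray | None = None,
    return_merged: bool = False,
):
    """Draw observed per-study effects under the meta-regression model.

    ``gamma`` is (J, 5) of true coefficients on the standardised axes
    (default all zero) and ``tau`` the per-variant heterogeneity SD
    (default zero).  Returns ``(cohorts, truth)`` as a list of
    :class:`CohortSummary`, or ``(merged, truth)`` with a ready
    :class:`MergedVariantTable` when ``return_merged`` (the fast path for
    large simulations, bypassing record objects and re-harmonisation).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if freqs is None:
        freqs = simulate_ancestry_freqs(config, rng)
    J, K = config.n_variants, config.n_studies
    gamma = np.zeros((J, 5)) if gamma is None else np.asarray(gamma, float)
    tau = np.zeros(J) if tau is None else np.asarray(tau, float)

    C = true_components(freqs)
    n_k = np.round(
        np.exp(rng.uniform(np.log(config.n_min), np.log(config.n_max), size=K))
    ).astype(int)
    rsq = rng.beta(*config.rsq_beta, size=(K, J))
    p = freqs.study  # (K, J)
    s = 1.0 / np.sqrt(2.0 * n_k[:, None] * p * (1 - p) * rsq)

    mean = (C @ gamma.T)  # (K, J)
    e = rng.normal(0.0, 1.0, size=(K, J)) * tau[None, :]
    eps = rng.normal(0.0, 1.0, size=(K, J)) * s
    b = mean + e + eps
    z = b / s

    truth = GroundTruth(
        gamma=gamma,
        tau=tau,
        causal=np.any(gamma != 0, axis=1) | (tau > 0),
        C=C,
        cline=freqs.cline,
        proportions=freqs.proportions,
        ancestry_maf=np.minimum(freqs.ancestry, 1 - freqs.ancestry),
    )
    variants = config.variant_frame()
    study_ids = [f"study{k:02d}" for k in range(K)]
    if return_merged:
        pooled = (n_k[:, None] * p).sum(axis=0) / n_k.sum()
        v = variants.copy()
        v["n_studies"] = K
        v["pooled_freq"] = pooled
        v["maf"] = np.minimum(pooled, 1 - pooled)
        v["effective_n"] = (n_k[:, None] * rsq).sum(axis=0)
        merged = MergedVariantTable(
            variants=v,
            study_ids=study_ids,
            n_per_study=n_k.astype(float),
            beta=b.T.copy(),
            se=s.T.copy(),
            z=z.T.copy(),
            freq=p.T.copy(),
            rsq=rsq.T.copy(),
        )
        return merged, truth

    cohorts = []
    for k in range(K):
        records = [
            VariantRecord(
                chrom=str(variants["chrom"].iloc[j]),
                pos=int(variants["pos"].iloc[j]),
                ref=str(variants["ref"].iloc[j]),
                alt=str(variants["alt"].iloc[j]),
                freq=float(p[k, j]),
                beta=float(b[k, j]),
                se=float(s[k, j]),
                z=float(z[k, j]),
                rsq=float(rsq[k, j]),
            )
            for j in range(J)
        ]
        lam = float(np.median(z[k] ** 2) / stats.chi2.ppf(0.5, 1))
        cohorts.append(
            CohortSummary(study_id=study_ids[k], n=int(n_k[k]), lambda_gc=lam, records=records)
        )
    return cohorts, truth


# ---------------------------------------------------------------------------
# LD panels
# ---------------------------------------------------------------------------

def simulate_ld_panel(
    config: SimulationConfig,
    freq: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    ancestry_label: str = "POOL",
    n_samples: int | None = None,
) -> LDPanel:
    """AR(1)-LD haplotype panel: genotypes are sums of two haplotypes
    whose alleles come from a latent Gaussian AR(1) process thresholded at
    each variant's frequency quantile."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    J = config.n_variants
    n = n_samples if n_samples is not None else config.panel_size
    if freq is None:
        lo, hi = config.base_freq_range
        freq = rng.uniform(lo, hi, size=J)
    freq = np.asarray(freq, float)
    rho = config.ld_rho
    thr = stats.norm.ppf(freq)
    haps = np.empty((2 * n, J), dtype=np.int8)
    x = rng.normal(size=2 * n)
    haps[:, 0] = x < thr[0]
    scale = np.sqrt(1 - rho**2)
    for j in range(1, J):
        x = rho * x + scale * rng.normal(size=2 * n)
        haps[:, j] = x < thr[j]
    dosages = (haps[0::2] + haps[1::2]).astype(np.int8)
    return LDPanel(
        dosages=dosages,
        variants=config.variant_frame(),
        ancestry=np.full(n, ancestry_label, dtype=object),
    )


# ---------------------------------------------------------------------------
# locus-level effects with LD (for conditional analysis and fine-mapping)
# ---------------------------------------------------------------------------

def simulate_locus_effects(
    R: np.ndarray,
    causal_index: int,
    ncp_total: float,
    s: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-study effect estimates for one locus with a single causal variant.

    Marginal Z statistics in study k follow ``z_k ~ N(sqrt(ncp_total/K) ·
    R[:, c], R)``, so the causal variant's pooled chi-square has
    noncentrality ``ncp_total`` and non-causal variants inherit signal
    through LD.  ``s`` is the (K, J) matrix of standard errors; returns
    the (K, J) effect-estimate matrix b = z·s.
    """
    K, J = s.shape
    mean = np.sqrt(ncp_total / K) * R[:, causal_index]
    L = np.linalg.cholesky(R + 1e-10 * np.eye(J))
    z = mean[None, :] + rng.normal(size=(K, J)) @ L.T
    return z * s


# ---------------------------------------------------------------------------
# individual-level cohort (for validating summary-based conditional analysis)
# ---------------------------------------------------------------------------

def simulate_individual_gwas(
    G: np.ndarray, beta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Quasi-continuous phenotype y = G·β + N(0,1) noise."""
    G = np.asarray(G, float)
    return G @ np.asarray(beta, float) + rng.normal(size=G.shape[0])


def marginal_summary_stats(G: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per-variant marginal OLS summary statistics (beta, se, z)."""
    G = np.asarray(G, float)
    y = np.asarray(y, float)
    n = len(y)
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    varg = np.sum(Gc**2, axis=0)
    beta = Gc.T @ yc / varg
    resid_var = (np.sum(yc**2) - beta**2 * varg) / (n - 2)
    se = np.sqrt(resid_var / varg)
    return pd.DataFrame({"beta": beta, "se": se, "z": beta / se})


# ---------------------------------------------------------------------------
# expression weights
# ---------------------------------------------------------------------------

def simulate_twas_weights(
    config: SimulationConfig,
    panel: LDPanel,
    n_genes: int = 20,
    tissue: str = "tissue1",
    rng: np.random.Generator | None = None,
    max_variants: int = 10,
) -> list[TwasWeights]:
    """Sparse N(0,1) expression weights on random contiguous variant runs
    (1–``max_variants`` variants per gene)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    keys = panel.variant_keys()
    J = len(keys)
    out = []
    for g in range(n_genes):
        m = int(rng.integers(1, max_variants + 1))
        start = int(rng.integers(0, max(J - m, 1)))
        w = rng.normal(size=m)
        while np.all(w == 0):  # ≥1 nonzero weight required
            w = rng.normal(size=m)
        out.append(
            TwasWeights(
                gene=f"GENE{g:04d}",
                tissue=tissue,
                variant_keys=keys[start : start + m],
                weights=w,
            )
        )
    return out


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def emit(config: SimulationConfig, out_dir, gamma=None, tau=None) -> dict:
    """Simulate one consortium and write per-study TSVs, a panel VCF,
    weight TSVs and a ground-truth JSON under ``out_dir``."""
    import json

    from .summary_io import write_cohort_summary

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    freqs = simulate_ancestry_freqs(config, rng)
    cohorts, truth = simulate_cohort_summaries(config, freqs, rng, gamma=gamma, tau=tau)
    paths = {"cohorts": []}
    for c in cohorts:
        p = out / f"{c.study_id}.tsv"
        write_cohort_summary(c, p)
        paths["cohorts"].append(str(p))
    panel = simulate_ld_panel(config, freq=freqs.base, rng=rng)
    vcf_path = out / "panel.vcf"
    panel.to_vcf(vcf_path)
    paths["panel_vcf"] = str(vcf_path)
    weights = simulate_twas_weights(config, panel, rng=rng)
    wrows = [
        {"gene": w.gene, "variant": k, "weight": wt}
        for w in weights
        for k, wt in zip(w.variant_keys, w.weights)
    ]
    wpath = out / "weights.tsv"
    pd.DataFrame(wrows).to_csv(wpath, sep="\t", index=False)
    paths["weights"] = str(wpath)
    tpath = out / "ground_truth.json"
    with open(tpath, "w") as fh:
        json.dump(
            {
                "gamma": truth.gamma.tolist(),
                "tau": truth.tau.tolist(),
                "causal": truth.causal.astype(bool).tolist(),
                "C": truth.C.tolist(),
            },
            fh,
        )
    paths["ground_truth"] = str(tpath)
    return paths
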