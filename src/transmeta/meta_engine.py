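"""Weighted-Z meta-analysis and mixed-effects ancestry meta-regression.

Two complementary meta-analytic engines operate on the harmonised
variants × studies table:

* the **weighted-Z** combination used for ancestry-stratified scans,
  ``Z_META = Σ_k w_k Z_k / sqrt(Σ_k w_k²)`` with
  ``w_k = sqrt(N_k p_k (1−p_k) R²_k)``, which absorbs differences in
  phenotype scale, imputation quality, allele frequency and sample size;

* the **MEMO** mixed-effects meta-regression used for the multi-ancestry
  scan, ``b_jk = Σ_{l=0}^{L} C_lk γ_jl + e_jk + ε_jk`` with
  ``e_jk ~ N(0, τ²)`` capturing residual heterogeneity and
  ``ε_jk ~ N(0, s²_jk)`` the sampling error.  τ² is estimated by profile
  maximum likelihood, γ by weighted least squares at τ̂², and association
  is tested by a joint Wald chi-square over all L+1 coefficients.  Models
  with 0–4 ancestry components are combined by a Bonferroni minimum-P rule.

A six-component mixture (NULL plus the five meta-regression models)
classifies each variant's evidence of ancestry-moderated effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .summary_io import MergedVariantTable
from .ancestry_axes import AncestryComponents

GENOME_WIDE_P = 5e-9

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# weighted-Z meta-analysis
# ---------------------------------------------------------------------------

def weighted_z_meta(
    z: np.ndarray,
    n: np.ndarray,
    freq: np.ndarray,
    rsq: np.ndarray,
) -> tuple[float, float]:
    """Sample-size/frequency/imputation weighted Z combination for one variant.

    Missing studies (NaN in any input) are ignored.  Returns the combined
    Z and its two-sided normal p-value.  All-zero weights are undefined
    and raise ``ValueError`` (callers skip and log such variants).
    """
    z = np.asarray(z, float)
    n = np.asarray(n, float)
    freq = np.asarray(freq, float)
    rsq = np.asarray(rsq, float)
    ok = ~(np.isnan(z) | np.isnan(n) | np.isnan(freq) | np.isnan(rsq))
    if not ok.any():
        raise ValueError("no studies with complete statistics")
    w = np.sqrt(n[ok] * freq[ok] * (1 - freq[ok]) * rsq[ok])
    denom = np.sqrt(np.sum(w**2))
    if denom == 0:
        raise ValueError("all weights zero")
    zm = float(np.sum(w * z[ok]) / denom)
    return zm, float(2.0 * stats.norm.sf(abs(zm)))


def weighted_z_meta_table(merged: MergedVariantTable) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised weighted-Z scan over a merged table (arrays of Z_META, p)."""
    z = merged.z
    n = np.broadcast_to(merged.n_per_study[None, :], z.shape)
    w = np.sqrt(n * merged.freq * (1 - merged.freq) * merged.rsq)
    w = np.where(np.isnan(z) | np.isnan(w), 0.0, w)
    zz = np.where(np.isnan(z), 0.0, z)
    denom = np.sqrt(np.sum(w**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        zmeta = np.sum(w * zz, axis=1) / denom
    p = 2.0 * stats.norm.sf(np.abs(zmeta))
    return zmeta, p


# ---------------------------------------------------------------------------
# MEMO meta-regression
# ---------------------------------------------------------------------------

@dataclass
class MemoModelFit:
    """One fitted L-component meta-regression for one variant."""

    L: int
    gamma: np.ndarray  # (L+1,)
    cov_gamma: np.ndarray  # (L+1, L+1)
    tau2: float
    X: float  # joint Wald chi-square over all L+1 coefficients
    df: int
    p: float
    loglik: float

    def component_wald_p(self) -> np.ndarray:
        """Per-coefficient two-sided Wald p-values (index 0 = intercept)."""
        se = np.sqrt(np.diag(self.cov_gamma))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.gamma / se
        return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class MemoFit:
    """All fitted sub-models plus the minimum-P combination for one variant."""

    key: str
    n_studies: int
    models: dict[int, MemoModelFit]
    null_loglik: float
    combined_p: float = 1.0
    selected_model: int = 0
    significant: bool = False


def _profile_nll(tau2: float, b: np.ndarray, s2: np.ndarray, C: np.ndarray, reml: bool):
    """Negative profile (restricted) log-likelihood at fixed τ².

    γ is profiled out by weighted least squares either way; with
    ``reml`` the ``log|CᵀWC|`` correction for the estimated fixed effects
    is added, which removes most of the downward bias of the ML τ̂².
    """
    v = s2 + tau2
    w = 1.0 / v
    Cw = C * w[:, None]
    A = C.T @ Cw
    gamma = np.linalg.solve(A, Cw.T @ b)
    r = b - C @ gamma
    nll = 0.5 * (np.sum(np.log(v)) + np.sum(r * r * w) + len(b) * _LOG2PI)
    if reml:
        nll += 0.5 * np.linalg.slogdet(A)[1]
    return nll, gamma, A


def _score_at_zero(b: np.ndarray, s2: np.ndarray, C: np.ndarray, reml: bool) -> float:
    """d/dτ² of the profile (restricted) log-likelihood at τ² = 0."""
    w = 1.0 / s2
    Cw = C * w[:, None]
    A = C.T @ Cw
    gamma = np.linalg.solve(A, Cw.T @ b)
    r = b - C @ gamma
    score = 0.5 * (np.sum(r * r * w * w) - np.sum(w))
    if reml:
        score += 0.5 * np.trace(np.linalg.solve(A, C.T @ (C * (w * w)[:, None])))
    return float(score)


def fit_memo_model(
    b: np.ndarray,
    s: np.ndarray,
    C: np.ndarray,
    L: int,
    tau2: float | None = None,
    tau2_upper: float | None = None,
    method: str = "reml",
) -> MemoModelFit | None:
    """Fit the L-component mixed-effects meta-regression for one variant.

    Parameters
    ----------
    b, s
        Per-study effect estimates and standard errors; NaNs mark studies
        without the variant.
    C
        Studies × (≥L+1) ancestry design (intercept first); only the first
        L+1 columns are used.
    tau2
        If given, τ² is held fixed instead of profiled.
    tau2_upper
        Upper bound of the τ² search (default 100 × median s²).
    method
        ``"reml"`` (default) or ``"ml"`` for the τ² profile criterion.
        The reported ``loglik`` is always the marginal ML log-likelihood
        at the fitted (γ̂, τ̂²), so sub-models remain comparable.

    Returns ``None`` when the variant is observed in too few studies
    (fewer than L+2) or the design over contributing studies is singular.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    reml = method == "reml"
    b = np.asarray(b, float)
    s = np.asarray(s, float)
    ok = ~(np.isnan(b) | np.isnan(s))
    b, s = b[ok], s[ok]
    Cm = np.asarray(C, float)[ok][:, : L + 1]
    K = len(b)
    if K <= L + 1:
        return None
    # collinearity over the contributing studies
    if np.linalg.matrix_rank(Cm) < L + 1:
        return None
    s2 = s * s

    if tau2 is None:
        # gradient of the profile criterion at τ²=0 (envelope theorem):
        # if non-positive, the boundary is the maximum.
        if _score_at_zero(b, s2, Cm, reml) <= 0:
            tau2_hat = 0.0
        else:
            upper = tau2_upper if tau2_upper is not None else 100.0 * float(np.median(s2))
            res = optimize.minimize_scalar(
                lambda t: _profile_nll(t, b, s2, Cm, reml)[0],
                bounds=(0.0, upper),
                method="bounded",
                options={"xatol": max(upper * 1e-8, 1e-14)},
            )
            tau2_hat = float(res.x)
            if _profile_nll(0.0, b, s2, Cm, reml)[0] < _profile_nll(tau2_hat, b, s2, Cm, reml)[0]:
                tau2_hat = 0.0
    else:
        tau2_hat = float(tau2)

    nll, gamma, A = _profile_nll(tau2_hat, b, s2, Cm, reml=False)
    cov = np.linalg.inv(A)
    X = float(gamma @ A @ gamma)
    df = L + 1
    p = float(stats.chi2.sf(X, df))
    return MemoModelFit(
        L=L, gamma=gamma, cov_gamma=cov, tau2=tau2_hat, X=X, df=df, p=p, loglik=-nll
    )


def null_loglik(b: np.ndarray, s: np.ndarray) -> float:
    """Log-likelihood of the no-effect, no-heterogeneity model b ~ N(0, s²)."""
    b = np.asarray(b, float)
    s = np.asarray(s, float)
    ok = ~(np.isnan(b) | np.isnan(s))
    b, s = b[ok], s[ok]
    return float(np.sum(stats.norm.logpdf(b, 0.0, s)))


def memo_scan(
    b: np.ndarray,
    s: np.ndarray,
    C: np.ndarray,
    key: str = "",
    models: Iterable[int] = range(5),
    significance: float = GENOME_WIDE_P,
    method: str = "reml",
) -> MemoFit:
    """Fit all requested component counts and combine by Bonferroni min-P.

    ``combined_p = min(1, M·min_l p_l)`` over the M models that could be
    fitted; ``selected_model`` is the component count achieving the
    minimum P.  The significance flag uses the genome-wide threshold
    P < 5×10⁻⁹ appropriate for scans including low-frequency variants.
    """
    fits: dict[int, MemoModelFit] = {}
    for L in models:
        f = fit_memo_model(b, s, C, L, method=method)
        if f is not None:
            fits[L] = f
    if not fits:
        raise ValueError(f"variant {key!r}: no fittable meta-regression model")
    M = len(fits)
    best_L = min(fits, key=lambda L: (fits[L].p, L))
    combined = min(1.0, M * fits[best_L].p)
    ok = ~(np.isnan(np.asarray(b, float)) | np.isnan(np.asarray(s, float)))
    return MemoFit(
        key=key,
        n_studies=int(ok.sum()),
        models=fits,
        null_loglik=null_loglik(b, s),
        combined_p=combined,
        selected_model=best_L,
        significant=combined < significance,
    )


def memo_scan_table(
    merged: MergedVariantTable,
    components: AncestryComponents,
    models: Iterable[int] = range(5),
) -> list[MemoFit]:
    """Run :func:`memo_scan` over every variant of a merged table."""
    keys = merged.variant_keys().tolist()
    out = []
    for j in range(merged.n_variants):
        out.append(
            memo_scan(merged.beta[j], merged.se[j], components.C, key=keys[j], models=models)
        )
    return out


# ---------------------------------------------------------------------------
# effect-size-moderation mixture
# ---------------------------------------------------------------------------

MIXTURE_LABELS = ("NULL", "MR_0", "MR_1", "MR_2", "MR_3", "MR_4")


@dataclass
class MixtureResult:
    """EM-estimated mixture over the six per-variant sub-models."""

    q: np.ndarray  # (n_variants, 6) posterior over MIXTURE_LABELS
    weight_null: float
    omega: np.ndarray  # (5,) model prior within the alternative
    loglik: float
    converged: bool
    keys: list[str] = field(default_factory=list)

    def selected(self) -> list[str]:
        return [MIXTURE_LABELS[i] for i in np.argmax(self.q, axis=1)]

    def selected_T(self) -> np.ndarray:
        """Component count of the selected model (NULL counted as 0)."""
        idx = np.argmax(self.q, axis=1)
        return np.where(idx == 0, 0, idx - 1)


def _mixture_log_evidence(fits: Sequence[MemoFit]) -> np.ndarray:
    """BIC-style log evidence for NULL and MR_0..MR_4 per variant.

    ``log E_l = loglik_l − ½(l+1)·log K`` mirrors the (T+1)·log K penalty
    of the fine-mapping Bayes factor; the null model has no parameters.
    Unfitted sub-models get −inf.
    """
    n = len(fits)
    logE = np.full((n, 6), -np.inf)
    for i, f in enumerate(fits):
        logK = np.log(max(f.n_studies, 2))
        logE[i, 0] = f.null_loglik
        for L, m in f.models.items():
            logE[i, L + 1] = m.loglik - 0.5 * (L + 1) * logK
    return logE


def fit_heterogeneity_mixture(
    fits: Sequence[MemoFit],
    locus_ids: Sequence | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> MixtureResult:
    """EM fit of the NULL / MR_0..MR_4 mixture across variants.

    The NULL / alternative mixture weight is shared across all variants
    and estimated by EM (initialised at (0.5, 0.5)); within the
    alternative the five meta-regression sub-models carry a uniform prior
    and their per-variant probabilities q follow directly from the
    BIC-approximated evidence.  ``locus_ids`` are accepted for
    bookkeeping; weights are pooled globally.
    """
    logE = _mixture_log_evidence(fits)
    n = logE.shape[0]
    w_null = 0.5
    omega = np.full(5, 0.2)  # uniform within-alternative model prior
    last_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        logw = np.concatenate(([np.log(w_null)], np.log((1 - w_null) * omega + 1e-300)))
        a = logE + logw[None, :]
        amax = np.max(a, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            post = np.exp(a - amax)
        norm = post.sum(axis=1, keepdims=True)
        q = post / norm
        ll = float(np.sum(amax.ravel() + np.log(norm.ravel())))
        w_null = float(np.clip(np.mean(q[:, 0]), 1e-6, 1 - 1e-6))
        if abs(ll - last_ll) < tol:
            converged = True
            last_ll = ll
            break
        last_ll = ll
    return MixtureResult(
        q=q,
        weight_null=w_null,
        omega=omega,
        loglik=last_ll,
        converged=converged,
        keys=[f.key for f in fits],
    )


@dataclass
class HeterogeneityCall:
    """Per-variant ancestry-moderation classification."""

    key: str
    q: np.ndarray  # posterior over MIXTURE_LABELS
    selected: str
    het_class: str  # homogeneous | weak | strong
    moderating_components: list[int]
    polymorphic_ancestries: int


def classify_variant_heterogeneity(
    fit: MemoFit,
    q: np.ndarray,
    maf_by_ancestry: Mapping[str, float] | None = None,
    wald_alpha: float = 0.05 / 4,
    polymorphic_maf: float = 0.01,
) -> HeterogeneityCall:
    """Classify a variant as homogeneous / weakly / strongly heterogeneous.

    Homogeneous when the intercept-only (or null) sub-model has the
    largest posterior.  When a model with ≥1 ancestry component is
    selected the variant is at least weakly heterogeneous; it is strong
    only if some non-intercept coefficient of the selected model is
    significantly non-zero (Wald p below ``wald_alpha``, Bonferroni over
    the four axes) and the variant is polymorphic (MAF above
    ``polymorphic_maf``) in at least two ancestry-stratified datasets.
    """
    idx = int(np.argmax(q))
    selected = MIXTURE_LABELS[idx]
    poly = 0
    if maf_by_ancestry:
        poly = sum(1 for m in maf_by_ancestry.values() if m is not None and m > polymorphic_maf)
    if idx <= 1:
        return HeterogeneityCall(fit.key, q, selected, "homogeneous", [], poly)
    T = idx - 1
    model = fit.models.get(T)
    moderating: list[int] = []
    if model is not None:
        pvals = model.component_wald_p()
        moderating = [l for l in range(1, T + 1) if pvals[l] < wald_alpha]
    het = "strong" if (moderating and poly >= 2) else "weak"
    return HeterogeneityCall(fit.key, q, selected, het, moderating, poly)


# ---------------------------------------------------------------------------
# sign concordance
# ---------------------------------------------------------------------------

def sign_concordance(
    beta_a: np.ndarray, beta_b: np.ndarray
) -> tuple[float, float]:
    """Fraction of shared variants whose effect signs agree, plus a
    binomial test p-value against chance (0.5).  Zero effects and pairs
    with a missing side are excluded; an empty intersection is an error.
    """
    a = np.asarray(beta_a, float)
    b = np.asarray(beta_b, float)
    ok = ~(np.isnan(a) | np.isnan(b)) & (a != 0) & (b != 0)
    if not ok.any():
        raise ValueError("no overlapping non-zero effects")
    agree = np.sign(a[ok]) == np.sign(b[ok])
    n = int(ok.sum())
    k = int(agree.sum())
    pval = stats.binomtest(k, n, 0.5).pvalue
    return k / n, float(pval)
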