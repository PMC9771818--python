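"""Ancestry-aware transcriptome-wide association statistics.

Gene-level association is obtained by projecting per-variant effect
estimates through expression-prediction weights.  For each ancestry
meta-regression model (0–4 MDS components) a burden-style statistic

    z_gene = Σ_i w_i σ_i t_i / sqrt(wᵀ S R S w)

is formed, with w the expression weights, σ_i = sqrt(2·p_i·(1−p_i)) the
variant genotype scales (S = diag σ), R the reference-panel LD matrix and
t_i the variant's standardised effect estimate (β̂_i/se_i) from that
model.  The four component statistics (1–4 axes) are combined per tissue
by a Bonferroni minimum-P rule, tissues are combined per gene by the
Cauchy combination test, and genes are declared significant under a
Bonferroni threshold for the genome-wide gene × tissue search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: p-values are clipped into this open interval before tan() transforms.
P_CLIP = 1e-15


@dataclass
class TwasWeights:
    """Expression-prediction weights for one gene in one tissue."""

    gene: str
    tissue: str
    variant_keys: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.any(self.weights != 0):
            raise ValueError(f"{self.gene}/{self.tissue}: all weights zero")


def read_weights(path, tissue: str | None = None) -> list[TwasWeights]:
    """Read a per-tissue weight TSV with columns gene, variant, weight."""
    df = pd.read_csv(path, sep="\t")
    tis = tissue if tissue is not None else str(path)
    out = []
    for gene, grp in df.groupby("gene"):
        out.append(
            TwasWeights(
                gene=str(gene),
                tissue=tis,
                variant_keys=grp["variant"].astype(str).tolist(),
                weights=grp["weight"].to_numpy(float),
            )
        )
    return out


def twas_component_stats(
    weights: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    freq: np.ndarray,
    R: np.ndarray,
) -> tuple[float, float]:
    """Burden projection of one model's variant effects through weights.

    Parameters are aligned per weighted variant: expression weights,
    effect estimates and SEs from the given meta-regression model, alt
    allele frequencies, and the panel LD correlation submatrix.  Returns
    the gene-level z and its two-sided p.
    """
    w = np.asarray(weights, float)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    freq = np.asarray(freq, float)
    sigma = np.sqrt(2.0 * freq * (1.0 - freq))
    t = beta / se
    ws = w * sigma
    var = float(ws @ np.asarray(R, float) @ ws)
    if var <= 0:
        raise ValueError("non-positive projection variance")
    z = float(np.sum(ws * t) / np.sqrt(var))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def combine_min_p_components(pvals: Sequence[float]) -> float:
    """Bonferroni minimum-P combination over available component models."""
    p = np.asarray([v for v in pvals if np.isfinite(v)], dtype=float)
    if p.size == 0:
        raise ValueError("no component p-values")
    return float(min(1.0, p.size * p.min()))


def cauchy_combine(pvals: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Cauchy combination (ACAT) of p-values, valid under dependence.

    ``T = Σ w_i tan((0.5 − p_i)·π)``; combined ``p = 0.5 − arctan(T)/π``.
    Very small p use the tail-stable approximation tan((0.5−p)π) ≈ 1/(pπ),
    and p at exactly 0/1 are clipped into the open interval (logged).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p >= 1)):
        logger.info("cauchy_combine: clipping %d boundary p-values", int(np.sum((p <= 0) | (p >= 1))))
        p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = w / w.sum()
    small = p < 1e-10
    terms = np.empty_like(p)
    terms[small] = 1.0 / (p[small] * np.pi)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    T = float(np.sum(w * terms))
    if T > 1e10:  # deep tail: arctan underflows; use Cauchy survival tail
        return float(1.0 / (T * np.pi))
    return float(0.5 - np.arctan(T) / np.pi)


def twas_gene_pvalue(
    gene_pvals: Mapping[str, float],
    n_genes: int,
    n_tissues: int,
    alpha: float = 0.05,
) -> tuple[dict[str, bool], float]:
    """Bonferroni significance flags for combined gene p-values.

    The threshold is ``alpha / (n_genes · n_tissues)``, reflecting the
    full gene × tissue search space.
    """
    threshold = alpha / (n_genes * n_tissues)
    return {g: (p < threshold) for g, p in gene_pvals.items()}, threshold


@dataclass
class TwasResult:
    """Per-gene TWAS summary across tissues."""

    gene: str
    tissue_component_p: dict[str, dict[int, float]] = field(default_factory=dict)
    tissue_component_z: dict[str, dict[int, float]] = field(default_factory=dict)
    tissue_p: dict[str, float] = field(default_factory=dict)
    intercept_p: dict[str, float] = field(default_factory=dict)
    combined_p: float = np.nan
    significant: bool = False


def run_twas(
    weight_sets: Sequence[TwasWeights],
    effects: Mapping[int, pd.DataFrame],
    freqs: Mapping[str, float],
    panel,
    n_genes: int | None = None,
    n_tissues: int | None = None,
    alpha: float = 0.05,
) -> list[TwasResult]:
    """Gene-level TWAS over all weight sets.

    ``effects[l]`` is a frame indexed by variant key with columns beta, se
    from the l-component meta-regression (l = 0..4); ``freqs`` maps
    variant keys to pooled alt-allele frequencies; ``panel`` is an
    :class:`~transmeta.loci.LDPanel`.  Component statistics for l = 1..4
    are combined per tissue by min-P (the intercept-only statistic is
    reported separately), tissues are combined per gene by the Cauchy
    test, and significance uses the Bonferroni gene × tissue threshold.
    """
    key_to_col = {k: j for j, k in enumerate(panel.variant_keys())}
    per_gene: dict[str, TwasResult] = {}
    for ws in weight_sets:
        keep = [
            i
            for i, k in enumerate(ws.variant_keys)
            if k in key_to_col and all(k in effects[l].index for l in effects)
        ]
        if not keep:
            logger.info("twas: gene %s/%s has no usable weighted variants", ws.gene, ws.tissue)
            continue
        keys = [ws.variant_keys[i] for i in keep]
        w = ws.weights[keep]
        cols = [key_to_col[k] for k in keys]
        R = panel.corr_submatrix(cols)
        fr = np.array([freqs[k] for k in keys])
        res = per_gene.setdefault(ws.gene, TwasResult(gene=ws.gene))
        comp_p: dict[int, float] = {}
        comp_z: dict[int, float] = {}
        for l, eff in effects.items():
            sub = eff.loc[keys]
            z, p = twas_component_stats(w, sub["beta"].to_numpy(), sub["se"].to_numpy(), fr, R)
            comp_p[l], comp_z[l] = p, z
        res.tissue_component_p[ws.tissue] = comp_p
        res.tissue_component_z[ws.tissue] = comp_z
        if 0 in comp_p:
            res.intercept_p[ws.tissue] = comp_p[0]
        axis_p = [comp_p[l] for l in comp_p if l >= 1]
        res.tissue_p[ws.tissue] = (
            combine_min_p_components(axis_p) if axis_p else comp_p[0]
        )
    results = list(per_gene.values())
    for res in results:
        res.combined_p = cauchy_combine(list(res.tissue_p.values()))
    ng = n_genes if n_genes is not None else len(results)
    nt = n_tissues if n_tissues is not None else max(
        (len(r.tissue_p) for r in results), default=1
    )
    flags, _ = twas_gene_pvalue({r.gene: r.combined_p for r in results}, ng, nt, alpha)
    for res in results:
        res.significant = flags[res.gene]
    return results
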