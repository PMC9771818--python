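"""Between-study allele-frequency distances and MDS ancestry components.

Each contributing study is placed in a low-dimensional ancestry space by
classical (Torgerson) multidimensional scaling of the Euclidean distance
between study allele-frequency vectors, d_kk' = sqrt(Σ_j (f_jk − f_jk')²).
The resulting axes, standardised to mean 0 / SD 1 across studies and
prepended with an intercept column of ones, serve as the covariates of the
mixed-effects meta-regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    pass


@dataclass
class AncestryComponents:
    """Studies × (1+L) design matrix of ancestry covariates.

    The first column is the intercept (all ones); columns 1..L are the MDS
    axes, each standardised to mean 0 and SD 1 across studies.  The sign of
    each axis is fixed by an orientation anchor (by default the study with
    the largest-magnitude raw coordinate is made positive), because the MDS
    sign is otherwise arbitrary and downstream moderation signs must be
    reproducible.
    """

    study_ids: list[str]
    C: np.ndarray  # (K, L+1)
    component_sd: np.ndarray  # (L,) raw-coordinate SDs used to standardise
    orientation_anchors: dict[int, tuple[str, int]] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.C.shape[1] - 1

    def to_frame(self) -> pd.DataFrame:
        cols = {f"C{l}": self.C[:, l] for l in range(1, self.C.shape[1])}
        return pd.DataFrame({"study_id": self.study_ids, **cols})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def pairwise_freq_distance(freqs: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Euclidean distance between study allele-frequency vectors.

    ``freqs`` is studies × variants; missing frequencies (NaN) are handled
    pairwise-complete, with each pair's sum rescaled by the ratio of total
    to shared variant count so that distances remain comparable.
    """
    F = np.asarray(freqs, dtype=float)
    K, J = F.shape
    miss = np.isnan(F)
    if not miss.any():
        sq = np.sum(F**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * F @ F.T
        D = np.sqrt(np.maximum(d2, 0.0))
        np.fill_diagonal(D, 0.0)
        return (D + D.T) / 2.0
    D = np.zeros((K, K))
    for k in range(K):
        for k2 in range(k + 1, K):
            both = ~(miss[k] | miss[k2])
            j_pair = int(both.sum())
            if j_pair == 0:
                raise ValueError(f"studies {k} and {k2} share no variants")
            diff = F[k, both] - F[k2, both]
            d = np.sqrt(np.sum(diff**2) * (J / j_pair))
            D[k, k2] = D[k2, k] = d
    return D


def mds_components(
    D: np.ndarray,
    L: int,
    study_ids: list[str] | None = None,
    orientation_anchors: dict[int, tuple[str, int]] | None = None,
) -> AncestryComponents:
    """Classical MDS of a study distance matrix into L ancestry axes.

    Double-centres −½·D² and takes the top-L eigenvectors scaled by the
    square root of their eigenvalues, then standardises each axis to mean
    0 / SD 1.  Degenerate geometry (a negative leading eigenvalue) is an
    error.
    """
    D = np.asarray(D, dtype=float)
    K = D.shape[0]
    if not 1 <= L <= 4:
        raise ConfigurationError("number of components must be in 1..4")
    if K <= L:
        raise ConfigurationError(f"need more than {L} studies for {L} components")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if study_ids is None:
        study_ids = [f"study{k}" for k in range(K)]

    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if w[0] < -1e-10 * max(1.0, abs(w).max()):
        raise ValueError("degenerate distance matrix: negative leading eigenvalue")
    coords = np.zeros((K, L))
    for l in range(L):
        lam = max(w[l], 0.0)
        coords[:, l] = V[:, l] * np.sqrt(lam)

    anchors: dict[int, tuple[str, int]] = {}
    sds = np.zeros(L)
    C = np.ones((K, L + 1))
    for l in range(L):
        col = coords[:, l]
        if orientation_anchors and (l + 1) in orientation_anchors:
            sid, sign = orientation_anchors[l + 1]
            k_anchor = study_ids.index(sid)
            if col[k_anchor] * sign < 0:
                col = -col
            anchors[l + 1] = (sid, sign)
        else:
            k_anchor = int(np.argmax(np.abs(col)))
            if col[k_anchor] < 0:
                col = -col
            anchors[l + 1] = (study_ids[k_anchor], 1)
        sd = col.std()
        sds[l] = sd
        if sd > 0:
            C[:, l + 1] = (col - col.mean()) / sd
        else:
            C[:, l + 1] = 0.0
    return AncestryComponents(
        study_ids=list(study_ids), C=C, component_sd=sds, orientation_anchors=anchors
    )


def components_from_freqs(
    freqs: np.ndarray | pd.DataFrame,
    L: int = 4,
    study_ids: list[str] | None = None,
    maf_floor: float = 0.05,
) -> AncestryComponents:
    """Convenience path: distance matrix then MDS from a frequency matrix.

    Variants are restricted to those common (MAF > ``maf_floor``) in all
    studies where observed, to keep the distance dominated by genome-wide
    ancestry rather than rare-variant noise.
    """
    F = np.asarray(freqs, dtype=float)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(F, 1 - F)
    common = np.all(np.isnan(F) | (maf > maf_floor), axis=0) & ~np.all(np.isnan(F), axis=0)
    use = F[:, common] if common.any() else F
    return mds_components(pairwise_freq_distance(use), L, study_ids=study_ids)
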