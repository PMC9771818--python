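"""LD reference panels, approximate conditional analysis, locus definition.

Locus discovery proceeds in stages: 1-Mb windows around genome-wide
significant sentinel variants are collapsed; within each window a
sequential forward selection identifies independently associated
variants, with conditional Z-scores computed from summary statistics and
a reference-panel LD matrix; finally each independent variant seeds a
locus spanning all variants in LD (r² > 0.1) with it, and overlapping
loci are collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENOME_WIDE_P = 5e-9

#: ridge added to the diagonal of conditioning correlation matrices before
#: inversion, for stability with finite reference panels.
RIDGE = 1e-3


@dataclass
class LDPanel:
    """Reference genotype dosages with ancestry labels.

    ``dosages`` is samples × variants (values in [0, 2]); ``variants`` has
    columns chrom, pos, ref, alt aligned with the dosage columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    ancestry: np.ndarray  # (n_samples,) string labels

    def __post_init__(self) -> None:
        self.ancestry = np.asarray(self.ancestry)
        if self.dosages.shape[0] != len(self.ancestry):
            raise ValueError("ancestry labels must match sample count")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant table must match dosage columns")
        self._key_index = {
            (c, int(p), r, a): j
            for j, (c, p, r, a) in enumerate(
                zip(
                    self.variants["chrom"].astype(str),
                    self.variants["pos"],
                    self.variants["ref"],
                    self.variants["alt"],
                )
            )
        }

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_keys(self) -> list[str]:
        v = self.variants
        return [
            f"{c}:{p}:{r}:{a}"
            for c, p, r, a in zip(v["chrom"].astype(str), v["pos"], v["ref"], v["alt"])
        ]

    def index_of(self, key: tuple[str, int, str, str]) -> int | None:
        return self._key_index.get(key)

    def corr_submatrix(self, idx: Sequence[int]) -> np.ndarray:
        """Dosage correlation matrix for the requested variant columns."""
        G = self.dosages[:, list(idx)].astype(float)
        R = np.corrcoef(G, rowvar=False)
        if R.ndim == 0:
            R = np.array([[1.0]])
        return np.nan_to_num(R, nan=0.0)

    def r2(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        return float(self.corr_submatrix([i, j])[0, 1] ** 2)

    # -- VCF I/O -----------------------------------------------------------

    @classmethod
    def from_vcf(cls, path, ancestry: Sequence[str] | Mapping[str, str] | None = None) -> "LDPanel":
        """Read a panel from VCF using GT (preferred) or DS fields."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = vcf.samples
        rows = []
        cols = []
        for rec in vcf:
            gts = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown->?, 3 hom-alt
            ds = np.where(gts == 3, 2, np.where(gts == 1, 1, 0)).astype(np.int16)
            cols.append(ds)
            rows.append((str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0]))
        vcf.close()
        dos = np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), np.int16)
        variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        if ancestry is None:
            anc = np.array(["NA"] * len(samples))
        elif isinstance(ancestry, Mapping):
            anc = np.array([ancestry.get(s, "NA") for s in samples])
        else:
            anc = np.asarray(ancestry)
        return cls(dosages=dos, variants=variants, ancestry=anc)

    def to_vcf(self, path) -> None:
        """Write the panel as an uncompressed VCF with diploid GT calls."""
        n = self.n_samples
        names = [f"S{i}" for i in range(n)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(names) + "\n")
            gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
            for j, row in self.variants.iterrows():
                calls = "\t".join(gt_str[int(d)] for d in self.dosages[:, j])
                fh.write(
                    f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{calls}\n"
                )


# ---------------------------------------------------------------------------
# panel pooling
# ---------------------------------------------------------------------------

def allocate_panel_counts(
    available: Mapping[str, int], proportions: Mapping[str, float]
) -> dict[str, int]:
    """Largest feasible per-ancestry sample counts matching requested
    proportions, by largest-remainder rounding.

    The total is the largest T such that the rounded allocation fits the
    available samples of every requested ancestry.
    """
    props = {a: p for a, p in proportions.items() if p > 0}
    total_p = sum(props.values())
    props = {a: p / total_p for a, p in props.items()}
    for a in props:
        if available.get(a, 0) <= 0:
            raise ValueError(f"no reference samples available for ancestry {a!r}")
    T = min(int(np.floor(available[a] / p + 1e-9)) for a, p in props.items())
    while T > 0:
        counts = _largest_remainder(T, props)
        if all(counts[a] <= available[a] for a in props):
            return counts
        T -= 1
    raise ValueError("requested proportions unachievable from available samples")


def _largest_remainder(total: int, props: Mapping[str, float]) -> dict[str, int]:
    raw = {a: total * p for a, p in props.items()}
    counts = {a: int(np.floor(v)) for a, v in raw.items()}
    short = total - sum(counts.values())
    for a in sorted(props, key=lambda a: raw[a] - counts[a], reverse=True)[:short]:
        counts[a] += 1
    return counts


def pool_reference_panels(
    panels: Mapping[str, LDPanel],
    proportions: Mapping[str, float],
    rng: np.random.Generator | None = None,
) -> LDPanel:
    """Combine per-ancestry panels into one matching requested proportions.

    Samples are subsampled (without replacement, first-come when no rng is
    given) so the per-ancestry counts follow largest-remainder rounding of
    the proportions; the pooled size is the sum of the selected
    subsamples.
    """
    first = next(iter(panels.values()))
    for p in panels.values():
        if not p.variants[["chrom", "pos", "ref", "alt"]].equals(
            first.variants[["chrom", "pos", "ref", "alt"]]
        ):
            raise ValueError("panels must share identical variant keys")
    counts = allocate_panel_counts({a: p.n_samples for a, p in panels.items()}, proportions)
    blocks = []
    labels = []
    for a, c in counts.items():
        panel = panels[a]
        idx = np.arange(panel.n_samples)
        if rng is not None and c < panel.n_samples:
            idx = rng.choice(idx, size=c, replace=False)
        else:
            idx = idx[:c]
        blocks.append(panel.dosages[idx])
        labels.append(np.full(c, a, dtype=object))
    return LDPanel(
        dosages=np.concatenate(blocks, axis=0),
        variants=first.variants.copy(),
        ancestry=np.concatenate(labels),
    )


# ---------------------------------------------------------------------------
# windows, forward selection, loci
# ---------------------------------------------------------------------------

def define_windows(
    sentinels: pd.DataFrame, half_width: int = 500_000
) -> pd.DataFrame:
    """±500 kb windows around sentinel variants, overlapping ones merged.

    ``sentinels`` needs columns chrom, pos (and optionally p).  Returns a
    frame with chrom, start, end (1-based closed, floored at 1).
    """
    out = []
    for chrom, grp in sentinels.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        start = None
        end = None
        for p in pos:
            lo, hi = max(1, p - half_width), p + half_width
            if start is None:
                start, end = lo, hi
            elif lo <= end:
                end = max(end, hi)
            else:
                out.append((chrom, start, end))
                start, end = lo, hi
        if start is not None:
            out.append((chrom, start, end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )


def conditional_z(
    z: np.ndarray, R: np.ndarray, selected: Sequence[int], candidate: int, ridge: float = RIDGE
) -> float:
    """Z of ``candidate`` conditional on ``selected`` from summary stats.

    ``z_cond = (z_v − r_vSᵀ R_SS⁻¹ z_S) / sqrt(1 − r_vSᵀ R_SS⁻¹ r_vS)``
    with a ridge on R_SS.  A candidate already in the conditioning set is
    a contract violation and returns 0 (never conditions on itself).
    """
    if candidate in selected:
        return 0.0
    if not selected:
        return float(z[candidate])
    S = list(selected)
    Rss = R[np.ix_(S, S)] + ridge * np.eye(len(S))
    rvS = R[candidate, S]
    sol = np.linalg.solve(Rss, np.column_stack([np.asarray(z)[S], rvS]))
    num = z[candidate] - rvS @ sol[:, 0]
    den2 = 1.0 - rvS @ sol[:, 1]
    if den2 <= 1e-8:
        return 0.0
    return float(num / np.sqrt(den2))


def forward_select_independent(
    z: np.ndarray,
    R: np.ndarray,
    p_threshold: float = GENOME_WIDE_P,
) -> list[int]:
    """Sequential forward selection of independently associated variants.

    Starts from the most significant variant; at each step computes every
    remaining variant's conditional Z given the selected set and adds the
    top signal while its conditional two-sided P stays below
    ``p_threshold``.  Returns indices in selection order (the set ϕ).
    """
    z = np.asarray(z, float)
    m = len(z)
    z_threshold = float(stats.norm.isf(p_threshold / 2.0))
    phi: list[int] = []
    remaining = [j for j in range(m) if np.isfinite(z[j])]
    while remaining:
        zc = np.array([conditional_z(z, R, phi, j) for j in remaining])
        k = int(np.argmax(np.abs(zc)))
        if abs(zc[k]) < z_threshold:
            break
        phi.append(remaining.pop(k))
    return phi


@dataclass
class Locus:
    """A collapsed association locus."""

    chrom: str
    start: int
    end: int
    sentinel: str
    phi: list[str] = field(default_factory=list)
    members: list[str] = field(default_factory=list)


def define_loci(
    phi_idx: Sequence[int],
    panel_idx: Sequence[int],
    variants: pd.DataFrame,
    pvals: np.ndarray,
    R: np.ndarray,
    r2_threshold: float = 0.1,
) -> list[Locus]:
    """Expand independent variants into r²-linked loci and collapse overlaps.

    ``phi_idx`` indexes rows of ``variants`` (which needs chrom, pos and a
    key per row via index); ``panel_idx[i]`` maps variant i to a column of
    the panel correlation matrix ``R`` (or −1 when absent).  Each
    independent variant's members are all variants with r² above the
    threshold against it; loci whose spans overlap are collapsed; the
    sentinel of a collapsed locus is its minimum-p member of ϕ.
    """
    pvals = np.asarray(pvals, float)
    keys = [
        f"{c}:{p}:{r}:{a}"
        for c, p, r, a in zip(
            variants["chrom"].astype(str), variants["pos"], variants["ref"], variants["alt"]
        )
    ]
    raw: list[dict] = []
    for iv in phi_idx:
        pj = panel_idx[iv]
        members = [iv]
        if pj >= 0:
            for j in range(len(variants)):
                qj = panel_idx[j]
                if j != iv and qj >= 0 and R[pj, qj] ** 2 > r2_threshold:
                    members.append(j)
        pos = variants["pos"].to_numpy()[members]
        raw.append(
            {
                "chrom": str(variants["chrom"].iloc[iv]),
                "start": int(pos.min()),
                "end": int(pos.max()),
                "phi": [iv],
                "members": set(members),
            }
        )
    # transitive collapse of overlapping spans per chromosome
    raw.sort(key=lambda d: (d["chrom"], d["start"]))
    collapsed: list[dict] = []
    for loc in raw:
        if (
            collapsed
            and collapsed[-1]["chrom"] == loc["chrom"]
            and loc["start"] <= collapsed[-1]["end"]
        ):
            collapsed[-1]["end"] = max(collapsed[-1]["end"], loc["end"])
            collapsed[-1]["phi"].extend(loc["phi"])
            collapsed[-1]["members"] |= loc["members"]
        else:
            collapsed.append(loc)
    out = []
    for loc in collapsed:
        phi_sorted = sorted(
            loc["phi"], key=lambda j: (pvals[j], variants["pos"].iloc[j], keys[j])
        )
        sentinel = keys[phi_sorted[0]]
        out.append(
            Locus(
                chrom=loc["chrom"],
                start=loc["start"],
                end=loc["end"],
                sentinel=sentinel,
                phi=[keys[j] for j in phi_sorted],
                members=sorted({keys[j] for j in loc["members"]}),
            )
        )
    return out


def loci_to_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    """BED-like summary table of loci."""
    return pd.DataFrame(
        {
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "sentinel": [l.sentinel for l in loci],
            "n_independent": [len(l.phi) for l in loci],
            "n_members": [len(l.members) for l in loci],
        }
    )
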