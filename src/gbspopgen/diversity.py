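"""Per-site and genome-wide diversity statistics and Tajima's D.

Per-site statistics are the minor allele frequency, observed
heterozygosity (fraction of heterozygous calls among non-missing) and
expected heterozygosity 2p(1−p). Tajima's D contrasts mean pairwise
nucleotide diversity θπ with Watterson's θW = S/a1, normalised by the
variance of their difference under the neutral constant-size model:

    D = (θπ − θW) / sqrt(e1·S + e2·S·(S−1))

with the usual constant cascade a1, a2, b1, b2, c1, c2, e1, e2 evaluated
at the number of sequences n (2 × diploid samples). θπ is computed in
allele-frequency form, per site

    π = c_alt (n_k − c_alt) / C(n_k, 2)

with c_alt the alternate-allele count and n_k the non-missing allele
count at site k; summed over sites this equals the average of pairwise
sequence differences exactly (phase never enters a per-site difference
count). Sites with missing calls use their site-specific n_k in both θπ
and the per-site Watterson weight 1/a1(n_k); the variance constants use
the full n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("gbspopgen")


class DiversityError(RuntimeError):
    pass


def site_stats(gm: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant MAF / Ho / He plus genome-wide unweighted means and SDs.

    Returns ``(per_site, summary)``: *per_site* has one row per variant
    (chrom, pos, maf, ho, he); *summary* is a one-row table of the means
    and standard deviations over variants.
    """
    if gm.n_variants == 0 or gm.n_samples == 0:
        raise DiversityError("site_stats requires a non-empty matrix")
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        raise DiversityError("matrix contains all-missing variants; run QC first")
    p = gm.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    ho = ((gm.dosage == 1) & called).sum(axis=0) / n_called
    he = 2 * p * (1 - p)
    per_site = pd.DataFrame(
        {
            "chrom": gm.chroms,
            "pos": gm.positions,
            "maf": maf,
            "ho": ho,
            "he": he,
        }
    )
    summary = pd.DataFrame(
        {
            "n_variants": [gm.n_variants],
            "mean_maf": [maf.mean()],
            "sd_maf": [maf.std(ddof=1) if gm.n_variants > 1 else 0.0],
            "mean_ho": [ho.mean()],
            "sd_ho": [ho.std(ddof=1) if gm.n_variants > 1 else 0.0],
            "mean_he": [he.mean()],
            "sd_he": [he.std(ddof=1) if gm.n_variants > 1 else 0.0],
        }
    )
    return per_site, summary


@dataclass
class TajimaComponents:
    """All quantities behind a Tajima's D value.

    ``d`` is NaN when there are no segregating sites (undefined, not zero).
    """

    n_seq: int
    S: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    theta_w: float
    theta_pi: float
    d: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: [getattr(self, k)] for k in self.__dataclass_fields__})


def tajima_constants(n_seq: int) -> dict[str, float]:
    """Tajima (1989) variance constants for n sequences."""
    if n_seq < 2:
        raise DiversityError(f"need >= 2 sequences, got {n_seq}")
    n = n_seq
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(gm: GenotypeMatrix) -> TajimaComponents:
    """Genome-wide Tajima's D with all components reported.

    Uses every polymorphic site in the matrix as one segregating site.
    With complete data this is the textbook computation; sites with
    missing calls contribute with their own allele count n_k (π weight
    C(n_k,2), Watterson weight 1/a1(n_k)) while the variance constants
    are evaluated at the full 2 × n_samples.
    """
    if gm.n_samples < 2:
        raise DiversityError("tajima_d requires >= 2 samples")
    n_seq = 2 * gm.n_samples
    consts = tajima_constants(n_seq)

    called = gm.dosage != MISSING
    n_k = 2 * called.sum(axis=0)
    c_alt = np.where(called, gm.dosage, 0).sum(axis=0)
    seg = (c_alt > 0) & (c_alt < n_k)
    S = int(seg.sum())

    if S == 0:
        logger.warning("tajima_d: no segregating sites; D is undefined")
        return TajimaComponents(
            n_seq=n_seq, S=0, theta_w=0.0, theta_pi=0.0, d=math.nan, **consts
        )

    nk_seg = n_k[seg].astype(np.float64)
    ca_seg = c_alt[seg].astype(np.float64)
    theta_pi = float(np.sum(ca_seg * (nk_seg - ca_seg) / (nk_seg * (nk_seg - 1) / 2.0)))

    # per-site Watterson weight: 1 / a1(n_k); equals S / a1(n) for complete data
    uniq = np.unique(nk_seg)
    a1_site = {int(u): sum(1.0 / i for i in range(1, int(u))) for u in uniq}
    theta_w = float(np.sum([1.0 / a1_site[int(u)] for u in nk_seg]))

    var = consts["e1"] * S + consts["e2"] * S * (S - 1)
    d = (theta_pi - theta_w) / math.sqrt(var)
    return TajimaComponents(
        n_seq=n_seq, S=S, theta_w=theta_w, theta_pi=theta_pi, d=float(d), **consts
    )


def tajima_d_windows(gm: GenotypeMatrix, window_bp: int) -> pd.DataFrame:
    """Tajima's D in non-overlapping windows of ``window_bp`` per chromosome.

    Windows with no segregating sites report NaN.
    """
    if window_bp <= 0:
        raise DiversityError("window size must be positive")
    chroms = gm.chroms
    positions = gm.positions
    rows = []
    seen: dict[str, None] = {}
    for c in chroms:
        seen.setdefault(c, None)
    for chrom in seen:
        mask = chroms == chrom
        pos = positions[mask]
        idx = np.flatnonzero(mask)
        for start in range(1, int(pos.max()) + 1, window_bp):
            in_win = (pos >= start) & (pos < start + window_bp)
            if not in_win.any():
                continue
            sub = gm.subset_variants(idx[in_win])
            comp = tajima_d(sub)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + window_bp,
                    "n_snps": sub.n_variants,
                    "S": comp.S,
                    "theta_w": comp.theta_w,
                    "theta_pi": comp.theta_pi,
                    "d": comp.d,
                }
            )
    return pd.DataFrame(rows)
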