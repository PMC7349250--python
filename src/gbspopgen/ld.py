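"""Pairwise linkage disequilibrium (r²) and its decay with distance.

Two estimators are provided. The *composite* estimator is the squared
Pearson correlation of allele-dosage vectors (Rogers–Huff), the standard
choice for unphased genotype data. The *phased* estimator counts the four
haplotypes directly and returns

    r² = D² / (P_A P_a P_B P_b),  D = P_AB − P_A P_B,

which equals (P_AB P_ab − P_Ab P_aB)² over the same denominator.

Pair enumeration is within-chromosome by default, with a physical
distance cutoff; decay summaries bin pairs into half-open distance
intervals [lo, hi) and report the pair count, mean and SD of r², and the
fractions exceeding 0.2 and 0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("gbspopgen")


class LDError(RuntimeError):
    pass


#: half-open distance bins (bp) mirroring a 12-interval kb-to-Mb decay layout
DEFAULT_BINS: list[tuple[int, int, str]] = [
    (0, 40_000, "0-40 kb"),
    (40_000, 60_000, "40-60 kb"),
    (60_000, 100_000, "60-100 kb"),
    (100_000, 250_000, "100-250 kb"),
    (250_000, 500_000, "250-500 kb"),
    (500_000, 1_000_000, "0.5-1 Mb"),
    (1_000_000, 2_000_000, "1-2 Mb"),
    (2_000_000, 5_000_000, "2-5 Mb"),
    (5_000_000, 10_000_000, "5-10 Mb"),
    (10_000_000, 20_000_000, "10-20 Mb"),
    (20_000_000, 50_000_000, "20-50 Mb"),
    (50_000_000, 92_000_000, "50-92 Mb"),
]


def pair_r2(
    ga: np.ndarray,
    gb: np.ndarray,
    mode: str = "composite",
) -> float:
    """r² between two sites.

    ``composite`` expects dosage vectors (0/1/2, MISSING allowed) and uses
    pairwise-complete cells; ``phased`` expects haplotype allele vectors
    (0/1, one entry per haplotype). Returns NaN when either site is
    monomorphic on the complete cells or fewer than 3 complete cells remain.
    """
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    if ga.shape != gb.shape:
        raise LDError(f"length mismatch: {ga.shape} vs {gb.shape}")
    if mode == "composite":
        ok = (ga != MISSING) & (gb != MISSING)
        if ok.sum() < 3:
            return float("nan")
        x = ga[ok].astype(float)
        y = gb[ok].astype(float)
        if x.std() == 0 or y.std() == 0:
            return float("nan")
        r = np.corrcoef(x, y)[0, 1]
        return float(r * r)
    if mode == "phased":
        return phased_r2(ga, gb)
    raise LDError(f"unknown mode {mode!r}")


def phased_r2(ha: np.ndarray, hb: np.ndarray) -> float:
    """r² from direct haplotype counting on 0/1 allele vectors."""
    ha = np.asarray(ha, dtype=float)
    hb = np.asarray(hb, dtype=float)
    if ha.shape != hb.shape:
        raise LDError(f"length mismatch: {ha.shape} vs {hb.shape}")
    p_a = ha.mean()
    p_b = hb.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    p_ab = (ha * hb).mean()
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def _pairwise_r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """Composite r² between all site pairs, pairwise-complete over missing.

    ``dosage``: (n_samples, n_sites). Entries where either site has < 3
    complete cells or zero variance are NaN.
    """
    valid = (dosage != MISSING).astype(np.float64)
    x = np.where(dosage == MISSING, 0, dosage).astype(np.float64)
    n = valid.T @ valid
    sx = x.T @ valid  # sx[i, j] = sum of site i over cells complete with j
    sxy = x.T @ x
    sxx = (x * x).T @ valid
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_a = n * sxx - sx**2
        var_b = var_a.T
        r2 = cov**2 / (var_a * var_b)
        r2[(n < 3) | (var_a <= 0) | (var_b <= 0)] = np.nan
    return r2


def collect_pairs(
    gm: GenotypeMatrix,
    max_distance_bp: int | None = None,
    same_chrom_only: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Enumerate within-chromosome SNP pairs with composite r².

    Every unordered pair with ``distance <= max_distance_bp`` appears
    exactly once (``idx_a < idx_b``); pairs with undefined r² are excluded
    and returned as a count.

    Returns ``(pairs, n_undefined)`` where *pairs* has columns chrom,
    idx_a, idx_b, pos_a, pos_b, distance_bp, r2.
    """
    if not same_chrom_only:
        raise LDError("between-chromosome pairs are not supported")
    chroms = gm.chroms
    positions = gm.positions
    frames = []
    n_undefined = 0
    seen: dict[str, None] = {}
    for c in chroms:
        seen.setdefault(c, None)
    for chrom in seen:
        idx = np.flatnonzero(chroms == chrom)
        if idx.size < 2:
            continue
        pos = positions[idx]
        r2 = _pairwise_r2_matrix(gm.dosage[:, idx])
        ia, ib = np.triu_indices(idx.size, k=1)
        dist = pos[ib] - pos[ia]
        if max_distance_bp is not None:
            keep = dist <= max_distance_bp
            ia, ib, dist = ia[keep], ib[keep], dist[keep]
        vals = r2[ia, ib]
        defined = ~np.isnan(vals)
        n_undefined += int((~defined).sum())
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "idx_a": idx[ia[defined]],
                    "idx_b": idx[ib[defined]],
                    "pos_a": pos[ia[defined]],
                    "pos_b": pos[ib[defined]],
                    "distance_bp": dist[defined],
                    "r2": vals[defined],
                }
            )
        )
    if frames:
        pairs = pd.concat(frames, ignore_index=True)
    else:
        pairs = pd.DataFrame(
            columns=["chrom", "idx_a", "idx_b", "pos_a", "pos_b", "distance_bp", "r2"]
        )
    if n_undefined:
        logger.info("collect_pairs: %d pairs with undefined r2 skipped", n_undefined)
    return pairs, n_undefined


@dataclass
class LDBinSummary:
    label: str
    lo_bp: int
    hi_bp: int
    n_pairs: int
    mean_r2: float
    sd_r2: float
    frac_gt_02: float
    frac_gt_03: float
    mean_distance_bp: float


def decay_summary(
    pairs: pd.DataFrame,
    bins: list[tuple[int, int, str]] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Bin pairs by distance and summarise r² per bin.

    Bins are half-open [lo, hi), must be sorted and non-overlapping.
    Pairs falling outside every bin are tallied, never silently dropped.
    SD is the population SD (a single-pair bin reports 0).

    Returns ``(summary, n_unbinned)``.
    """
    if bins is None:
        bins = DEFAULT_BINS
    for (lo1, hi1, _), (lo2, _, _) in zip(bins, bins[1:]):
        if hi1 > lo2 or lo1 >= hi1:
            raise LDError("bins must be sorted and non-overlapping")
    dist = pairs["distance_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    rows = []
    assigned = np.zeros(len(pairs), dtype=bool)
    for lo, hi, label in bins:
        mask = (dist >= lo) & (dist < hi)
        assigned |= mask
        vals = r2[mask]
        rows.append(
            {
                "label": label,
                "lo_bp": lo,
                "hi_bp": hi,
                "n_pairs": int(mask.sum()),
                "mean_r2": float(vals.mean()) if vals.size else float("nan"),
                "sd_r2": float(vals.std(ddof=0)) if vals.size else float("nan"),
                "frac_gt_02": float((vals > 0.2).mean()) if vals.size else float("nan"),
                "frac_gt_03": float((vals > 0.3).mean()) if vals.size else float("nan"),
                "mean_distance_bp": float(dist[mask].mean()) if vals.size else float("nan"),
            }
        )
    n_unbinned = int((~assigned).sum())
    if n_unbinned:
        logger.info("decay_summary: %d pairs outside all bins", n_unbinned)
    return pd.DataFrame(rows), n_unbinned
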