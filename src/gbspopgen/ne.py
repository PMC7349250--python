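"""Historical effective population size from binned LD.

The expectation behind the method is Sved's relation between LD at
recombination fraction c and effective size Ne,

    E[r²] = 1 / (1 + 4 Ne c),

inverted per distance bin after a mutation correction α and an optional
sample-size adjustment r²_adj = r² − 1/(βn):

    N_t = (1 / r²_adj − α) / (4 c),   t = 1 / (2 c) generations ago,

with c obtained from the bin's mean physical distance through a mapping
function (linear at a constant Morgans-per-bp rate by default, Haldane or
Kosambi alternatives). α = 1 is the pure-drift form (the exact algebraic
inverse of Sved's relation), α = 2 or 2.2 corrects for mutation; β = 2
when gametic phase is known and 1 otherwise.

Bins are reported from most recent (largest distance, smallest c) to
oldest. Bins whose adjusted r² or resulting N_t is non-positive are
dropped with a warning rather than clamped — clamping fabricates history.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gbspopgen")


class NeError(RuntimeError):
    pass


@dataclass
class NeConfig:
    """Settings for LD-based Ne estimation.

    alpha
        Mutation correction, one of {1, 2, 2.2}.
    beta
        Phase factor: 2 for phased data, 1 for unphased.
    n_samples
        Number of individuals sampled (for the 1/(βn) adjustment).
    mapping
        Physical-to-genetic mapping: "linear", "haldane" or "kosambi".
    rec_rate_per_bp
        Morgans per bp (default 1e-8, i.e. 1 cM/Mb).
    apply_sample_adjustment
        Subtract 1/(βn) from each bin's mean r² before inversion.
    min_pairs
        Bins with fewer pairs are skipped.
    """

    alpha: float = 2.0
    beta: int = 1
    n_samples: int = 0
    mapping: str = "linear"
    rec_rate_per_bp: float = 1e-8
    apply_sample_adjustment: bool = True
    min_pairs: int = 50

    def __post_init__(self) -> None:
        if self.alpha not in (1, 2, 2.2):
            raise NeError(f"alpha must be one of 1, 2, 2.2; got {self.alpha}")
        if self.beta not in (1, 2):
            raise NeError(f"beta must be 1 or 2; got {self.beta}")
        if self.rec_rate_per_bp <= 0:
            raise NeError("rec_rate_per_bp must be positive")
        if self.mapping not in ("linear", "haldane", "kosambi"):
            raise NeError(f"unknown mapping {self.mapping!r}")
        if self.apply_sample_adjustment and self.n_samples < 2:
            raise NeError("sample adjustment requires n_samples >= 2")


def expected_r2(ne: float, c: float) -> float:
    """Sved's expectation 1/(1 + 4·Ne·c)."""
    if ne <= 0 or not 0 < c <= 0.5:
        raise NeError(f"need ne > 0 and 0 < c <= 0.5, got ne={ne}, c={c}")
    return 1.0 / (1.0 + 4.0 * ne * c)


def adjust_r2(r2: float, cfg: NeConfig) -> float:
    """Sample-size-adjusted r²; may be negative (caller excludes such bins)."""
    if not 0 <= r2 <= 1:
        raise NeError(f"r2 must be in [0, 1], got {r2}")
    if not cfg.apply_sample_adjustment:
        return r2
    return r2 - 1.0 / (cfg.beta * cfg.n_samples)


def genetic_distance(distance_bp: float, cfg: NeConfig) -> float:
    """Recombination fraction c for a physical distance, via cfg.mapping."""
    if distance_bp <= 0:
        raise NeError(f"distance must be positive, got {distance_bp}")
    d = distance_bp * cfg.rec_rate_per_bp  # Morgans
    if cfg.mapping == "linear":
        return min(d, 0.5)
    if cfg.mapping == "haldane":
        return 0.5 * (1.0 - math.exp(-2.0 * d))
    # kosambi
    return 0.5 * math.tanh(2.0 * d)


def estimate_ne_trajectory(
    bins: pd.DataFrame,
    cfg: NeConfig,
) -> pd.DataFrame:
    """Per-bin Ne estimates from a table of LD bin summaries.

    ``bins`` needs columns mean_distance_bp, mean_r2, n_pairs and
    optionally sd_r2. Output columns: t_generations (1/(2c), 2 decimals),
    t_rounded (nearest integer, half-to-even), nt, mean_distance_bp, c,
    mean_r2, r2_adj, sd_r2, n_pairs — ordered most recent first (largest
    distance). Bins with too few pairs, non-positive adjusted r², or
    non-positive Ne are excluded with a warning.
    """
    required = {"mean_distance_bp", "mean_r2", "n_pairs"}
    if not required.issubset(bins.columns):
        raise NeError(f"bins table must have columns {sorted(required)}")
    rows = []
    for rec in bins.itertuples(index=False):
        if rec.n_pairs < cfg.min_pairs:
            logger.warning(
                "ne: bin at %.0f bp has %d pairs < min_pairs=%d; skipped",
                rec.mean_distance_bp, rec.n_pairs, cfg.min_pairs,
            )
            continue
        if np.isnan(rec.mean_r2):
            continue
        c = genetic_distance(rec.mean_distance_bp, cfg)
        r2_adj = adjust_r2(float(rec.mean_r2), cfg)
        if r2_adj <= 0:
            logger.warning(
                "ne: bin at %.0f bp has adjusted r2 %.4g <= 0; excluded",
                rec.mean_distance_bp, r2_adj,
            )
            continue
        nt = (1.0 / r2_adj - cfg.alpha) / (4.0 * c)
        if nt <= 0:
            logger.warning(
                "ne: bin at %.0f bp yields Ne %.4g <= 0; excluded",
                rec.mean_distance_bp, nt,
            )
            continue
        t = 1.0 / (2.0 * c)
        rows.append(
            {
                "t_generations": round(t, 2),
                "t_rounded": int(np.round(t)),  # half-to-even
                "nt": nt,
                "mean_distance_bp": float(rec.mean_distance_bp),
                "c": c,
                "mean_r2": float(rec.mean_r2),
                "r2_adj": r2_adj,
                "sd_r2": float(getattr(rec, "sd_r2", float("nan"))),
                "n_pairs": int(rec.n_pairs),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("mean_distance_bp", ascending=False).reset_index(drop=True)
    return out


def equal_count_bins(
    pairs: pd.DataFrame,
    n_bins: int = 20,
    min_bp: int = 40_000,
    max_bp: int = 20_000_000,
) -> pd.DataFrame:
    """Bin raw LD pairs into ~equal-count distance bins for Ne estimation.

    The short-range floor (default 40 kb) dodges strong-LD ascertainment;
    the output table feeds :func:`estimate_ne_trajectory` directly.
    """
    if n_bins < 1:
        raise NeError("n_bins must be >= 1")
    sel = pairs[(pairs["distance_bp"] >= min_bp) & (pairs["distance_bp"] < max_bp)]
    if sel.empty:
        return pd.DataFrame(
            columns=["mean_distance_bp", "mean_r2", "sd_r2", "n_pairs"]
        )
    dist = sel["distance_bp"].to_numpy()
    r2 = sel["r2"].to_numpy()
    order = np.argsort(dist)
    dist, r2 = dist[order], r2[order]
    edges = np.array_split(np.arange(dist.size), min(n_bins, dist.size))
    rows = []
    for idx in edges:
        if idx.size == 0:
            continue
        rows.append(
            {
                "mean_distance_bp": float(dist[idx].mean()),
                "mean_r2": float(r2[idx].mean()),
                "sd_r2": float(r2[idx].std(ddof=0)),
                "n_pairs": int(idx.size),
            }
        )
    return pd.DataFrame(rows)
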