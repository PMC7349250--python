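"""Population differentiation, genomic relatedness and PCA.

Differentiation uses the Weir–Cockerham (1984) θ estimator of FST,
combining loci as a ratio of summed variance components (a: among
populations, b: among individuals within populations, c: within
individuals), and Nei's (1972) standard genetic distance
D = −ln(J_xy / sqrt(J_x J_y)). Relatedness is the unadjusted Yang et al.
A_jk statistic (the off-diagonal of the SNP genetic-relationship matrix,
allele frequencies taken from the sample itself). PCA operates on the
column-standardised dosage matrix with per-site mean imputation of
missing calls.

Negative multi-locus θ values are reported as computed, not clamped:
weakly differentiated populations sit at the estimator's noise floor and
clamping would bias comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger("gbspopgen")


class StructureError(RuntimeError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric between-population matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise StructureError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=True):
            raise StructureError("distance matrix diagonal must be zero")
        if not np.allclose(
            self.values, self.values.T, equal_nan=True, atol=1e-12
        ):
            raise StructureError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_nexus(self) -> str:
        """NEXUS DISTANCES block (for SplitsTree-style network tools)."""
        n = len(self.labels)
        lines = [
            "#NEXUS",
            "BEGIN TAXA;",
            f"  DIMENSIONS NTAX={n};",
            "  TAXLABELS " + " ".join(self.labels) + ";",
            "END;",
            "BEGIN DISTANCES;",
            f"  DIMENSIONS NTAX={n};",
            "  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;",
            "  MATRIX",
        ]
        for label, row in zip(self.labels, self.values):
            lines.append("    " + label + " " + " ".join(f"{v:.6g}" for v in row))
        lines += ["  ;", "END;", ""]
        return "\n".join(lines)


def _pop_groups(gm: GenotypeMatrix, pm: PopulationMap) -> dict[str, np.ndarray]:
    pm.validate_against(gm)
    index = {s: i for i, s in enumerate(gm.sample_ids)}
    groups: dict[str, np.ndarray] = {}
    for pop in pm.populations():
        rows = np.array([index[s] for s in pm.samples_in(pop)], dtype=int)
        if rows.size < 2:
            raise StructureError(f"population {pop!r} has < 2 samples")
        groups[pop] = rows
    if len(groups) < 2:
        raise StructureError("need >= 2 populations")
    return groups


def wc_fst_components(
    gm: GenotypeMatrix, rows_by_pop: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components a, b, c.

    ``rows_by_pop`` lists the sample-row indices of each population.
    Loci where any population has zero calls contribute zeros.
    """
    r = len(rows_by_pop)
    if r < 2:
        raise StructureError("need >= 2 populations")
    n_i = []  # called diploid counts per pop per locus
    p_i = []  # alt-allele frequency per pop per locus
    h_i = []  # observed heterozygote proportion per pop per locus
    for rows in rows_by_pop:
        d = gm.dosage[rows]
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, d, 0).sum(axis=0) / (2 * n)
            h = ((d == 1) & called).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)  # (r, loci)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    usable = (n_i > 0).all(axis=0)
    n_i = np.where(usable, n_i, 1.0)  # placeholder; zeroed below

    n_bar = n_i.mean(axis=0)
    n_total = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_total - (n_i**2).sum(axis=0) / n_total) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_total
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_total

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    bad = ~usable | ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    for arr in (a, b, c):
        arr[bad] = 0.0
    return a, b, c


def pairwise_fst(gm: GenotypeMatrix, pm: PopulationMap) -> DistanceMatrix:
    """Pairwise multi-locus Weir–Cockerham θ between all populations.

    θ for each pair is Σa / Σ(a+b+c) over loci polymorphic in the pooled
    pair; a pair with no polymorphic shared sites gets NaN (flagged).
    """
    groups = _pop_groups(gm, pm)
    labels = list(groups)
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b, c = wc_fst_components(gm, [groups[labels[i]], groups[labels[j]]])
            denom = (a + b + c).sum()
            if denom == 0:
                logger.warning(
                    "fst: no usable polymorphic sites for %s vs %s",
                    labels[i], labels[j],
                )
                theta = float("nan")
            else:
                theta = float(a.sum() / denom)
            values[i, j] = values[j, i] = theta
    return DistanceMatrix(labels, values, metric="wc_fst")


def nei_distance(gm: GenotypeMatrix, pm: PopulationMap) -> DistanceMatrix:
    """Nei's (1972) standard distance between all population pairs."""
    groups = _pop_groups(gm, pm)
    labels = list(groups)
    freqs = {}
    for pop, rows in groups.items():
        d = gm.dosage[rows]
        called = d != MISSING
        n = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(n > 0, np.where(called, d, 0).sum(axis=0) / n, np.nan)
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p1, p2 = freqs[labels[i]], freqs[labels[j]]
            ok = ~np.isnan(p1) & ~np.isnan(p2)
            if not ok.any():
                values[i, j] = values[j, i] = float("nan")
                continue
            p1o, p2o = p1[ok], p2[ok]
            # J terms averaged over loci, summed over the two alleles
            j_x = np.mean(p1o**2 + (1 - p1o) ** 2)
            j_y = np.mean(p2o**2 + (1 - p2o) ** 2)
            j_xy = np.mean(p1o * p2o + (1 - p1o) * (1 - p2o))
            d = -np.log(j_xy / np.sqrt(j_x * j_y))
            values[i, j] = values[j, i] = float(d)
    return DistanceMatrix(labels, values, metric="nei_1972")


@dataclass
class RelatednessMatrix:
    """Symmetric sample × sample A_jk matrix; NaN marks flagged pairs."""

    sample_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]


def ajk_matrix(gm: GenotypeMatrix, min_sites: int = 100) -> RelatednessMatrix:
    """Unadjusted Yang A_jk genomic relationship matrix.

    Allele frequencies come from the matrix itself; sites fixed in the
    sample (p ∈ {0, 1}) are excluded. Off-diagonal entries average
    (x_j − 2p)(x_k − 2p) / (2p(1−p)) over pairwise-complete sites; the
    diagonal uses (x² − (1+2p)x + 2p²) / (2p(1−p)). Pairs with fewer than
    ``min_sites`` usable sites are flagged NaN.
    """
    p = gm.allele_frequencies()
    use = ~np.isnan(p) & (p > 0) & (p < 1)
    if not use.any():
        raise StructureError("no polymorphic sites for relatedness")
    x = gm.dosage[:, use].astype(float)
    pu = p[use]
    valid = (x != MISSING).astype(float)
    denom = 2.0 * pu * (1.0 - pu)

    z = np.where(x == MISSING, 0.0, x - 2.0 * pu) / np.sqrt(denom)
    z *= valid  # missing cells contribute 0
    numer = z @ z.T
    m = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        a = numer / m
    a[m < min_sites] = np.nan

    # diagonal: self-term, not the squared-deviation form
    diag_terms = np.where(
        valid > 0,
        (x**2 - (1.0 + 2.0 * pu) * x + 2.0 * pu**2) / denom,
        0.0,
    )
    m_self = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = diag_terms.sum(axis=1) / m_self
    diag[m_self < min_sites] = np.nan
    np.fill_diagonal(a, diag)
    return RelatednessMatrix(list(gm.sample_ids), a)


@dataclass
class PcaCoordinates:
    sample_ids: list[str]
    coords: np.ndarray  # (n_samples, n_axes)
    variance_fractions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=cols)


def pca_coords(gm: GenotypeMatrix, n_axes: int = 10) -> PcaCoordinates:
    """PCA of the column-standardised dosage matrix.

    Missing dosages are mean-imputed per site for the decomposition only;
    constant sites are dropped. ``n_axes`` is truncated (with a warning)
    to what the matrix supports.
    """
    from sklearn.decomposition import PCA

    x = gm.dosage.astype(float)
    x[x == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mu, inds[1])
    sd = x.std(axis=0)
    keep = sd > 0
    x = (x[:, keep] - mu[keep]) / sd[keep]

    max_axes = min(gm.n_samples, int(keep.sum()))
    if n_axes > max_axes:
        logger.warning("pca: n_axes truncated from %d to %d", n_axes, max_axes)
        n_axes = max_axes
    pca = PCA(n_components=n_axes, svd_solver="full")
    coords = pca.fit_transform(x)
    return PcaCoordinates(
        list(gm.sample_ids), coords, pca.explained_variance_ratio_.copy()
    )
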