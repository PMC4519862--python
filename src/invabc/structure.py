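"""Population structure: AMOVA, great-circle distances, Mantel / IBD tests.

AMOVA follows the Excoffier (1992) squared-distance partition with the
pairwise-difference count between haplotypic sequences playing the role of
the squared Euclidean distance, the default for sequence data in the
standard AMOVA framework.  Permutation p-values count the observed statistic
in both numerator and denominator so they are never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import pairwise_difference_matrix
from .seq_io import Alignment, InputError, PopulationMap

EARTH_RADIUS_KM = 6371.0


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    SSD_among: float
    SSD_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    Phi_ST: float
    p_value: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.Phi_ST)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among_populations", "within_populations"],
                "df": [self.df_among, self.df_within],
                "SSD": [self.SSD_among, self.SSD_within],
                "variance_component": [self.sigma2_among, self.sigma2_within],
                "pct_variation": [self.pct_among, self.pct_within],
                "Phi_ST": [self.Phi_ST, math.nan],
                "p_value": [self.p_value, math.nan],
            }
        )


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    two_sided: bool


def _amova_components(
    d2: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float, int, int]:
    """Variance components from a squared-distance matrix and labels.

    Returns (SSD_among, SSD_within, sigma2_among, sigma2_within, df_a, df_w).
    """
    n = d2.shape[0]
    pops, inverse = np.unique(labels, return_inverse=True)
    P = len(pops)
    iu = np.triu_indices(n, 1)
    ssd_total = float(d2[iu].sum()) / n
    ssd_within = 0.0
    sizes = np.zeros(P)
    for p in range(P):
        idx = np.flatnonzero(inverse == p)
        sizes[p] = idx.size
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ssd_within += float(sub[np.triu_indices(idx.size, 1)].sum()) / idx.size
    ssd_among = ssd_total - ssd_within
    df_a, df_w = P - 1, n - P
    sigma2_w = ssd_within / df_w if df_w > 0 else math.nan
    n_c = (n - float(np.sum(sizes**2)) / n) / df_a
    msd_a = ssd_among / df_a
    sigma2_a = (msd_a - sigma2_w) / n_c
    return ssd_among, ssd_within, sigma2_a, sigma2_w, df_a, df_w


def amova_two_level(
    aln: Alignment,
    popmap: PopulationMap,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> AmovaResult:
    """Two-level AMOVA (among vs within populations) on sequence data.

    The squared distance between two sequences is their pairwise difference
    count at complete sites.  The significance of Phi_ST is assessed by
    permuting individuals among populations.
    """
    popmap.check_alignment(aln)
    labels = np.array([popmap.population_of(s) for s in aln.sample_ids])
    pops, counts = np.unique(labels, return_counts=True)
    if len(pops) < 2:
        raise InputError("AMOVA needs at least two populations")
    if not np.any(counts >= 2):
        raise InputError("AMOVA needs at least one population with >= 2 sequences")
    d2 = pairwise_difference_matrix(aln).astype(float)

    ssd_a, ssd_w, s2a, s2w, df_a, df_w = _amova_components(d2, labels)
    total_var = s2a + s2w
    if total_var <= 0 or np.all(d2 == 0):
        return AmovaResult(
            df_among=df_a, df_within=df_w, SSD_among=ssd_a, SSD_within=ssd_w,
            sigma2_among=s2a, sigma2_within=s2w,
            pct_among=math.nan, pct_within=math.nan,
            Phi_ST=math.nan, p_value=math.nan,
        )
    phi = s2a / total_var

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, _, pa, pw, _, _ = _amova_components(d2, perm)
        tot = pa + pw
        phi_p = pa / tot if tot > 0 else -math.inf
        if phi_p >= phi:
            hits += 1
    p = hits / (n_perm + 1)
    return AmovaResult(
        df_among=df_a, df_within=df_w, SSD_among=ssd_a, SSD_within=ssd_w,
        sigma2_among=s2a, sigma2_within=s2w,
        pct_among=100.0 * s2a / total_var, pct_within=100.0 * s2w / total_var,
        Phi_ST=float(phi), p_value=float(p),
    )


def pairwise_phi_st(aln: Alignment, popmap: PopulationMap) -> pd.DataFrame:
    """Matrix of pairwise Phi_ST between all population pairs.

    Each entry is the Phi_ST of a two-population AMOVA on that pair alone
    (no permutations).  Pairs with zero total variance get Phi_ST = 0.
    Negative method-of-moments estimates are reported as computed.
    """
    popmap.check_alignment(aln)
    labels = np.array([popmap.population_of(s) for s in aln.sample_ids])
    pops = [p for p in popmap.populations if p in set(labels)]
    d2 = pairwise_difference_matrix(aln).astype(float)
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            idx = np.flatnonzero((labels == a) | (labels == b))
            sub = d2[np.ix_(idx, idx)]
            _, _, s2a, s2w, _, _ = _amova_components(sub, labels[idx])
            tot = s2a + s2w
            phi = s2a / tot if tot > 0 else 0.0
            out.loc[a, b] = out.loc[b, a] = phi
    return out


def geographic_distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Great-circle (haversine) distances in km between populations.

    ``coords`` is indexed by population with columns ``latitude_deg`` and
    ``longitude_deg`` (signed decimal degrees).
    """
    lat = coords["latitude_deg"].to_numpy(dtype=float)
    lon = coords["longitude_deg"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90):
        raise InputError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise InputError("longitude outside [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


def mantel_test(
    gen_matrix,
    geo_matrix,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = 0,
    two_sided: bool = True,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel correlation between two symmetric distance matrices.

    ``r`` is the Pearson correlation of the upper-triangle entries; ``p`` is
    the proportion of joint row/column permutations of the second matrix
    whose statistic is as extreme as the observed (|r| for the two-sided
    test, r for the one-sided greater test), counting the observed
    permutation itself.  With ``exhaustive=True`` all n! permutations are
    enumerated instead of sampling (small matrices only) and the identity
    permutation plays the role of the observed draw.
    """
    A = np.asarray(gen_matrix, dtype=float)
    B = np.asarray(geo_matrix, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise InputError("Mantel matrices must be square and of equal order")
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    a = A[iu]
    if a.std() == 0 or B[iu].std() == 0:
        return MantelResult(r=math.nan, p=math.nan, n_perm=n_perm,
                            two_sided=two_sided)

    def corr(mat: np.ndarray) -> float:
        return float(np.corrcoef(a, mat[iu])[0, 1])

    r_obs = corr(B)

    def extreme(r_p: float) -> bool:
        if two_sided:
            return abs(r_p) >= abs(r_obs) - 1e-12
        return r_p >= r_obs - 1e-12

    if exhaustive:
        from itertools import permutations

        hits = total = 0
        for order in permutations(range(n)):
            idx = np.asarray(order)
            total += 1
            if extreme(corr(B[np.ix_(idx, idx)])):
                hits += 1
        return MantelResult(r=r_obs, p=hits / total, n_perm=total,
                            two_sided=two_sided)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        order = rng.permutation(n)
        if extreme(corr(B[np.ix_(order, order)])):
            hits += 1
    return MantelResult(
        r=r_obs, p=hits / (n_perm + 1), n_perm=n_perm, two_sided=two_sided
    )


def isolation_by_distance(
    aln: Alignment,
    popmap: PopulationMap,
    coords: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MantelResult:
    """IBD test: pairwise Phi_ST vs great-circle distance, Mantel permutation.

    The genetic matrix is pairwise-population Phi_ST (a distance-like
    dissimilarity), so a positive r indicates isolation by distance.
    """
    gen = pairwise_phi_st(aln, popmap)
    missing = [p for p in gen.index if p not in coords.index]
    if missing:
        raise InputError(f"populations without coordinates: {missing}")
    geo = geographic_distance_matrix(coords.loc[gen.index])
    return mantel_test(gen.to_numpy(), geo.to_numpy(), n_perm=n_perm, seed=seed)
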