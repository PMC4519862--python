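"""Diversity statistics and neutrality tests on sequence alignments.

All statistics use complete deletion: columns containing a gap or ``N`` in
any sequence are removed before anything is counted, consistently with the
haplotype-identity rule in :mod:`invabc.seq_io`.  Mean pairwise differences
``k`` average over all C(n,2) sequence pairs; per-site nucleotide diversity
is ``pi = k / (number of complete sites)`` with no extra n/(n-1) factor
beyond the pair average (the pair average is already an unbiased estimator
of heterozygosity per pair).

Neutrality statistics follow the standard frequency-spectrum formulations:
Tajima's D contrasts pairwise diversity with Watterson's estimator; Fu &
Li's D* (no outgroup) contrasts total mutations with singletons; Fu's Fs is
built on the Ewens sampling formula via unsigned Stirling numbers of the
first kind, with a coalescent-simulation p-value.  Statistics that are
undefined for the input (e.g. no segregating sites) return ``nan`` and are
flagged in the report containers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_io import Alignment, HaplotypeTable, PopulationMap, collapse_haplotypes

DISTANCE_MODELS = ("p", "JC69", "K2P", "MCL")

_PURINES = (ord("A"), ord("G"))
_PYRIMIDINES = (ord("C"), ord("T"))


@dataclass
class DiversityReport:
    n: int
    H: int
    Hd: float
    var_Hd: float
    sd_Hd: float
    pi: float
    k: float
    S: int


@dataclass
class NeutralityReport:
    tajima_D: float
    fu_li_Dstar: float
    fu_Fs: float
    p_Fs: float

    @property
    def tajima_D_defined(self) -> bool:
        return not math.isnan(self.tajima_D)

    @property
    def fu_li_Dstar_defined(self) -> bool:
        return not math.isnan(self.fu_li_Dstar)

    @property
    def fu_Fs_defined(self) -> bool:
        return not math.isnan(self.fu_Fs)


@dataclass
class DistanceMatrix:
    model: str
    entries: np.ndarray      # symmetric, zero diagonal; nan = saturated
    mean: float              # mean of defined off-diagonal upper-triangle


# ---------------------------------------------------------------------------
# basic within-sample statistics


def haplotype_diversity(counts, n: int | None = None):
    """Haplotype (gene) diversity with its sampling variance.

    ``Hd = n (1 - sum p_i^2) / (n - 1)`` and the variance follows Nei's
    (1987) sampling formula

    ``Var = 2/(n(n-1)) [ 2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2 ]``.

    Returns ``(Hd, var_Hd, sd_Hd)``; all nan when ``n < 2``.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if n is None:
        n = int(total)
    if total != n:
        raise ValueError(f"counts sum to {total}, expected n={n}")
    if n < 2:
        return (math.nan, math.nan, math.nan)
    p = counts / n
    sp2 = float(np.sum(p**2))
    sp3 = float(np.sum(p**3))
    hd = n * (1.0 - sp2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sp3 - sp2**2) + sp2 - sp2**2
    )
    var = max(var, 0.0)
    return (hd, var, math.sqrt(var))


def pairwise_difference_matrix(aln: Alignment) -> np.ndarray:
    """Counts of differing complete sites for every sequence pair."""
    core = aln.matrix()[:, aln.complete_sites()]
    n = aln.n
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i, i + 1:] = np.sum(core[i + 1:] != core[i], axis=1)
    return d + d.T


def nucleotide_diversity(aln: Alignment) -> tuple[float, float]:
    """Return ``(pi, k)``: per-site diversity and mean pairwise differences."""
    if aln.n < 2:
        return (math.nan, math.nan)
    d = pairwise_difference_matrix(aln)
    n = aln.n
    k = d[np.triu_indices(n, 1)].mean()
    n_sites = int(aln.complete_sites().sum())
    pi = k / n_sites if n_sites else math.nan
    return (float(pi), float(k))


def segregating_sites(aln: Alignment) -> int:
    """Number of complete columns with >= 2 distinct bases."""
    core = aln.matrix()[:, aln.complete_sites()]
    return int(np.sum(np.any(core != core[0], axis=0)))


def total_mutations(aln: Alignment) -> int:
    """Minimum mutation count eta: sum over complete columns of (variants-1)."""
    core = aln.matrix()[:, aln.complete_sites()]
    eta = 0
    for j in range(core.shape[1]):
        eta += len(np.unique(core[:, j])) - 1
    return eta


def singleton_mutations(aln: Alignment) -> int:
    """Mutations carried by exactly one sequence (no outgroup: minor variants).

    Each variant observed in a single sequence counts as one singleton
    mutation; with only two sequences a differing column is one mutation,
    not two.
    """
    core = aln.matrix()[:, aln.complete_sites()]
    eta_s = 0
    for j in range(core.shape[1]):
        _, cnts = np.unique(core[:, j], return_counts=True)
        if len(cnts) < 2:
            continue
        ones = int(np.sum(cnts == 1))
        if len(cnts) == 2 and cnts.sum() == 2:
            ones = 1
        eta_s += ones
    return eta_s


# ---------------------------------------------------------------------------
# pairwise distance models


def _k2p_counts(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Transition and transversion proportions between two byte vectors."""
    diff = a != b
    L = a.size
    both_pur = np.isin(a, _PURINES) & np.isin(b, _PURINES)
    both_pyr = np.isin(a, _PYRIMIDINES) & np.isin(b, _PYRIMIDINES)
    ts = int(np.sum(diff & (both_pur | both_pyr)))
    tv = int(np.sum(diff)) - ts
    return ts / L, tv / L, L


def _k2p(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _jc69(p: float) -> float:
    w = 1.0 - 4.0 * p / 3.0
    if w <= 0:
        return math.nan
    return -0.75 * math.log(w)


def _tn93(P1: float, P2: float, Q: float, g: dict[str, float]) -> float:
    """Tamura–Nei distance with pooled base frequencies g."""
    gA, gC, gG, gT = g["A"], g["C"], g["G"], g["T"]
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0:
        return math.nan
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.nan
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def distance_matrix(haps: HaplotypeTable, model: str = "K2P") -> DistanceMatrix:
    """Pairwise distances between haplotypes under a substitution model.

    ``p`` is the raw mismatch proportion; ``JC69`` and ``K2P`` are the usual
    one- and two-parameter corrections.  ``MCL`` is a composite-likelihood
    style Tamura–Nei distance: base frequencies are pooled over all
    haplotypes so every pairwise distance shares the same frequency
    parameters (the convention of MEGA's Maximum Composite Likelihood
    distances).  Saturated pairs (a log of a non-positive value) are nan and
    excluded from the mean with a warning.
    """
    if model not in DISTANCE_MODELS:
        raise ValueError(f"model must be one of {DISTANCE_MODELS}")
    core = haps.core_matrix()
    h = core.shape[0]
    if h < 2:
        raise ValueError("need at least 2 haplotypes")
    if model == "MCL":
        flat = core.ravel()
        g = {
            b: float(np.mean(flat == ord(b))) for b in "ACGT"
        }
    d = np.zeros((h, h), dtype=float)
    for i in range(h):
        for j in range(i + 1, h):
            a, b = core[i], core[j]
            if model == "p":
                val = float(np.mean(a != b))
            elif model == "JC69":
                val = _jc69(float(np.mean(a != b)))
            elif model == "K2P":
                P, Q, _ = _k2p_counts(a, b)
                val = _k2p(P, Q)
            else:  # MCL
                diff = a != b
                L = a.size
                P1 = float(np.sum(diff & (a + b == ord("A") + ord("G")))) / L
                P2 = float(np.sum(diff & (a + b == ord("C") + ord("T")))) / L
                Q = float(np.sum(diff)) / L - P1 - P2
                val = _tn93(P1, P2, Q, g)
            d[i, j] = d[j, i] = val
    upper = d[np.triu_indices(h, 1)]
    defined = upper[~np.isnan(upper)]
    if defined.size < upper.size:
        warnings.warn(
            f"{upper.size - defined.size} saturated {model} distances "
            "excluded from the mean"
        )
    mean = float(defined.mean()) if defined.size else math.nan
    return DistanceMatrix(model=model, entries=d, mean=mean)


# ---------------------------------------------------------------------------
# neutrality tests


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def tajima_D(aln: Alignment) -> float:
    """Tajima's (1989) D.  ``nan`` when n < 4 or S = 0."""
    n = aln.n
    if n < 4:
        return math.nan
    S = segregating_sites(aln)
    if S == 0:
        return math.nan
    _, k = nucleotide_diversity(aln)
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return float((k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1)))


def fu_li_Dstar(aln: Alignment) -> float:
    """Fu & Li's (1993) D* without an outgroup.  ``nan`` when n < 4 or S = 0."""
    n = aln.n
    if n < 4:
        return math.nan
    eta = total_mutations(aln)
    if eta == 0:
        return math.nan
    eta_s = singleton_mutations(aln)
    an, bn = _harmonics(n)
    an1 = an + 1.0 / n
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
    )
    nn = n / (n - 1.0)
    v = (nn**2 * bn + an**2 * dn - 2.0 * n * an * (an + 1) / (n - 1) ** 2) / (
        an**2 + bn
    )
    u = nn * (an - nn) - v
    denom = u * eta + v * eta**2
    if denom <= 0:
        return math.nan
    return float((nn * eta - an * eta_s) / math.sqrt(denom))


def log_stirling1(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling, first kind).

    Recursion |s(n+1,k)| = n|s(n,k)| + |s(n,k-1)| carried in log space so it
    stays finite for sample sizes in the hundreds.
    """
    log_s = np.full(n + 1, -np.inf)
    log_s[0] = 0.0  # s(0,0) = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1:m + 1] = np.logaddexp(
            math.log(m - 1) + log_s[1:m + 1] if m > 1 else -np.inf,
            log_s[0:m],
        )
        log_s = new
    return log_s


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_s = log_stirling1(n)
    lt = math.log(theta)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    k = np.arange(n + 1)
    return log_s + k * lt - log_rising


def fu_fs_statistic(n: int, k_obs: int, theta: float) -> float:
    """Fs = ln(S'/(1-S')) with S' = P(K >= k_obs | theta).

    ``nan`` when S' is exactly 0 or 1 (log of 0 or infinity): every sample
    has at least one allele, so k_obs <= 1 gives S' = 1 identically.
    """
    if k_obs <= 1 or k_obs > n:
        return math.nan

    def logsumexp(x: np.ndarray) -> float:
        m = x.max()
        if not np.isfinite(m):
            return -math.inf
        return float(m + np.log(np.sum(np.exp(x - m))))

    logp = ewens_log_pmf(n, theta)
    log_tail = logsumexp(logp[k_obs:])      # log S'
    log_head = logsumexp(logp[:k_obs])      # log (1 - S')
    if not (np.isfinite(log_tail) and np.isfinite(log_head)):
        return math.nan
    return log_tail - log_head


def _simulate_null_fs(n: int, theta: float, rng: np.random.Generator) -> float:
    """One neutral constant-size coalescent draw of Fs at scaled theta.

    Infinite-sites mutations on a random coalescent genealogy; branch lengths
    in coalescent units so a pair of lineages has expected 2 units of branch
    and E[pairwise differences] = theta.
    """
    # each leaf accumulates a set of mutation ids; a mutation carried by c
    # leaves contributes c (n - c) to the total pairwise difference count
    members: list[list[int]] = [[i] for i in range(n)]
    muts: list[set[int]] = [set() for _ in range(n)]
    next_mut = 0
    total_diffs = 0
    j = n
    while j > 1:
        t = rng.exponential(1.0 / (j * (j - 1) / 2.0))
        for li in range(j):
            nm = rng.poisson(theta / 2.0 * t)
            if nm:
                c = len(members[li])
                total_diffs += nm * c * (n - c)
                for leaf in members[li]:
                    muts[leaf].update(range(next_mut, next_mut + nm))
                next_mut += nm
        a, b = rng.choice(j, size=2, replace=False)
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        members[a] = members[a] + members[b]
        del members[b]
        j -= 1
    K = len({frozenset(s) for s in muts})
    k_mean = total_diffs / (n * (n - 1) / 2.0)
    if k_mean <= 0:
        return math.nan
    return fu_fs_statistic(n, K, k_mean)


def fu_Fs(
    aln: Alignment,
    n_null_sims: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, float]:
    """Fu's (1997) Fs with a coalescent-simulation p-value.

    theta is estimated by the mean pairwise differences; the observed allele
    count is the number of distinct haplotypes under complete deletion.  The
    p-value is the proportion of ``n_null_sims`` neutral constant-size
    simulations at that theta with ``Fs_sim <= Fs_obs``.
    Returns ``(Fs, p)``; ``(nan, nan)`` when theta = 0 or Fs is undefined.
    """
    n = aln.n
    if n < 2:
        return (math.nan, math.nan)
    _, k = nucleotide_diversity(aln)
    if not k or math.isnan(k):
        return (math.nan, math.nan)
    core = aln.matrix()[:, aln.complete_sites()]
    K_obs = len({row.tobytes() for row in core})
    fs_obs = fu_fs_statistic(n, K_obs, k)
    if math.isnan(fs_obs):
        return (fs_obs, math.nan)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    valid = 0
    for _ in range(n_null_sims):
        fs_sim = _simulate_null_fs(n, k, rng)
        if math.isnan(fs_sim):
            continue
        valid += 1
        if fs_sim <= fs_obs:
            hits += 1
    p = hits / valid if valid else math.nan
    return (float(fs_obs), float(p))


# ---------------------------------------------------------------------------
# report assembly


def diversity_report(aln: Alignment) -> DiversityReport:
    core = aln.matrix()[:, aln.complete_sites()]
    hap_counts: dict[bytes, int] = {}
    for row in core:
        key = row.tobytes()
        hap_counts[key] = hap_counts.get(key, 0) + 1
    counts = list(hap_counts.values())
    hd, var, sd = haplotype_diversity(counts, aln.n)
    pi, k = nucleotide_diversity(aln)
    return DiversityReport(
        n=aln.n, H=len(counts), Hd=hd, var_Hd=var, sd_Hd=sd,
        pi=pi, k=k, S=segregating_sites(aln),
    )


def population_report(
    aln: Alignment,
    popmap: PopulationMap,
    n_null_sims: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population and overall diversity + neutrality table (TSV-ready).

    Mirrors the usual survey-table layout: one row per population plus an
    ``overall`` row with n, H, Hd, var_Hd, sd_Hd, pi, k, S, D, D*, Fs, p_Fs.
    """
    popmap.check_alignment(aln)
    rows = []
    groups: dict[str, list[str]] = {}
    for sid in aln.sample_ids:
        groups.setdefault(popmap.population_of(sid), []).append(sid)
    rng = np.random.default_rng(seed)
    for label, sids in list(groups.items()) + [("overall", aln.sample_ids)]:
        sub = aln.subset(sids)
        if sub.n >= 2:
            rep = diversity_report(sub)
            fs, p_fs = fu_Fs(sub, n_null_sims=n_null_sims, seed=rng)
            rows.append({
                "population": label, "n": rep.n, "H": rep.H, "Hd": rep.Hd,
                "var_Hd": rep.var_Hd, "sd_Hd": rep.sd_Hd, "pi": rep.pi,
                "k": rep.k, "S": rep.S, "tajima_D": tajima_D(sub),
                "fu_li_Dstar": fu_li_Dstar(sub), "fu_Fs": fs, "p_Fs": p_fs,
            })
        else:
            rows.append({
                "population": label, "n": sub.n, "H": 1, "Hd": math.nan,
                "var_Hd": math.nan, "sd_Hd": math.nan, "pi": math.nan,
                "k": math.nan, "S": math.nan, "tajima_D": math.nan,
                "fu_li_Dstar": math.nan, "fu_Fs": math.nan, "p_Fs": math.nan,
            })
    return pd.DataFrame(rows)
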