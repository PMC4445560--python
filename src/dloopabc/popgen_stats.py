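"""Within- and between-group summary statistics for haploid mtDNA alignments.

Implements the descriptive statistics used for the spatiotemporal groups
(number of haplotypes, haplotype diversity, mean pairwise differences,
segregating sites, Tajima's D, Fu's Fs), pairwise F_ST with permutation
tests, and the 32-element summary-statistic vector consumed by the ABC
(5 within-group statistics x 4 groups + 2 between-group statistics x 6
pairs).

Missing data (N, -, ?) is handled by pairwise deletion for distance-based
statistics and, by default, by a wildcard policy for haplotype calling: two
sequences share a haplotype if they agree at every site at which both are
non-missing, with matches merged transitively.

Neutrality-test p-values come from constant-size coalescent null samples
simulated at theta = pi-hat (the convention of simulation-based tests in
standard population-genetics toolchains), lower tail:
p = Pr(stat_sim <= stat_obs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .data_model import AlignedSequences

ABC_GROUP_ORDER = ("ancient_NE", "ancient_EU", "modern_NE", "modern_EU")

WITHIN_STAT_NAMES = ("K", "H", "pi", "S", "tajimas_D")
BETWEEN_STAT_NAMES = ("phi_st", "pi_between")


def _as_matrix(aln: AlignedSequences | np.ndarray) -> np.ndarray:
    if isinstance(aln, np.ndarray):
        return aln
    return aln.to_matrix()


def pairwise_diff_matrix(mat: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Counts of differing sites for all sequence pairs, pairwise deletion."""
    n = mat.shape[0]
    out = np.zeros((n, n), dtype=np.int32)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        a = mat[lo:hi, None, :]
        b = mat[None, :, :]
        both = (a >= 0) & (b >= 0)
        out[lo:hi] = ((a != b) & both).sum(axis=2)
    return out


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    """Partition of samples into haplotypes.

    ``haplotypes`` holds (haplotype_id, representative sequence index,
    member sample indices); counts per group are available once a grouping
    is supplied.
    """

    labels: np.ndarray                  # haplotype index per sample
    members: list[list[int]]            # sample indices per haplotype
    sample_ids: list[str]

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])

    def counts_by_group(self, groups: Mapping[str, Sequence[int]]) -> dict[str, np.ndarray]:
        out = {}
        for g, idx in groups.items():
            vec = np.zeros(self.k, dtype=int)
            for i in idx:
                vec[self.labels[i]] += 1
            out[g] = vec
        return out


def call_haplotypes(
    aln: AlignedSequences | np.ndarray,
    missing_policy: str = "wildcard",
    ids: Sequence[str] | None = None,
) -> HaplotypeTable:
    """Cluster sequences into haplotypes.

    ``wildcard``: sequences sharing a haplotype agree wherever both are
    non-missing; compatibility is closed transitively, so the result does
    not depend on input order.  ``complete_sites``: columns containing any
    missing symbol are dropped, then exact identity defines haplotypes.
    """
    mat = _as_matrix(aln)
    if mat.shape[0] == 0:
        raise ValueError("empty alignment")
    if ids is None:
        ids = aln.ids if isinstance(aln, AlignedSequences) else [
            f"s{i}" for i in range(mat.shape[0])
        ]
    n = mat.shape[0]
    if missing_policy == "wildcard":
        diffs = pairwise_diff_matrix(mat)
        adj = csr_matrix(diffs == 0)
        _, labels = connected_components(adj, directed=False)
    elif missing_policy == "complete_sites":
        keep = (mat >= 0).all(axis=0)
        sub = mat[:, keep]
        _, labels = np.unique(sub, axis=0, return_inverse=True)
        labels = np.asarray(labels).ravel()
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    # renumber haplotypes by first appearance for a stable order
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in labels])
    members: list[list[int]] = [[] for _ in range(len(order))]
    for i, lab in enumerate(labels):
        members[lab].append(i)
    return HaplotypeTable(labels=labels, members=members, sample_ids=list(ids))


def haplotype_diversity(counts: Sequence[int]) -> tuple[float, float]:
    """Nei's unbiased haplotype (gene) diversity and its standard deviation.

    H = n/(n-1) (1 - sum p_i^2); the variance is Nei's (1987) sampling
    variance of heterozygosity.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = counts / n
    sum2 = float((p**2).sum())
    sum3 = float((p**3).sum())
    h = n / (n - 1.0) * (1.0 - sum2)
    var = (
        2.0
        / (n * (n - 1.0))
        * (2.0 * (n - 2.0) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return h, math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def mean_pairwise_differences(
    aln: AlignedSequences | np.ndarray,
) -> tuple[float, float]:
    """Mean number of pairwise differences (pi) with standard deviation.

    Sites are compared only where both pair members are non-missing.  The
    standard deviation uses Tajima's (1983) total variance for a
    non-recombining locus:
    V = (n+1)/(3(n-1)) pi + 2(n^2+n+3)/(9n(n-1)) pi^2.
    """
    mat = _as_matrix(aln)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("pi requires n >= 2")
    diffs = pairwise_diff_matrix(mat)
    iu = np.triu_indices(n, k=1)
    pi = float(diffs[iu].mean())
    var = (n + 1.0) / (3.0 * (n - 1.0)) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def segregating_sites(aln: AlignedSequences | np.ndarray) -> int:
    """Number of columns with at least two distinct non-missing bases."""
    mat = _as_matrix(aln)
    if mat.shape[0] < 2:
        raise ValueError("segregating sites requires n >= 2")
    # a column segregates iff its non-missing min < max
    col_max = np.where(mat >= 0, mat, np.int8(-1)).max(axis=0)
    col_min = np.where(mat >= 0, mat, np.int8(9)).min(axis=0)
    return int((col_min < col_max).sum())


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------

@dataclass
class NeutralityResult:
    statistic: float | None
    p_value: float | None
    n_sims: int
    defined: bool = True

    def __str__(self) -> str:  # Table-style rendering
        if not self.defined:
            return "-"
        if self.p_value is None:
            return f"{self.statistic:.2f}"
        return f"{self.statistic:.2f} ({self.p_value:.2f})"


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d_value(pi: float, s: int, n: int) -> float | None:
    """Tajima's D from pi, S and sample size; None when S = 0 (undefined)."""
    if s == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1.0)
    if var <= 0:  # n = 2: the variance estimator vanishes, D undefined
        return None
    return (pi - s / a1) / math.sqrt(var)


def tajimas_d(
    aln: AlignedSequences | np.ndarray,
    n_null_sims: int = 1000,
    seed: int | None = None,
) -> NeutralityResult:
    """Tajima's D with a simulation-based p-value.

    The null is a constant-size neutral coalescent at theta = pi-hat;
    p = Pr(D_sim <= D_obs) over ``n_null_sims`` samples.
    """
    mat = _as_matrix(aln)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2")
    pi, _ = mean_pairwise_differences(mat)
    s = segregating_sites(mat)
    d = tajimas_d_value(pi, s, n)
    if d is None:
        return NeutralityResult(None, None, 0, defined=False)
    if n_null_sims <= 0:
        return NeutralityResult(d, None, 0)
    rng = np.random.default_rng(seed)
    sims = np.array(
        [neutral_null_sample(n, pi, rng)["D"] for _ in range(n_null_sims)],
        dtype=float,
    )
    sims = sims[~np.isnan(sims)]
    p = float((sims <= d).mean()) if sims.size else float("nan")
    return NeutralityResult(d, p, n_null_sims)


@lru_cache(maxsize=32)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = -np.inf
    if n == 0:
        return np.array([0.0])
    prev = np.array([0.0])  # n=0: |s(0,0)| = 1
    for m in range(1, n + 1):
        cur = np.full(m + 1, -np.inf)
        # |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|
        if m - 1 >= 1:
            cur[: len(prev)] = prev + math.log(m - 1)
        cur[1 : len(prev) + 1] = np.logaddexp(cur[1 : len(prev) + 1], prev)
        prev = cur
    return prev


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_s = _log_stirling_row(n)[1:]
    k = np.arange(1, n + 1)
    log_rising = np.log(theta + np.arange(n)).sum()
    return log_s + k * math.log(theta) - log_rising


def fs_value(n: int, k_obs: int, theta: float) -> float | None:
    """Fu's Fs = ln(S'/(1-S')) with S' = Pr(K >= k_obs | theta).

    None (undefined) when theta = 0 or k_obs = 1 (S' = 1, log-odds diverge).
    """
    if theta <= 0 or k_obs <= 1:
        return None
    logp = ewens_log_pmf(n, theta)
    from scipy.special import logsumexp

    log_sp = logsumexp(logp[k_obs - 1 :])
    log_one_minus = logsumexp(logp[: k_obs - 1]) if k_obs > 1 else -np.inf
    if not np.isfinite(log_one_minus):
        return None
    return float(log_sp - log_one_minus)


def fus_fs(
    aln: AlignedSequences | np.ndarray,
    n_null_sims: int = 1000,
    seed: int | None = None,
    missing_policy: str = "wildcard",
) -> NeutralityResult:
    """Fu's Fs with a simulation-based p-value (lower tail, null theta = pi-hat)."""
    mat = _as_matrix(aln)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("Fu's Fs requires n >= 2")
    pi, _ = mean_pairwise_differences(mat)
    k_obs = call_haplotypes(mat, missing_policy=missing_policy).k
    fs = fs_value(n, k_obs, pi)
    if fs is None:
        return NeutralityResult(None, None, 0, defined=False)
    if n_null_sims <= 0:
        return NeutralityResult(fs, None, 0)
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_null_sims):
        null = neutral_null_sample(n, pi, rng)
        f = fs_value(n, null["K"], null["pi"]) if null["pi"] > 0 else None
        if f is not None:
            sims.append(f)
    sims = np.asarray(sims)
    p = float((sims <= fs).mean()) if sims.size else float("nan")
    return NeutralityResult(fs, p, n_null_sims)


def neutral_null_sample(n: int, theta: float, rng: np.random.Generator) -> dict:
    """One constant-size neutral coalescent sample (infinite sites).

    Time is measured in units of N generations; mutations fall on lineages
    at rate theta/2 per unit time so that E[pi] = theta.  Returns pi, S, K
    and Tajima's D for a sample of size ``n``.
    """
    if n < 2:
        raise ValueError("n >= 2 required")
    # lineage -> set of leaves beneath it; branch mutation counts
    lineages: list[list[int]] = [[i] for i in range(n)]
    site_counts: list[int] = []       # derived-allele count per mutation
    muts_per_leaf: list[list[int]] = [[] for _ in range(n)]
    k = n
    while k > 1:
        rate_coal = k * (k - 1) / 2.0
        t = rng.exponential(1.0 / rate_coal)
        # mutations on each of the k lineages over duration t
        n_mut = rng.poisson(theta / 2.0 * t * k)
        for _ in range(n_mut):
            lin = lineages[rng.integers(k)]
            mut_id = len(site_counts)
            site_counts.append(len(lin))
            for leaf in lin:
                muts_per_leaf[leaf].append(mut_id)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merged = lineages[i] + lineages[j]
        lineages[i] = merged
        lineages.pop(j)
        k -= 1
    counts = np.asarray(site_counts, dtype=float)
    s = len(site_counts)
    if s:
        pi = float((counts * (n - counts)).sum() / (n * (n - 1) / 2.0))
    else:
        pi = 0.0
    haps = {tuple(sorted(m)) for m in muts_per_leaf}
    d = tajimas_d_value(pi, s, n)
    return {"pi": pi, "S": s, "K": len(haps), "D": d if d is not None else np.nan}


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _phi_st_from_diffs(diffs: np.ndarray, sizes: Sequence[int]) -> float:
    """AMOVA-based Phi_ST from a pairwise-difference matrix and group sizes."""
    sizes = np.asarray(sizes)
    n_total = int(sizes.sum())
    n_groups = len(sizes)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    iu = np.triu_indices(n_total, k=1)
    ssd_total = float(diffs[iu].sum()) / n_total
    ssd_within = 0.0
    for g in range(n_groups):
        lo, hi = bounds[g], bounds[g + 1]
        sub = diffs[lo:hi, lo:hi]
        ssd_within += float(np.triu(sub, k=1).sum()) / sizes[g]
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n_total - n_groups)
    ms_among = ssd_among / (n_groups - 1)
    n_prime = (n_total - float((sizes**2).sum()) / n_total) / (n_groups - 1)
    sigma_a = (ms_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return float(sigma_a / denom)


def _wc_haploid_theta(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Weir-Cockerham-style theta for haploid haplotype frequencies.

    Frequency-based analogue of the Reynolds coancestry estimator used for
    haplotype data: an ANOVA on haplotype indicator variables.
    """
    n1, n2 = len(labels_a), len(labels_b)
    alleles = np.unique(np.concatenate([labels_a, labels_b]))
    p1 = np.array([(labels_a == u).mean() for u in alleles])
    p2 = np.array([(labels_b == u).mean() for u in alleles])
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    msa = float((n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2).sum())  # r-1 = 1
    msw = float((n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)).sum()) / (n1 + n2 - 2)
    n_c = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    denom = msa + (n_c - 1.0) * msw
    if denom == 0.0:
        return 0.0
    return float((msa - msw) / denom)


def pairwise_fst(
    a: AlignedSequences | np.ndarray,
    b: AlignedSequences | np.ndarray,
    estimator: str = "phi_st",
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Pairwise F_ST between two groups with an optional permutation test.

    ``phi_st`` (default) is the AMOVA estimator on pairwise sequence
    differences; ``haplotype_freq`` is the frequency-based (Reynolds /
    Weir-Cockerham style) estimator on haplotype counts.  The permutation
    p-value is the proportion of label permutations (group sizes preserved)
    with F_ST >= observed.
    """
    mat_a, mat_b = _as_matrix(a), _as_matrix(b)
    n1, n2 = mat_a.shape[0], mat_b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.vstack([mat_a, mat_b])
    if estimator == "phi_st":
        diffs = pairwise_diff_matrix(pooled)

        def stat(order: np.ndarray) -> float:
            return _phi_st_from_diffs(diffs[np.ix_(order, order)], (n1, n2))

    elif estimator == "haplotype_freq":
        labels = call_haplotypes(pooled).labels

        def stat(order: np.ndarray) -> float:
            lab = labels[order]
            return _wc_haploid_theta(lab[:n1], lab[n1:])

    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    identity = np.arange(n1 + n2)
    observed = stat(identity)
    if n_perm <= 0:
        return observed, None
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(n1 + n2)) >= observed:
            count += 1
    return observed, count / n_perm


def fst_matrix(
    groups: Mapping[str, AlignedSequences] | Sequence[AlignedSequences],
    labels: Sequence[str] | None = None,
    estimator: str = "phi_st",
    n_perm: int = 0,
    seed: int | None = None,
) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Symmetric pairwise F_ST matrix plus permutation p-value matrix."""
    import pandas as pd

    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        alns = list(groups.values())
    else:
        alns = list(groups)
        labels = list(labels) if labels is not None else [
            f"g{i}" for i in range(len(alns))
        ]
    if len(alns) < 2:
        raise ValueError("need at least two groups")
    k = len(alns)
    fst = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            f, p = pairwise_fst(
                alns[i], alns[j], estimator=estimator, n_perm=n_perm,
                seed=None if seed is None else seed + 7919 * i + j,
            )
            fst[i, j] = fst[j, i] = f
            if p is not None:
                pvals[i, j] = pvals[j, i] = p
    return (
        pd.DataFrame(fst, index=labels, columns=labels),
        pd.DataFrame(pvals, index=labels, columns=labels),
    )


# ---------------------------------------------------------------------------
# ABC statistic vector
# ---------------------------------------------------------------------------

@dataclass
class StatVector:
    """The 32-element ABC summary-statistic vector.

    Five within-group statistics (K, H, pi, S, Tajima's D) for each of the
    four sample groups in fixed order, then (Phi_ST, mean between-group
    pairwise differences) for the six group pairs in lexicographic order of
    that fixed group order.  An undefined Tajima's D contributes 0 with its
    flag recorded; simulated and observed vectors are encoded identically.
    """

    values: np.ndarray
    names: tuple[str, ...]
    d_defined: tuple[bool, ...]  # per group, in ABC_GROUP_ORDER

    def __post_init__(self) -> None:
        assert len(self.values) == len(self.names)


def stat_vector_names() -> tuple[str, ...]:
    names = [
        f"{g}:{s}" for g in ABC_GROUP_ORDER for s in WITHIN_STAT_NAMES
    ]
    for i in range(4):
        for j in range(i + 1, 4):
            for s in BETWEEN_STAT_NAMES:
                names.append(f"{ABC_GROUP_ORDER[i]}|{ABC_GROUP_ORDER[j]}:{s}")
    return tuple(names)


STAT_VECTOR_NAMES = stat_vector_names()


def abc_stat_vector(
    groups: Mapping[str, AlignedSequences | np.ndarray],
) -> StatVector:
    """Compute the 32-element statistic vector from the four sample groups."""
    missing = set(ABC_GROUP_ORDER) - set(groups)
    if missing:
        raise ValueError(f"missing abc groups: {sorted(missing)}")
    mats = [_as_matrix(groups[g]) for g in ABC_GROUP_ORDER]
    for g, m in zip(ABC_GROUP_ORDER, mats):
        if m.shape[0] < 2:
            raise ValueError(f"group {g} needs n >= 2")
    sizes = [m.shape[0] for m in mats]
    pooled = np.vstack(mats)
    diffs = pairwise_diff_matrix(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])

    values: list[float] = []
    d_defined: list[bool] = []
    for gi, mat in enumerate(mats):
        n = mat.shape[0]
        lo, hi = bounds[gi], bounds[gi + 1]
        sub = diffs[lo:hi, lo:hi]
        iu = np.triu_indices(n, k=1)
        pi = float(sub[iu].mean())
        if (mat >= 0).all():
            # no missing data: identity is transitive, label = first equal row
            labels = np.argmax(sub == 0, axis=1)
            counts = np.bincount(np.unique(labels, return_inverse=True)[1])
        else:
            counts = call_haplotypes(mat).counts
        k = len(counts)
        h, _ = haplotype_diversity(counts)
        s = segregating_sites(mat)
        d = tajimas_d_value(pi, s, n)
        d_defined.append(d is not None)
        values.extend([float(k), h, pi, float(s), d if d is not None else 0.0])
    for i in range(4):
        for j in range(i + 1, 4):
            li, hi_i = bounds[i], bounds[i + 1]
            lj, hj = bounds[j], bounds[j + 1]
            pair = diffs[np.ix_(np.r_[li:hi_i, lj:hj], np.r_[li:hi_i, lj:hj])]
            phi = _phi_st_from_diffs(pair, (sizes[i], sizes[j]))
            pi_between = float(diffs[li:hi_i, lj:hj].mean())
            values.extend([phi, pi_between])
    return StatVector(
        values=np.asarray(values, dtype=float),
        names=STAT_VECTOR_NAMES,
        d_defined=tuple(d_defined),
    )
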