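"""Serial (heterochronous) coalescent simulator for the two-deme cattle model.

The demography, backwards in time from the present (t in generations BP):

* Near East / Anatolia (NE): size N_NE = 1,007,170 at t = 0, shrinking
  exponentially back to the domestication bottleneck size N_D at
  t = T_dom = 1,750 generations BP (8,500 BCE); for t >= T_dom the
  population is the ancestral wild aurochs pool of size N_anc = 45,000.
* Europe (EU): founded at t = T_split = 1,400 generations BP (6,400 BCE)
  by a proportion P of the NE population; size N_E = 7,942,392 at t = 0,
  shrinking exponentially back to the founding size P * N_NE(T_split).
* Migration between the demes is symmetric per lineage: rate M_L (late)
  for t < T_mig_change = 7000/6 generations BP (5,000 BCE), rate M_E
  (early) from there back to the split, and zero before the split (one
  deme only).

All sizes are female effective sizes; mtDNA is haploid, so a pair of
lineages in a deme of size N coalesces at instantaneous rate 1/N.
Exponential-size epochs are integrated by closed-form inversion of the
cumulative coalescent hazard (no time discretization); epoch boundaries,
sampling times and migration-rate changes truncate each waiting-time draw,
which is valid by the memorylessness of the underlying point processes.

Mutation is finite-sites with a uniform rate: hits are a Poisson process
per branch at (per-site rate x sequence length); each hit picks a uniform
site and changes the base to a uniform different base.  The rate, 45% per
site per million years, converts to 0.45e-6 x 6 = 2.7e-6 per site per
generation at the 6-year generation interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .data_model import (
    ABC_WINDOW,
    GENERATION_TIME_YEARS,
    AlignedSequences,
    matrix_to_alignment,
)

NE = "NE"
EU = "EU"


@dataclass(frozen=True)
class DemographicModel:
    """Fixed constants plus the four free parameters of the two-deme model."""

    n_anc: float = 45_000.0            # ancestral aurochs female N_e
    n_d: float = 100.0                 # bottleneck size at domestication (free)
    t_dom: float = 1_750.0             # 8,500 BCE in generations BP
    n_ne_modern: float = 1_007_170.0
    t_split: float = 1_400.0           # 6,400 BCE
    founding_p: float = 0.5            # proportion founding Europe (free)
    n_e_modern: float = 7_942_392.0
    t_mig_change: float = 7_000.0 / 6.0   # 5,000 BCE, kept exact
    m_early: float = 0.0               # per-lineage migration, split..5,000 BCE
    m_late: float = 0.0                # per-lineage migration, 5,000 BCE..present
    generation_time: float = GENERATION_TIME_YEARS
    size_scale_ne: float = 1.0         # sensitivity-analysis multipliers
    size_scale_e: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_anc, self.n_d, self.n_ne_modern, self.n_e_modern) <= 0:
            raise ValueError("population sizes must be positive")
        if not (0.0 <= self.founding_p <= 1.0):
            raise ValueError("founding proportion P must be in [0, 1]")
        if not (self.t_dom > self.t_split > self.t_mig_change > 0):
            raise ValueError("require T_dom > T_split > T_mig_change > 0")
        if self.m_early < 0 or self.m_late < 0:
            raise ValueError("migration rates must be non-negative")
        if min(self.size_scale_ne, self.size_scale_e) <= 0:
            raise ValueError("size scales must be positive")

    @property
    def n_ne0(self) -> float:
        return self.n_ne_modern * self.size_scale_ne

    @property
    def n_e0(self) -> float:
        return self.n_e_modern * self.size_scale_e

    @property
    def r_ne(self) -> float:
        """Backward shrinkage rate of the NE deme over [0, T_dom)."""
        return math.log(self.n_ne0 / self.n_d) / self.t_dom

    @property
    def eu_founding_size(self) -> float:
        return self.founding_p * deme_size_at(self, NE, self.t_split)

    @property
    def r_e(self) -> float:
        """Backward shrinkage rate of the EU deme over [0, T_split)."""
        if self.founding_p <= 0:
            raise ValueError("P = 0: European deme has no founders")
        return math.log(self.n_e0 / self.eu_founding_size) / self.t_split

    def with_params(
        self, n_d: float, founding_p: float, m_early: float, m_late: float
    ) -> "DemographicModel":
        return replace(
            self, n_d=n_d, founding_p=founding_p, m_early=m_early, m_late=m_late
        )


def deme_size_at(model: DemographicModel, deme: str, t: float) -> float:
    """Female effective size of a deme at time t generations BP."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if deme == NE:
        if t >= model.t_dom:
            return model.n_anc
        return model.n_ne0 * math.exp(-model.r_ne * t)
    if deme == EU:
        if t >= model.t_split:
            raise ValueError("European deme does not exist at t >= T_split")
        if model.founding_p <= 0:
            raise ValueError("P = 0: European deme has no founders")
        return model.n_e0 * math.exp(-model.r_e * t)
    raise ValueError(f"unknown deme {deme!r}")


def migration_rate_at(model: DemographicModel, t: float) -> float:
    """Symmetric per-lineage migration rate at time t generations BP."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t < model.t_mig_change:
        return model.m_late
    if t < model.t_split:
        return model.m_early
    return 0.0


@dataclass(frozen=True)
class MutationModel:
    rate_per_site_per_myr: float = 0.45
    seq_length: int = 240
    generation_time: float = GENERATION_TIME_YEARS

    def __post_init__(self) -> None:
        if self.rate_per_site_per_myr < 0:
            raise ValueError("mutation rate must be >= 0")
        if self.seq_length < 1:
            raise ValueError("sequence length must be >= 1")

    @property
    def rate_per_site_per_generation(self) -> float:
        return self.rate_per_site_per_myr / 1e6 * self.generation_time

    @property
    def rate_per_seq_per_generation(self) -> float:
        return self.rate_per_site_per_generation * self.seq_length


@dataclass(frozen=True)
class SampleSpec:
    deme: str
    time: float           # generations BP
    n: int
    group: str | None = None


class SamplingScheme:
    """Heterochronous sampling layout: (deme, time, count, group) entries."""

    def __init__(self, entries: Iterable[tuple | SampleSpec]):
        specs = []
        for e in entries:
            spec = e if isinstance(e, SampleSpec) else SampleSpec(*e)
            if spec.deme not in (NE, EU):
                raise ValueError(f"unknown deme {spec.deme!r}")
            if spec.time < 0:
                raise ValueError("sampling times must be >= 0")
            if spec.n < 1:
                raise ValueError("sample counts must be >= 1")
            specs.append(spec)
        if not specs:
            raise ValueError("empty sampling scheme")
        self.entries: list[SampleSpec] = specs

    @property
    def total_n(self) -> int:
        return sum(e.n for e in self.entries)

    def validate_for(self, model: DemographicModel) -> None:
        for e in self.entries:
            if e.deme == EU and e.time >= model.t_split:
                raise ValueError(
                    f"EU sample at t={e.time} >= T_split={model.t_split}"
                )
        if any(e.deme == EU for e in self.entries) and model.founding_p <= 0:
            raise ValueError("P = 0: cannot sample from the European deme")

    def leaf_groups(self) -> list[str]:
        out = []
        for i, e in enumerate(self.entries):
            label = e.group if e.group is not None else f"{e.deme}@{e.time:g}"
            out.extend([label] * e.n)
        return out


@dataclass
class Genealogy:
    """Rooted genealogy: leaves 0..n-1 in scheme order, internal nodes after."""

    time: np.ndarray        # node times, generations BP
    parent: np.ndarray      # parent index, -1 for the root
    n_leaves: int
    leaf_groups: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.time)

    @property
    def total_branch_length(self) -> float:
        has_parent = self.parent >= 0
        return float(
            (self.time[self.parent[has_parent]] - self.time[has_parent]).sum()
        )

    def pair_path_length(self, i: int, j: int) -> float:
        """Total branch length separating two leaves (sum of both root paths
        up to the MRCA)."""
        anc_i = {}
        k = i
        while k != -1:
            anc_i[k] = self.time[k]
            k = self.parent[k]
        k = j
        while k not in anc_i:
            k = self.parent[k]
        mrca_t = self.time[k]
        return float((mrca_t - self.time[i]) + (mrca_t - self.time[j]))


def _exp_epoch_wait(
    rng: np.random.Generator,
    n_pairs: float,
    n_modern: float,
    r: float,
    t0: float,
) -> float:
    """Waiting time to coalescence from t0 in a deme with size
    N(t) = n_modern * exp(-r t); cumulative-hazard inversion."""
    if n_pairs <= 0:
        return math.inf
    e = rng.exponential()
    if abs(r) < 1e-12:
        return e * n_modern / n_pairs
    # hazard per pair 1/N(t) = exp(r t)/n_modern
    arg = math.exp(r * t0) + r * n_modern * e / n_pairs
    if arg <= 0:
        return math.inf
    return math.log(arg) / r - t0


def simulate_genealogy(
    model: DemographicModel,
    scheme: SamplingScheme,
    seed: int | np.random.Generator | None = None,
) -> Genealogy:
    """Simulate one genealogy under the two-deme serial coalescent."""
    scheme.validate_for(model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = scheme.total_n
    times = []
    parent = []
    # leaves in scheme order
    leaf_time = []
    leaf_deme = []
    for e in scheme.entries:
        leaf_time.extend([e.time] * e.n)
        leaf_deme.extend([e.deme] * e.n)
    times = list(map(float, leaf_time))
    parent = [-1] * n

    # pending leaves sorted by activation time (stable in leaf order)
    pending = sorted(range(n), key=lambda i: times[i])
    active = {NE: [], EU: []}
    p_idx = 0
    t = 0.0
    eu_exists = True

    def n_active() -> int:
        return len(active[NE]) + len(active[EU])

    while p_idx < n or n_active() > 1:
        # next fixed boundary
        boundaries = []
        if p_idx < n:
            boundaries.append(times[pending[p_idx]])
        for b in (model.t_mig_change, model.t_split, model.t_dom):
            if b > t:
                boundaries.append(b)
        t_bound = min(boundaries) if boundaries else math.inf

        k_ne = len(active[NE])
        k_eu = len(active[EU])

        # coalescence waits
        pairs_ne = k_ne * (k_ne - 1) / 2.0
        if t >= model.t_dom:
            w_ne = (
                rng.exponential(model.n_anc / pairs_ne) if pairs_ne > 0 else math.inf
            )
        else:
            w_ne = _exp_epoch_wait(rng, pairs_ne, model.n_ne0, model.r_ne, t)
        pairs_eu = k_eu * (k_eu - 1) / 2.0
        if pairs_eu > 0:
            w_eu = _exp_epoch_wait(
                rng, pairs_eu, model.n_e0, model.r_e, t
            )
        else:
            w_eu = math.inf
        # migration (rate constant between boundaries)
        m = migration_rate_at(model, t)
        rate_mig = m * (k_ne + k_eu) if eu_exists and t < model.t_split else 0.0
        w_mig = rng.exponential(1.0 / rate_mig) if rate_mig > 0 else math.inf

        w = min(w_ne, w_eu, w_mig)
        if t + w >= t_bound:
            # advance to the boundary; redraw (memoryless)
            t = t_bound
            if p_idx < n and times[pending[p_idx]] == t_bound:
                while p_idx < n and times[pending[p_idx]] == t_bound:
                    leaf = pending[p_idx]
                    active[leaf_deme[leaf]].append(leaf)
                    p_idx += 1
            if t >= model.t_split and eu_exists:
                active[NE].extend(active[EU])
                active[EU] = []
                eu_exists = False
            continue
        t = t + w
        if w == w_mig:
            idx = int(rng.integers(k_ne + k_eu))
            if idx < k_ne:
                lineage = active[NE].pop(idx)
                active[EU].append(lineage)
            else:
                lineage = active[EU].pop(idx - k_ne)
                active[NE].append(lineage)
        else:
            deme = NE if w == w_ne else EU
            lin = active[deme]
            k = len(lin)
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            a, b = lin[i], lin[j]
            node = len(times)
            times.append(t)
            parent.append(-1)
            parent[a] = node
            parent[b] = node
            for idx in sorted((i, j), reverse=True):
                lin.pop(idx)
            lin.append(node)

    return Genealogy(
        time=np.asarray(times),
        parent=np.asarray(parent, dtype=np.int64),
        n_leaves=n,
        leaf_groups=scheme.leaf_groups(),
    )


@dataclass
class SimulatedSample:
    """Simulated sequences with group labels, leaf order = scheme order."""

    matrix: np.ndarray          # (n_leaves, L) int8, values 0..3
    groups: list[str]

    def by_group(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, g in enumerate(self.groups):
            out.setdefault(g, []).append(i)
        return {g: self.matrix[idx] for g, idx in out.items()}

    def to_alignment(self, ids: Sequence[str] | None = None) -> AlignedSequences:
        return matrix_to_alignment(self.matrix, ids=ids, window=ABC_WINDOW)


def add_mutations(
    genealogy: Genealogy,
    mut: MutationModel,
    seed: int | np.random.Generator | None = None,
) -> SimulatedSample:
    """Drop finite-sites mutations on a genealogy and build leaf sequences."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_nodes = genealogy.n_nodes
    L = mut.seq_length
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    root = -1
    for i, p in enumerate(genealogy.parent):
        if p >= 0:
            children[p].append(i)
        else:
            root = i
    seqs = np.empty((n_nodes, L), dtype=np.int8)
    seqs[root] = rng.integers(0, 4, size=L, dtype=np.int8)
    rate = mut.rate_per_site_per_generation
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children[node]:
            branch = genealogy.time[node] - genealogy.time[child]
            seq = seqs[node].copy()
            n_mut = rng.poisson(branch * rate * L)
            for _ in range(n_mut):
                site = int(rng.integers(L))
                seq[site] = (seq[site] + int(rng.integers(1, 4))) % 4
            seqs[child] = seq
            stack.append(child)
    return SimulatedSample(
        matrix=seqs[: genealogy.n_leaves].copy(),
        groups=list(genealogy.leaf_groups),
    )


def simulate_dataset(
    params: tuple[float, float, float, float],
    scheme: SamplingScheme,
    mut: MutationModel | None = None,
    seed: int | np.random.Generator | None = None,
    base_model: DemographicModel | None = None,
) -> SimulatedSample:
    """Simulate a grouped dataset at free parameters (N_D, P, M_E, M_L).

    Deterministic function of the seed: genealogy and mutations share one
    generator stream.
    """
    n_d, p, m_e, m_l = params
    base = base_model if base_model is not None else DemographicModel()
    model = base.with_params(n_d=n_d, founding_p=p, m_early=m_e, m_late=m_l)
    mut = mut if mut is not None else MutationModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genealogy = simulate_genealogy(model, scheme, rng)
    return add_mutations(genealogy, mut, rng)
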