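"""Coalescent simulation of single and repeat (recurrent) mutations.

Genealogies for n haplotypes are simulated under the standard (constant
population size) coalescent: while k lineages remain, an exponential waiting
time with rate k(k-1)/2 elapses (pairwise coalescence rate 1 per coalescent
unit of 2*Ne generations) and a uniformly chosen pair merges. Mutations are
then laid down as a Poisson process along branches.

Exponential growth of N-fold starting at time s (looking back) is handled by
rescaling node times t -> t' with rate g = log(N)/s:

    t' = (1/g) (exp(g t) - 1)                       for t <= s
    t' = (1/g) (exp(g s) - 1) + (t - s)             for t >  s

which stretches recent time, making genealogies star-like and inflating the
singleton class of the site frequency spectrum.

A *repeat* mutation is two independent mutation events at the same site: two
branches are drawn (length-weighted) and the carrier sets are OR-ed, which
correctly captures nested and non-nested event pairs. Repeat events whose
union covers every leaf are fixed, not segregating, and are excluded from
spectra (but tallied).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CoalescentTree",
    "GrowthModel",
    "SFS",
    "simulate_tree",
    "rescale_growth",
    "place_mutations",
    "or_repeat",
    "aggregate_sfs",
    "cpg_proportion_model",
]


@dataclass(frozen=True)
class GrowthModel:
    """N-fold exponential growth starting at time ``onset`` (coalescent
    units, looking back); ``rate`` g = log(N)/onset."""

    fold: float
    onset: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("growth fold must be >= 1")
        if self.onset <= 0:
            raise ValueError("growth onset must be positive")

    @property
    def rate(self) -> float:
        return float(np.log(self.fold) / self.onset)

    def rescale_time(self, t: np.ndarray | float) -> np.ndarray | float:
        g, s = self.rate, self.onset
        t = np.asarray(t, dtype=float)
        if g == 0.0:  # no growth: identity (g -> 0 limit)
            out = t.copy()
        else:
            out = np.where(
                t <= s,
                np.expm1(g * np.minimum(t, s)) / g,
                np.expm1(g * s) / g + (t - s),
            )
        return out if out.shape else float(out)


@dataclass
class CoalescentTree:
    """A binary coalescent genealogy over n leaves.

    Nodes 0..n-1 are leaves (time 0); nodes n..2n-2 are internal in merge
    order; the last node is the root. ``parent[v]`` is -1 for the root.
    """

    n: int
    parent: np.ndarray
    node_times: np.ndarray
    children: np.ndarray  # (n-1, 2) children of each internal node
    rescaled_times: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def times(self, rescaled: bool = False) -> np.ndarray:
        if rescaled:
            if self.rescaled_times is None:
                raise ValueError("tree has no rescaled times; call rescale_growth")
            return self.rescaled_times
        return self.node_times

    def branch_lengths(self, rescaled: bool = False) -> np.ndarray:
        """Length of the branch above each non-root node (length 2n-2)."""
        t = self.times(rescaled)
        nodes = np.arange(self.n_nodes - 1)
        return t[self.parent[nodes]] - t[nodes]

    def leaf_counts(self) -> np.ndarray:
        """Number of leaves below each node."""
        counts = np.ones(self.n_nodes, dtype=np.int64)
        for v in range(self.n, self.n_nodes):
            a, b = self.children[v - self.n]
            counts[v] = counts[a] + counts[b]
        return counts

    def carrier_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n): leaf membership below each node."""
        car = np.zeros((self.n_nodes, self.n), dtype=bool)
        car[np.arange(self.n), np.arange(self.n)] = True
        for v in range(self.n, self.n_nodes):
            a, b = self.children[v - self.n]
            car[v] = car[a] | car[b]
        return car

    def total_branch_length(self, rescaled: bool = False) -> float:
        return float(self.branch_lengths(rescaled).sum())


def simulate_tree(n: int, seed: int | np.random.Generator | None = None) -> CoalescentTree:
    """Simulate one standard-coalescent genealogy for ``n`` haplotypes."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes, dtype=float)
    children = np.zeros((n - 1, 2), dtype=np.int64)
    ks = np.arange(n, 1, -1)
    waits = rng.exponential(scale=2.0 / (ks * (ks - 1)))
    active = list(range(n))
    t = 0.0
    for step in range(n - 1):
        t += waits[step]
        k = len(active)
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        new = n + step
        parent[a] = parent[b] = new
        times[new] = t
        children[step] = (a, b)
        # replace the merged pair by the new node
        lo, hi = (i, j) if i < j else (j, i)
        active[lo] = new
        del active[hi]
    return CoalescentTree(n, parent, times, children)


def rescale_growth(tree: CoalescentTree, model: GrowthModel) -> CoalescentTree:
    """Attach growth-rescaled node times t' to a tree (non-destructive)."""
    return replace(tree, rescaled_times=np.asarray(model.rescale_time(tree.node_times)))


def place_mutations(
    tree: CoalescentTree,
    theta: float,
    use_rescaled: bool = False,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Drop Poisson(theta/2 x length) mutations on each branch; return the
    derived-allele count (leaves below the branch) of each mutation."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lengths = tree.branch_lengths(use_rescaled)
    k = rng.poisson(theta / 2.0 * lengths)
    return np.repeat(tree.leaf_counts()[: tree.n_nodes - 1], k)


def or_repeat(
    tree: CoalescentTree,
    theta: float,
    use_rescaled: bool = False,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, int]:
    """Simulate repeat-mutation events: two length-weighted branch draws per
    event, carrier sets OR-ed. Returns (segregating union sizes, number of
    fixed events whose union covered all leaves)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lengths = tree.branch_lengths(use_rescaled)
    total = lengths.sum()
    m = rng.poisson(theta / 2.0 * total)
    if m == 0:
        return np.zeros(0, dtype=np.int64), 0
    probs = lengths / total
    pairs = rng.choice(len(lengths), size=(m, 2), p=probs)
    car = tree.carrier_matrix()
    union = (car[pairs[:, 0]] | car[pairs[:, 1]]).sum(axis=1)
    fixed = int((union == tree.n).sum())
    return union[union < tree.n].astype(np.int64), fixed


@dataclass
class SFS:
    """A pooled site frequency spectrum over independent genealogies."""

    counts: np.ndarray  # index i-1 holds the count of i-ton mutations
    kind: str
    n: int
    n_trees: int
    n_fixed: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.n - 1:
            raise ValueError("SFS must cover derived counts 1..n-1")
        if (self.counts < 0).any():
            raise ValueError("negative SFS entries")

    @property
    def allele_counts(self) -> np.ndarray:
        return np.arange(1, self.n)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise ValueError("empty spectrum")
        return self.counts / total

    def scaled(self) -> np.ndarray:
        """Proportions divided by 1/n, the expected frequency of single
        mutations at each count under the constant-size coalescent plot
        convention."""
        return self.proportions() * self.n


def aggregate_sfs(
    n: int,
    n_trees: int,
    theta: float = 2.0,
    growth: GrowthModel | None = None,
    kinds: tuple[str, ...] = ("single",),
    seed: int | None = None,
) -> dict[str, SFS]:
    """Pool frequency spectra over independent trees.

    Each tree is simulated under the standard coalescent; if a growth model
    is given its times are rescaled before mutations are placed. ``kinds``
    selects "single" and/or "repeat" mutation processes (simulated on the
    same trees)."""
    if n_trees < 1:
        raise ValueError("need at least one tree")
    unknown = set(kinds) - {"single", "repeat"}
    if unknown:
        raise ValueError(f"unknown SFS kinds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    use_rescaled = growth is not None
    out = {k: np.zeros(n - 1, dtype=np.int64) for k in kinds}
    n_fixed = 0
    for _ in range(n_trees):
        tree = simulate_tree(n, rng)
        if growth is not None:
            tree = rescale_growth(tree, growth)
        if "single" in kinds:
            ac = place_mutations(tree, theta, use_rescaled, rng)
            out["single"] += np.bincount(ac, minlength=n)[1:n]
        if "repeat" in kinds:
            ac, fixed = or_repeat(tree, theta, use_rescaled, rng)
            n_fixed += fixed
            out["repeat"] += np.bincount(ac, minlength=n)[1:n]
    return {
        k: SFS(v, k, n, n_trees, n_fixed if k == "repeat" else 0)
        for k, v in out.items()
    }


def cpg_proportion_model(
    sfs_single: SFS,
    sfs_repeat: SFS,
    frac_cpg: float = 0.15,
    frac_repeat: float = 0.10,
) -> pd.Series:
    """Expected proportion of CpG mutations by derived-allele count.

    Mixes the single-mutation spectrum S and repeat-mutation spectrum R
    (each normalized to unit total within kind), assuming a fraction
    ``frac_cpg`` of all mutations are CpGs and ``frac_repeat`` of CpG
    mutations are repeat events:

        P_i = frac_cpg ((1-frac_repeat) S_i + frac_repeat R_i)
              / [ frac_cpg ((1-frac_repeat) S_i + frac_repeat R_i)
                  + (1-frac_cpg) S_i ]

    Counts where both spectra are empty are undefined and omitted. An empty
    repeat spectrum is treated as contributing nothing (R = 0), in which
    case P_i reduces to the constant
    frac_cpg (1-frac_repeat) / (frac_cpg (1-frac_repeat) + 1-frac_cpg).
    """
    if sfs_single.n != sfs_repeat.n:
        raise ValueError("spectra must come from the same sample size n")
    if not 0 <= frac_cpg <= 1 or not 0 <= frac_repeat <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    S = sfs_single.proportions()
    R = (
        sfs_repeat.proportions()
        if sfs_repeat.total > 0
        else np.zeros_like(sfs_repeat.counts, dtype=float)
    )
    cpg = frac_cpg * ((1 - frac_repeat) * S + frac_repeat * R)
    denom = cpg + (1 - frac_cpg) * S
    defined = (S > 0) | (R > 0)
    idx = sfs_single.allele_counts[defined]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = cpg[defined] / denom[defined]
    return pd.Series(p, index=pd.Index(idx, name="allele_count"), name="proportion_cpg")
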