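"""Neutral Kingman coalescent simulation (no recombination) and Monte-Carlo
null distributions for site-frequency-spectrum statistics.

Null p-values condition on the observed number of segregating sites S
(Hudson-style fixed-S): each replicate draws a genealogy, places exactly S
infinite-sites mutations on branches with probability proportional to branch
length, and recomputes the statistic.  In simulated data the derived state
is known by construction, so polarized statistics need no outgroup.

The heterogeneity test for synonymous vs nonsynonymous Tajima's D places both
mutation classes on a *shared* genealogy per replicate (the two classes are
physically linked on a nonrecombining molecule) and compares the observed
difference in D to the null distribution of differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import harmonic, harmonic2

STATS = ("tajima_d", "fu_li_d", "fay_wu_h")


@dataclass
class Mutation:
    branch: int  # node below the branch carrying the mutation
    site_id: int
    site_class: str = "unlabeled"


@dataclass
class GenealogySample:
    """A coalescent tree: parent pointers, node times, optional mutations.

    Nodes 0..n-1 are tips; the root is node 2n-2 (parent -1).  Times are in
    coalescent units of 2N generations for haploids.
    """

    n: int
    parent: np.ndarray
    time: np.ndarray
    mutations: list[Mutation] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return float(self.time[p] - self.time[node]) if p >= 0 else 0.0

    @property
    def branch_lengths(self) -> np.ndarray:
        lengths = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lengths[has_parent] = (
            self.time[self.parent[has_parent]] - self.time[has_parent]
        )
        return lengths

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def tip_sets(self) -> list[np.ndarray]:
        """Boolean tip-membership mask below each node."""
        masks = [np.zeros(self.n, dtype=bool) for _ in range(self.n_nodes)]
        for tip in range(self.n):
            masks[tip][tip] = True
        for node in range(self.n_nodes - 1):  # children precede parents
            p = self.parent[node]
            if p >= 0:
                masks[p] |= masks[node]
        return masks


def simulate_genealogy(n: int, rng: np.random.Generator) -> GenealogySample:
    """Standard neutral coalescent: Exp(k(k-1)/2) waiting times, uniform merges."""
    if n < 2:
        raise ValueError("need n >= 2 tips")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return GenealogySample(n=n, parent=parent, time=time)


def drop_fixed_s(
    tree: GenealogySample, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Place exactly S infinite-sites mutations; return the n x S 0/1 matrix."""
    if S < 0:
        raise ValueError("S must be >= 0")
    matrix = np.zeros((tree.n, S), dtype=np.int8)
    if S == 0:
        return matrix
    lengths = tree.branch_lengths
    probs = lengths / lengths.sum()
    branches = rng.choice(len(probs), size=S, p=probs)
    masks = tree.tip_sets()
    for s, br in enumerate(branches):
        matrix[masks[br], s] = 1
        tree.mutations.append(Mutation(branch=int(br), site_id=s))
    return matrix


# ---------------------------------------------------------------------------
# vectorised batch machinery


def _batch_branches(
    n: int, n_rep: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_rep`` genealogies; return per-branch descendant-tip counts
    and branch lengths, shape (n_rep, 2n-2)."""
    counts = np.ones((n_rep, n), dtype=np.int64)
    birth = np.zeros((n_rep, n))
    t = np.zeros(n_rep)
    desc = np.empty((n_rep, 2 * n - 2), dtype=np.int64)
    lens = np.empty((n_rep, 2 * n - 2))
    rows = np.arange(n_rep)
    col = 0
    for k in range(n, 1, -1):
        t = t + rng.exponential(2.0 / (k * (k - 1)), size=n_rep)
        i = rng.integers(0, k, size=n_rep)
        j = rng.integers(0, k - 1, size=n_rep)
        j = j + (j >= i)
        ci, cj = counts[rows, i], counts[rows, j]
        desc[:, col] = ci
        lens[:, col] = t - birth[rows, i]
        desc[:, col + 1] = cj
        lens[:, col + 1] = t - birth[rows, j]
        col += 2
        counts[rows, i] = ci + cj
        birth[rows, i] = t
        # move the last active lineage into slot j
        counts[rows, j] = counts[rows, k - 1]
        birth[rows, j] = birth[rows, k - 1]
    return desc, lens


def _batch_derived_counts(
    desc: np.ndarray, lens: np.ndarray, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Derived-allele counts of S fixed mutations per replicate, (n_rep, S)."""
    n_rep = desc.shape[0]
    cum = np.cumsum(lens, axis=1)
    total = cum[:, -1]
    u = rng.random((n_rep, S)) * total[:, None]
    out = np.empty((n_rep, S), dtype=np.int64)
    for r in range(n_rep):
        idx = np.searchsorted(cum[r], u[r])
        out[r] = desc[r, idx]
    return out


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    return c1 / a1, c2 / (a1 * a1 + a2)


def _tajima_d_from_derived(d: np.ndarray, n: int, S: int | np.ndarray) -> np.ndarray:
    """Vectorised Tajima's D from derived-count rows (S = row width)."""
    e1, e2 = _tajima_constants(n)
    a1 = harmonic(n - 1)
    pi_v = (2.0 * d * (n - d) / (n * (n - 1))).sum(axis=-1)
    S = np.asarray(S, dtype=float)
    return (pi_v - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def _fu_li_d_from_derived(d: np.ndarray, n: int, S: int) -> np.ndarray:
    a_n = harmonic(n - 1)
    b_n = harmonic2(n - 1)
    c_n = 2 * (n * a_n - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1 + (a_n * a_n / (b_n + a_n * a_n)) * (c_n - (n + 1) / (n - 1))
    u_d = a_n - 1 - v_d
    eta_e = (d == 1).sum(axis=-1)
    return (S - a_n * eta_e) / np.sqrt(u_d * S + v_d * S * S)


def _fay_wu_h_from_derived(d: np.ndarray, n: int) -> np.ndarray:
    pi_v = (2.0 * d * (n - d)).sum(axis=-1)
    th = (2.0 * d * d).sum(axis=-1)
    return (pi_v - th) / (n * (n - 1))


_STAT_FUNCS = {
    "tajima_d": lambda d, n, S: _tajima_d_from_derived(d, n, S),
    "fu_li_d": _fu_li_d_from_derived,
    "fay_wu_h": lambda d, n, S: _fay_wu_h_from_derived(d, n),
}


def simulate_stat_null(
    stat_name: str, n: int, S: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Null sample of a statistic conditioned on S (one value per replicate)."""
    if stat_name not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic {stat_name!r}; choose from {STATS}")
    if S <= 0:
        raise ValueError("null distributions require S >= 1")
    desc, lens = _batch_branches(n, n_reps, rng)
    d = _batch_derived_counts(desc, lens, S, rng)
    return _STAT_FUNCS[stat_name](d, n, S)


def stat_null_pvalue(
    stat_name: str,
    observed: float,
    n: int,
    S: int,
    n_reps: int = 10000,
    tail: str = "lower",
    seed: int | None = None,
) -> float:
    """Monte-Carlo p-value of an observed statistic against its fixed-S null.

    Uses the (r+1)/(m+1) estimator; ``tail`` is 'lower', 'upper' or 'two'
    (doubled smaller tail, capped at 1).
    """
    rng = np.random.default_rng(seed)
    sims = simulate_stat_null(stat_name, n, S, n_reps, rng)
    p_low = (1 + int((sims <= observed).sum())) / (n_reps + 1)
    p_high = (1 + int((sims >= observed).sum())) / (n_reps + 1)
    if tail == "lower":
        return p_low
    if tail == "upper":
        return p_high
    if tail == "two":
        return min(1.0, 2 * min(p_low, p_high))
    raise ValueError("tail must be 'lower', 'upper' or 'two'")


def heterogeneity_test(
    n: int,
    S_syn: int,
    S_nonsyn: int,
    observed_delta_d: float,
    n_reps: int = 10000,
    seed: int | None = None,
    shared_genealogy: bool = True,
    tail: str = "two",
) -> float:
    """Null p-value for the difference in Tajima's D between nonsynonymous and
    synonymous polymorphisms (delta = D_nonsyn - D_syn).

    Each replicate simulates one genealogy (shared by both classes by
    default), drops S_syn + S_nonsyn mutations on it, labels them at random,
    and recomputes the difference.  ``shared_genealogy=False`` simulates the
    two classes on independent genealogies instead.
    """
    if S_syn < 1 or S_nonsyn < 1:
        raise ValueError("heterogeneity_test requires S >= 1 in both classes")
    rng = np.random.default_rng(seed)
    if shared_genealogy:
        desc, lens = _batch_branches(n, n_reps, rng)
        d = _batch_derived_counts(desc, lens, S_syn + S_nonsyn, rng)
        # mutation draws are exchangeable given the tree: the first S_syn
        # columns are a uniformly random labeling
        d_syn = _tajima_d_from_derived(d[:, :S_syn], n, S_syn)
        d_non = _tajima_d_from_derived(d[:, S_syn:], n, S_nonsyn)
    else:
        d_syn = simulate_stat_null("tajima_d", n, S_syn, n_reps, rng)
        d_non = simulate_stat_null("tajima_d", n, S_nonsyn, n_reps, rng)
    delta = d_non - d_syn
    if tail == "two":
        r = int((np.abs(delta) >= abs(observed_delta_d)).sum())
    elif tail == "lower":
        r = int((delta <= observed_delta_d).sum())
    elif tail == "upper":
        r = int((delta >= observed_delta_d).sum())
    else:
        raise ValueError("tail must be 'lower', 'upper' or 'two'")
    return (1 + r) / (n_reps + 1)
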