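"""Bayesian inference for binary characters under the symmetric Mk model.

The two-state Mk (Jukes–Cantor-like) model has stationary frequencies
(½, ½) and transition probabilities

    P(same, t) = ½(1 + e^(−2t)),   P(different, t) = ½(1 − e^(−2t)),

with branch lengths in expected substitutions per character.  The module
provides the pruning-algorithm log-likelihood (optionally conditioned on
characters being variable, the standard restriction-site ascertainment
correction) and a single-chain Metropolis–Hastings sampler over
(topology, branch lengths) with NNI, single-branch-scaling and
whole-tree-scaling proposals, an exponential branch-length prior and a
uniform topology prior.  The sampler is fully seeded; a prior-only mode
supports the standard MCMC correctness check against the topology prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import dendropy
import numpy as np

from .coding import MISSING, CharacterMatrix
from .parsimony import _tree_from_splits

__all__ = [
    "MkModel",
    "McmcConfig",
    "PosteriorSample",
    "BayesError",
    "transition_matrix",
    "mk_loglik",
    "run_mcmc",
]


class BayesError(ValueError):
    pass


@dataclass(frozen=True)
class MkModel:
    """Two-state symmetric Mk model (fixed stationary frequencies ½, ½).

    ``ascertainment="variable_only"`` conditions each character's likelihood
    on not being constant (divides by 1 − P(constant)).
    """

    n_states: int = 2
    ascertainment: str = "none"

    def __post_init__(self) -> None:
        if self.n_states != 2:
            raise BayesError("only the 2-state Mk model is supported")
        if self.ascertainment not in ("none", "variable_only"):
            raise BayesError(f"unknown ascertainment {self.ascertainment!r}")


def transition_matrix(t: float) -> np.ndarray:
    """2×2 stochastic transition matrix after branch length *t* ≥ 0."""
    if t < 0:
        raise BayesError("branch length must be non-negative")
    same = 0.5 * (1.0 + math.exp(-2.0 * t))
    diff = 0.5 * (1.0 - math.exp(-2.0 * t))
    return np.array([[same, diff], [diff, same]])


def _leaf_partials(m: CharacterMatrix) -> dict[str, np.ndarray]:
    out = {}
    for taxon, row in zip(m.taxa, m.cells):
        p = np.zeros((m.n_characters, 2))
        p[row == 0, 0] = 1.0
        p[row == 1, 1] = 1.0
        p[row == MISSING, :] = 1.0
        out[taxon] = p
    return out


def mk_loglik(
    tree: dendropy.Tree, m: CharacterMatrix, model: MkModel = MkModel()
) -> float:
    """Felsenstein-pruning log-likelihood of the matrix on a clocklessly
    branch-lengthed tree; missing cells are marginalised over both states."""
    partials = _leaf_partials(m)
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if leaves != sorted(m.taxa):
        raise BayesError("tree leaves do not match matrix taxa")

    def down(nd) -> np.ndarray:
        if nd.is_leaf():
            return partials[nd.taxon.label]
        acc = None
        for child in nd.child_nodes():
            t = child.edge.length
            if t is None or t <= 0:
                raise BayesError("all branch lengths must be strictly positive")
            contrib = down(child) @ transition_matrix(t)
            acc = contrib if acc is None else acc * contrib
        return acc

    root = down(tree.seed_node)
    per_char = 0.5 * root.sum(axis=1)
    ll = float(np.log(per_char).sum())
    if model.ascertainment == "variable_only":
        const = _constant_pattern_prob(tree)
        ll -= m.n_characters * math.log1p(-const)
    return ll


def _constant_pattern_prob(tree: dendropy.Tree) -> float:
    """Probability of an all-0 or all-1 leaf pattern under the model."""

    def down(nd) -> np.ndarray:
        if nd.is_leaf():
            return np.eye(2)  # column s = pattern "all leaves in state s"
        acc = None
        for child in nd.child_nodes():
            contrib = transition_matrix(child.edge.length) @ down(child)
            acc = contrib if acc is None else acc * contrib
        return acc

    root = down(tree.seed_node)
    # root[s, c] = P(all leaves show state c | root in state s)
    return float((0.5 * root.sum(axis=0)).sum())


# ---------------------------------------------------------------------------
# MCMC


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``generations`` counts proposal steps; every ``sample_every``-th state
    after ``burn_in`` is recorded.  Proposal weights are relative
    frequencies of the NNI, single-branch-scaler and whole-tree-scaler
    moves.  ``prior_rate`` is the exponential branch-length prior rate
    (mean branch length 1/rate).
    """

    generations: int = 200_000
    sample_every: int = 100
    burn_in: int = 50_000
    seed: int = 0
    weight_nni: float = 1.0
    weight_blen: float = 2.0
    weight_scale: float = 0.5
    prior_rate: float = 10.0
    prior_only: bool = False
    tuning_blen: float = 2.0
    tuning_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.generations:
            raise BayesError("burn_in must be smaller than generations")
        if self.sample_every < 1:
            raise BayesError("sample_every must be positive")


@dataclass
class PosteriorSample:
    """Post-burn-in MCMC output: sampled trees (Newick, with branch
    lengths), the log-likelihood trace, split posterior probabilities and
    the majority-rule consensus annotated with them (scale 0–1)."""

    newicks: list[str]
    loglik_trace: np.ndarray
    split_posteriors: dict[frozenset, float]
    consensus: dendropy.Tree
    config: McmcConfig

    @property
    def n_samples(self) -> int:
        return len(self.newicks)


class _Chain:
    """Rooted-binary working tree with array storage.

    The Mk model is reversible, so root placement is immaterial to the
    likelihood; topology moves are NNI on internal edges.
    """

    def __init__(self, m: CharacterMatrix, rng: np.random.Generator, prior_rate: float):
        n = m.n_taxa
        self.n = n
        self.taxa = list(m.taxa)
        self.root = 2 * n - 2
        total = 2 * n - 1
        self.left = np.full(total, -1, dtype=int)
        self.right = np.full(total, -1, dtype=int)
        self.parent = np.full(total, -1, dtype=int)
        self.blen = rng.exponential(1.0 / prior_rate, size=total)
        # random sequential attachment
        self.left[self.root], self.right[self.root] = 0, 1
        self.parent[0] = self.parent[1] = self.root
        attachable = [0, 1]
        nxt = n
        for leaf in range(2, n):
            x = attachable[rng.integers(0, len(attachable))]
            p = self.parent[x]
            new = nxt
            nxt += 1
            if self.left[p] == x:
                self.left[p] = new
            else:
                self.right[p] = new
            self.parent[new] = p
            self.left[new], self.right[new] = x, leaf
            self.parent[x] = new
            self.parent[leaf] = new
            self.blen[new] = rng.exponential(1.0 / prior_rate)
            attachable += [leaf, new]
        sets = np.zeros((n, m.n_characters, 2))
        for i, row in enumerate(m.cells):
            sets[i, row == 0, 0] = 1.0
            sets[i, row == 1, 1] = 1.0
            sets[i, row == MISSING, :] = 1.0
        self.leaf_partials = sets

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            if nd >= self.n:
                stack.append(self.left[nd])
                stack.append(self.right[nd])
        return order[::-1]

    def loglik(self, model: MkModel) -> float:
        partial = {}
        for nd in self.postorder():
            if nd < self.n:
                partial[nd] = self.leaf_partials[nd]
            else:
                acc = None
                for child in (self.left[nd], self.right[nd]):
                    P = transition_matrix(self.blen[child])
                    contrib = partial[child] @ P
                    acc = contrib if acc is None else acc * contrib
                partial[nd] = acc
        per_char = 0.5 * partial[self.root].sum(axis=1)
        return float(np.log(per_char).sum())

    def log_prior(self, rate: float) -> float:
        edges = [nd for nd in range(2 * self.n - 1) if nd != self.root]
        b = self.blen[edges]
        return float(len(edges) * math.log(rate) - rate * b.sum())

    def internal_edges(self) -> list[int]:
        return [
            nd
            for nd in range(self.n, 2 * self.n - 1)
            if nd != self.root and self.parent[nd] != -1
        ]

    def sibling(self, nd: int) -> int:
        p = self.parent[nd]
        return self.right[p] if self.left[p] == nd else self.left[p]

    def _replace_child(self, parent: int, old: int, new: int) -> None:
        if self.left[parent] == old:
            self.left[parent] = new
        else:
            self.right[parent] = new
        self.parent[new] = parent

    def nni(self, c: int, which: int) -> tuple:
        """Swap sibling of internal node *c* with one of its children."""
        p = self.parent[c]
        s = self.sibling(c)
        g = self.left[c] if which == 0 else self.right[c]
        self._replace_child(p, s, g)
        self._replace_child(c, g, s)
        return (c, which, p, s, g)

    def undo_nni(self, token) -> None:
        c, which, p, s, g = token
        self._replace_child(p, g, s)
        self._replace_child(c, s, g)

    def splits(self) -> frozenset:
        labels = self.taxa
        first = min(labels)
        full = frozenset(labels)
        below: dict[int, set] = {}
        out = set()
        for nd in self.postorder():
            if nd < self.n:
                below[nd] = {labels[nd]}
            else:
                below[nd] = below[self.left[nd]] | below[self.right[nd]]
                if nd != self.root:
                    side = below[nd]
                    side = full - side if first in side else set(side)
                    if 2 <= len(side) <= self.n - 2:
                        out.add(frozenset(side))
        return frozenset(out)

    def newick(self) -> str:
        def render(nd) -> str:
            if nd < self.n:
                return f"{self.taxa[nd]}:{self.blen[nd]:.6g}"
            body = f"({render(self.left[nd])},{render(self.right[nd])})"
            if nd == self.root:
                return body
            return f"{body}:{self.blen[nd]:.6g}"

        return render(self.root) + ";"


def run_mcmc(
    m: CharacterMatrix,
    config: McmcConfig,
    model: MkModel = MkModel(),
) -> PosteriorSample:
    """Single-chain Metropolis–Hastings over (topology, branch lengths).

    Deterministic for a fixed seed.  With ``config.prior_only`` the
    likelihood is switched off, so split frequencies converge to those of
    the uniform topology prior (a standard sampler validation).
    """
    if m.n_taxa < 4:
        raise BayesError("MCMC needs at least four taxa")
    rng = np.random.default_rng(config.seed)
    chain = _Chain(m, rng, config.prior_rate)

    def loglik() -> float:
        return 0.0 if config.prior_only else chain.loglik(model)

    cur_ll = loglik()
    cur_lp = chain.log_prior(config.prior_rate)
    weights = np.array(
        [config.weight_nni, config.weight_blen, config.weight_scale], dtype=float
    )
    weights /= weights.sum()
    non_root = np.array([nd for nd in range(2 * m.n_taxa - 1) if nd != chain.root])

    newicks: list[str] = []
    trace: list[float] = []
    split_counts: dict[frozenset, int] = {}
    n_samples = 0

    for gen in range(1, config.generations + 1):
        move = rng.choice(3, p=weights)
        log_hastings = 0.0
        token = None
        touched = None
        old_blen = None
        if move == 0:
            candidates = chain.internal_edges()
            c = candidates[rng.integers(0, len(candidates))]
            token = chain.nni(c, int(rng.integers(0, 2)))
        elif move == 1:
            touched = int(non_root[rng.integers(0, len(non_root))])
            old_blen = chain.blen[touched]
            mult = math.exp(config.tuning_blen * (rng.random() - 0.5))
            chain.blen[touched] = old_blen * mult
            log_hastings = math.log(mult)
        else:
            old_blen = chain.blen.copy()
            mult = math.exp(config.tuning_scale * (rng.random() - 0.5))
            chain.blen[non_root] *= mult
            log_hastings = len(non_root) * math.log(mult)
        new_ll = loglik()
        new_lp = chain.log_prior(config.prior_rate)
        log_alpha = (new_ll - cur_ll) + (new_lp - cur_lp) + log_hastings
        if math.log(rng.random() + 1e-300) < log_alpha:
            cur_ll, cur_lp = new_ll, new_lp
        else:
            if move == 0:
                chain.undo_nni(token)
            elif move == 1:
                chain.blen[touched] = old_blen
            else:
                chain.blen = old_blen
        if gen > config.burn_in and gen % config.sample_every == 0:
            n_samples += 1
            trace.append(cur_ll)
            newicks.append(chain.newick())
            for s in chain.splits():
                split_counts[s] = split_counts.get(s, 0) + 1

    posteriors = {s: c / n_samples for s, c in split_counts.items()}
    chosen = [(s, p) for s, p in posteriors.items() if p > 0.5]
    consensus = _tree_from_splits(sorted(m.taxa), chosen)
    return PosteriorSample(
        newicks=newicks,
        loglik_trace=np.asarray(trace),
        split_posteriors=posteriors,
        consensus=consensus,
        config=config,
    )
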