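"""Ancestral state reconstruction for discrete characters.

Two reconstruction modes over a K-state continuous-time Markov (Mk) model
(K <= 7; the single-rate symmetric "Mk1" is the default):

* maximum-likelihood marginal reconstruction on one chronogram: the rate is
  fitted by ML and each internal node gets a normalised vector of marginal
  state probabilities (the "proportional likelihoods" of Mesquite-style
  output), computed with the standard two-pass (inside/outside) algorithm;
* stochastic mapping over a sample of trees: for every tree and draw a rate
  is sampled from a prior, joint node states are sampled from their
  conditional distribution given the tip data, and the per-node marginal
  posterior probabilities (MPP) are the draw frequencies, aggregated across
  the trees that contain each node (nodes are matched across trees by the
  exact tip set they subtend).

Transition probabilities use the matrix exponential P(t) = expm(Q t); the
pruning (inside) pass is checked against brute-force enumeration in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .tree import TimeTree

__all__ = [
    "MkModel",
    "mk_loglik",
    "MkAncestralModel",
    "MarginalReconstruction",
    "stochastic_map",
    "StochasticMapSummary",
]

MAX_STATES = 7


@dataclass
class MkModel:
    """K-state Mk model: symmetric single-rate by default, or an explicit
    generator matrix Q (rows sum to zero).  ``root_prior`` defaults to
    uniform."""
    K: int
    rate: float = 1.0
    Q: np.ndarray | None = None
    root_prior: np.ndarray | None = None

    def __post_init__(self):
        if not 2 <= self.K <= MAX_STATES:
            raise ValueError(f"K must be in [2, {MAX_STATES}]")
        if self.Q is not None:
            Q = np.asarray(self.Q, dtype=float)
            if Q.shape != (self.K, self.K):
                raise ValueError("Q shape does not match K")
            off = Q - np.diag(np.diag(Q))
            if (off < -1e-12).any() or np.abs(Q.sum(axis=1)).max() > 1e-9:
                raise ValueError("Q must be a valid generator matrix")
            self.Q = Q
        if self.root_prior is None:
            self.root_prior = np.full(self.K, 1.0 / self.K)
        else:
            pi = np.asarray(self.root_prior, dtype=float)
            self.root_prior = pi / pi.sum()

    def generator(self, rate: float | None = None) -> np.ndarray:
        if self.Q is not None:
            return self.Q
        r = self.rate if rate is None else rate
        Q = np.full((self.K, self.K), r)
        np.fill_diagonal(Q, -(self.K - 1) * r)
        return Q


class _FlatTree:
    """Preorder-flattened tree with per-node branch lengths."""

    def __init__(self, tree: TimeTree):
        nodes = list(tree.dendropy_tree.preorder_node_iter())
        idx = {nd: i for i, nd in enumerate(nodes)}
        self.n = len(nodes)
        self.parent = [idx.get(nd.parent_node, -1) for nd in nodes]
        self.blen = [nd.edge.length if nd.parent_node is not None else 0.0
                     for nd in nodes]
        self.children = [[idx[c] for c in nd.child_nodes()] for nd in nodes]
        self.is_tip = [not nd.child_nodes() for nd in nodes]
        self.label = [nd.taxon.label if nd.taxon else None for nd in nodes]
        self.clade = [None] * self.n
        for i in range(self.n - 1, -1, -1):
            if self.is_tip[i]:
                self.clade[i] = frozenset([self.label[i]])
            else:
                s = frozenset()
                for c in self.children[i]:
                    s |= self.clade[c]
                self.clade[i] = s


def _pruning(flat: _FlatTree, states, Q, pi):
    """Inside pass: per-node partial likelihoods (rescaled), branch
    transition matrices, and total lnL."""
    K = Q.shape[0]
    P = [None] * flat.n
    down = np.zeros((flat.n, K))
    logscale = 0.0
    for i in range(flat.n - 1, -1, -1):
        if flat.is_tip[i]:
            down[i, int(states[flat.label[i]])] = 1.0
        else:
            w = np.ones(K)
            for c in flat.children[i]:
                if P[c] is None:
                    P[c] = expm(Q * flat.blen[c])
                w = w * (P[c] @ down[c])
            tot = w.sum()
            if not tot > 0:
                return P, down, -np.inf
            logscale += np.log(tot)
            down[i] = w / tot
    for c in range(1, flat.n):
        if P[c] is None:
            P[c] = expm(Q * flat.blen[c])
    lnL = float(np.log(np.dot(pi, down[0])) + logscale)
    return P, down, lnL


def mk_loglik(tree: TimeTree, annot, model: MkModel,
              rate: float | None = None) -> float:
    """Pruning log-likelihood of tip states under the Mk model."""
    flat = _FlatTree(tree)
    missing = [l for l in flat.label if l and l not in annot]
    if missing:
        raise ValueError(f"tips without annotation: {missing[:10]}")
    Q = model.generator(rate)
    _, _, lnL = _pruning(flat, annot, Q, model.root_prior)
    return lnL


@dataclass
class MarginalReconstruction:
    """ML marginal reconstruction: fitted rate, lnL, and per-node state
    probability vectors keyed by the tip set each node subtends."""
    rate: float
    lnL: float
    node_probs: dict            # frozenset(tips) -> np.ndarray (K,)
    K: int

    def at_mrca(self, tips) -> np.ndarray:
        """Probability vector of the smallest clade containing ``tips``."""
        want = frozenset(tips)
        best = None
        for clade, p in self.node_probs.items():
            if want <= clade and (best is None or len(clade) < len(best[0])):
                best = (clade, p)
        if best is None:
            raise KeyError(f"no clade contains {sorted(want)}")
        return best[1]

    def table(self) -> pd.DataFrame:
        rows = []
        for clade, p in sorted(self.node_probs.items(),
                               key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
            rows.append({"clade": "+".join(sorted(clade)),
                         "n_tips": len(clade),
                         "state": int(np.argmax(p)),
                         "PL": round(float(p.max()), 2),
                         **{f"p{i}": round(float(p[i]), 4)
                            for i in range(self.K)}})
        return pd.DataFrame(rows)


class MkAncestralModel:
    """Mk character model on a chronogram, for likelihood evaluation,
    ML rate estimation, and marginal ancestral reconstruction."""

    def __init__(self, tree: TimeTree, annot, K: int | None = None,
                 model: MkModel | None = None):
        self.tree = tree
        self.flat = _FlatTree(tree)
        tips = [l for l in self.flat.label if l]
        missing = [l for l in tips if l not in annot]
        if missing:
            raise ValueError(f"tips without annotation: {missing[:10]}")
        if K is None:
            K = (model.K if model is not None
                 else max(int(annot[l]) for l in tips) + 1)
        self.model = model if model is not None else MkModel(K=K)
        if any(not 0 <= int(annot[l]) < self.model.K for l in tips):
            raise ValueError("annotation outside the state alphabet")
        self.annot = {l: int(annot[l]) for l in tips}

    def loglik(self, rate: float) -> float:
        Q = self.model.generator(rate)
        _, _, lnL = _pruning(self.flat, self.annot, Q,
                             self.model.root_prior)
        return lnL

    def fit_rate(self) -> float:
        depth = self.tree.crown_age
        res = minimize_scalar(lambda lr: -self.loglik(np.exp(lr)),
                              bounds=(np.log(1e-6 / depth),
                                      np.log(1e3 / depth)),
                              method="bounded", options={"xatol": 1e-9})
        return float(np.exp(res.x))

    def fit(self, rate: float | None = None) -> MarginalReconstruction:
        """Marginal reconstruction at the given rate (default: ML rate)."""
        if rate is None and self.model.Q is None:
            rate = self.fit_rate()
        probs, lnL = self._marginals(rate)
        return MarginalReconstruction(
            rate=(rate if rate is not None else self.model.rate),
            lnL=lnL, node_probs=probs, K=self.model.K)

    def _marginals(self, rate):
        flat = self.flat
        Q = self.model.generator(rate)
        pi = self.model.root_prior
        P, down, lnL = _pruning(flat, self.annot, Q, pi)
        K = self.model.K
        up = np.zeros((flat.n, K))
        up[0] = pi
        # partial "toward-parent" messages S_c(i) = sum_j P_c[i,j] down_c(j)
        S = [None] + [P[c] @ down[c] for c in range(1, flat.n)]
        for v in range(flat.n):
            if flat.is_tip[v]:
                continue
            cs = flat.children[v]
            for c in cs:
                sib = np.ones(K)
                for c2 in cs:
                    if c2 != c:
                        sib = sib * S[c2]
                m = (up[v] * sib) @ P[c]
                tot = m.sum()
                up[c] = m / tot if tot > 0 else m
        probs = {}
        for v in range(flat.n):
            if flat.is_tip[v]:
                continue
            w = up[v] * down[v]
            probs[flat.clade[v]] = w / w.sum()
        return probs, lnL

    # ----------------------------------------------------- joint sampling

    def sample_node_states(self, rate, rng, n_draws=1):
        """Joint draws of internal-node states from their conditional
        distribution given the tip data (used by stochastic mapping)."""
        flat = self.flat
        Q = self.model.generator(rate)
        pi = self.model.root_prior
        P, down, lnL = _pruning(flat, self.annot, Q, pi)
        if not np.isfinite(lnL):
            raise ValueError("data impossible under this rate")
        internal = [v for v in range(flat.n) if not flat.is_tip[v]]
        out = np.zeros((n_draws, len(internal)), dtype=int)
        pos = {v: j for j, v in enumerate(internal)}
        for d in range(n_draws):
            state = {}
            w = pi * down[0]
            state[0] = rng.choice(self.model.K, p=w / w.sum())
            out[d, 0] = state[0]
            for v in range(1, flat.n):
                if flat.is_tip[v]:
                    continue
                i = state[flat.parent[v]]
                w = P[v][i] * down[v]
                state[v] = rng.choice(self.model.K, p=w / w.sum())
                out[d, pos[v]] = state[v]
        clades = [flat.clade[v] for v in internal]
        return clades, out


def ml_marginal_reconstruction(tree: TimeTree, annot, K: int | None = None,
                               rate: float | None = None
                               ) -> MarginalReconstruction:
    return MkAncestralModel(tree, annot, K=K).fit(rate=rate)


@dataclass
class StochasticMapSummary:
    """Per-node marginal posterior state probabilities aggregated over a
    tree sample; nodes keyed by the exact tip set they subtend."""
    mpp: dict                     # frozenset -> np.ndarray (K,)
    tree_count: dict              # frozenset -> trees containing the node
    n_trees: int
    n_draws_per_tree: int
    K: int
    seed: object = None

    def at_node(self, tips) -> np.ndarray:
        return self.mpp[frozenset(tips)]

    def table(self) -> pd.DataFrame:
        rows = []
        for clade in sorted(self.mpp, key=lambda c: (-len(c), sorted(c))):
            p = self.mpp[clade]
            rows.append({"clade": "+".join(sorted(clade)),
                         "n_tips": len(clade),
                         "trees": self.tree_count[clade],
                         "state": int(np.argmax(p)),
                         "MPP": round(float(p.max()), 2),
                         **{f"p{i}": round(float(p[i]), 4)
                            for i in range(self.K)}})
        return pd.DataFrame(rows)


def stochastic_map(trees, annot, K: int | None = None,
                   rate_prior=("gamma", 2.0, 0.05), n_draws: int = 100,
                   seed=None, model: MkModel | None = None
                   ) -> StochasticMapSummary:
    """Stochastic character mapping over a sample of chronograms.

    ``rate_prior`` is ``("gamma", shape, scale)`` or ``("fixed", rate)``;
    each draw samples a rate, then joint node states.  MPP per node is the
    frequency of each state across all draws of all trees containing that
    node.
    """
    if isinstance(trees, TimeTree):
        trees = [trees]
    if not trees:
        raise ValueError("need at least one tree")
    rng = np.random.default_rng(seed)
    counts: dict = {}
    tree_count: dict = {}
    Kref = None
    for tree in trees:
        m = MkAncestralModel(tree, annot, K=K, model=model)
        Kref = m.model.K
        for clade in {m.flat.clade[v] for v in range(m.flat.n)
                      if not m.flat.is_tip[v]}:
            tree_count[clade] = tree_count.get(clade, 0) + 1
        for _ in range(n_draws):
            if rate_prior[0] == "gamma":
                r = rng.gamma(rate_prior[1], rate_prior[2])
            elif rate_prior[0] == "fixed":
                r = rate_prior[1]
            else:
                raise ValueError("rate_prior must be ('gamma', shape, scale)"
                                 " or ('fixed', rate)")
            clades, draws = m.sample_node_states(r, rng, n_draws=1)
            for clade, s in zip(clades, draws[0]):
                vec = counts.setdefault(clade, np.zeros(Kref))
                vec[s] += 1
    mpp = {c: v / v.sum() for c, v in counts.items()}
    return StochasticMapSummary(mpp=mpp, tree_count=tree_count,
                                n_trees=len(trees), n_draws_per_tree=n_draws,
                                K=Kref, seed=seed)
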