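"""Simulators for every input class the analyses consume.

All generators condition on the number of extant tips, grow trees forward
from the two crown lineages, and are reproducible under an explicit seed:

* :func:`simulate_yule` -- constant-rate pure birth (the null of the
  CR/MCCR tests and of the delta-AIC significance test);
* :func:`simulate_multirate_yule` -- piecewise-constant speciation rate
  (the generating model behind the yule2rate/yule3rate fits);
* :func:`simulate_bd` -- constant-rate birth-death conditioned on n
  survivors, extinct lineages pruned;
* :func:`simulate_bisse` -- binary-state-dependent birth-death with
  character flips, returning the tree plus tip states;
* :func:`simulate_mk_characters` -- discrete characters evolved down an
  existing tree under a continuous-time Markov (Mk) model;
* :func:`subsample` -- random or diversity-biased incomplete taxon
  sampling (the alpha scale of the non-random-sampling sensitivity check).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm

from . import _core
from .tree import TimeTree

__all__ = [
    "SimulationConfig",
    "SubsamplingScheme",
    "simulate_yule",
    "simulate_bd",
    "simulate_multirate_yule",
    "simulate_bisse",
    "simulate_mk_characters",
    "subsample",
]


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SubsamplingScheme:
    """Incomplete-sampling scheme: uniform (``random``) or diversity-biased
    (``nonrandom``), where ``alpha`` interpolates from uniform removal
    (alpha=0) to always culling the shallowest remaining cherry (alpha=1)."""
    mode: str = "random"
    m: int = 0
    alpha: float = 0.0

    def __post_init__(self):
        if self.mode not in ("random", "nonrandom"):
            raise ValueError("mode must be 'random' or 'nonrandom'")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.mode == "nonrandom" else 0.0


@dataclass
class SimulationConfig:
    """Bag of generator settings mirrored by the CLI config file."""
    seed: int = 0
    n_tips: int = 100
    model: str = "yule"            # yule | bd | multirate | bisse
    lam: float = 1.0
    mu: float = 0.0
    rates: tuple = ()
    shift_times: tuple = ()
    bisse_params: tuple = (0.1, 0.1, 0.0, 0.0, 0.01, 0.01)
    root_state: int = 0
    replicates: int = 1
    subsampling: SubsamplingScheme | None = None


# ------------------------------------------------------- array -> TimeTree

def _build_timetree(parent, age, keep, labels=None):
    """Assemble the reconstructed TimeTree induced by the tips ``keep``."""
    has, deg = _core._subtree_marks(parent, keep)
    nra = _core.nearest_retained_ancestor(parent, deg)
    keep_set = set(keep)
    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)
    nodes = {}
    for v in range(len(parent)):
        is_split = deg[v] >= 2
        is_tip = v in keep_set
        if not (is_split or is_tip):
            continue
        if is_split and nra[v] == -1:
            nodes[v] = dtree.seed_node
            continue
        nd = dendropy.Node()
        nodes[nra[v]].add_child(nd)
        nd.edge.length = age[nra[v]] - age[v]
        nodes[v] = nd
        if is_tip:
            lab = labels[v] if labels else f"t{v}"
            nd.taxon = tns.new_taxon(lab)
    return TimeTree(dtree, validate=False)


def _tree_to_arrays(tree: TimeTree):
    """Flatten a TimeTree into (parent, age, tip_ids, tip_labels)."""
    parent, age, tips, labels = [], [], [], {}
    ids = {}
    for nd in tree.dendropy_tree.preorder_node_iter():
        v = len(parent)
        ids[nd] = v
        parent.append(-1 if nd.parent_node is None else ids[nd.parent_node])
        age.append(tree.node_age(nd))
        if not nd.child_nodes():
            tips.append(v)
            labels[v] = nd.taxon.label
    return parent, age, tips, labels


# ------------------------------------------------------------- generators

def simulate_yule(n: int, lam: float = 1.0, seed=None) -> TimeTree:
    """Constant-rate pure-birth tree with ``n`` extant tips.

    Grown from 2 crown lineages; the waiting time with k lineages is
    Exponential(k*lam) and the tree is observed just before the (n+1)-th
    tip would appear.  Under a fixed seed the tree at rate ``lam`` equals
    the tree at rate 1 with all durations divided by ``lam``.
    """
    return simulate_multirate_yule(n, [lam], [], seed)


def simulate_multirate_yule(n: int, rates, shift_times, seed=None) -> TimeTree:
    """Pure-birth tree whose speciation rate is piecewise constant.

    ``shift_times`` are measured forward from the crown split (the final
    tree depth is random, so shifts cannot be pinned to ages before the
    present ahead of time).  The realised shift ages are stored on the
    result as ``tree.shift_ages`` for parameter-recovery checks.  With a
    single rate this is exactly :func:`simulate_yule`.
    """
    rng = _rng(seed)
    parent, age, tips, crown = _core.yule_arrays(
        n, rng, rates=rates, shift_times=shift_times)
    tree = _build_timetree(parent, age, tips)
    tree.shift_ages = [crown - s for s in shift_times]
    return tree


def simulate_bd(n: int, lam: float, mu: float, seed=None,
                max_attempts: int = 100_000) -> TimeTree:
    """Birth-death tree conditioned on ``n`` extant tips (rejection
    sampling), with extinct lineages pruned.  At ``mu = 0`` the generating
    process is the same as :func:`simulate_yule`."""
    rng = _rng(seed)
    parent, age, tips, _ = _core.bd_arrays(n, lam, mu, rng,
                                           max_attempts=max_attempts)
    return _build_timetree(parent, age, tips)


def simulate_bisse(n: int, params, root_state: int = 0, seed=None,
                   max_attempts: int = 100_000):
    """State-dependent birth-death tree plus binary tip characters.

    ``params = (lam0, lam1, mu0, mu1, q01, q10)``.  Returns ``(TimeTree,
    {tip label: state})``.
    """
    if root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    rng = _rng(seed)
    parent, age, tips, state, _ = _core.bisse_arrays(
        n, tuple(params), root_state, rng, max_attempts=max_attempts)
    tree = _build_timetree(parent, age, tips)
    states = {f"t{v}": state[v] for v in tips}
    return tree, states


def simulate_mk_characters(tree: TimeTree, Q, root_distribution=None,
                           seed=None) -> dict:
    """Evolve a discrete character down ``tree`` under generator matrix Q.

    Q must have non-negative off-diagonals and zero row sums; at most 7
    states.  Returns ``{tip label: state}``.
    """
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[0]
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1] or K < 2 or K > 7:
        raise ValueError("Q must be square with 2..7 states")
    off = Q - np.diag(np.diag(Q))
    if (off < -1e-12).any() or np.abs(Q.sum(axis=1)).max() > 1e-9:
        raise ValueError("Q must have non-negative off-diagonals and "
                         "zero row sums")
    rng = _rng(seed)
    pi = (np.full(K, 1.0 / K) if root_distribution is None
          else np.asarray(root_distribution, dtype=float))
    pi = pi / pi.sum()
    dtree = tree.dendropy_tree
    state = {dtree.seed_node: rng.choice(K, p=pi)}
    out = {}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        P = expm(Q * nd.edge.length)
        row = np.clip(P[state[nd.parent_node]], 0, None)
        state[nd] = rng.choice(K, p=row / row.sum())
        if not nd.child_nodes():
            out[nd.taxon.label] = int(state[nd])
    return out


def subsample(tree: TimeTree, scheme: SubsamplingScheme, seed=None) -> TimeTree:
    """Remove tips down to ``scheme.m`` under the scheme's sampling mode."""
    if scheme.m > tree.n_tips:
        raise ValueError("cannot subsample to more tips than the tree has")
    if scheme.m == tree.n_tips:
        return tree.copy()
    rng = _rng(seed)
    parent, age, tips, labels = _tree_to_arrays(tree)
    keep = _core.choose_tips(parent, age, tips, scheme.m, rng,
                             alpha=scheme.effective_alpha)
    return tree.prune_to_tips([labels[v] for v in keep])
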