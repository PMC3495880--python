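"""Array-level birth-death machinery shared by the simulators and the
Monte-Carlo tests.

Trees are held as flat parallel lists indexed by node id, with the invariant
``parent[child] < child`` (parents are created before their children), which
lets subtree aggregation run as a single reverse sweep and ancestor lookups
as a single forward sweep.  The object layer (:mod:`macrodiv.simulate`,
:mod:`macrodiv.tree`) converts to and from :class:`~macrodiv.tree.TimeTree`;
the Monte-Carlo loops (MCCR, delta-AIC null) stay down here for speed.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "gamma_from_branching_times",
    "yule_arrays",
    "bd_arrays",
    "bisse_arrays",
    "pruned_branching_times",
    "choose_tips",
]


def gamma_from_branching_times(x) -> float:
    """Pybus-Harvey gamma from descending branching times x_2 > ... > x_n.

    With g_k the duration spent with exactly k lineages, T_i = sum_{k<=i} k g_k
    and T = T_n,

        gamma = [ mean_{i=2..n-1}(T_i) - T/2 ] / [ T sqrt(1/(12 (n-2))) ].

    Invariant to rescaling time; ~N(0,1) under a constant-rate pure-birth
    process with complete sampling.
    """
    x = np.asarray(x, dtype=float)
    n = x.size + 1
    if n < 3:
        raise ValueError("gamma needs at least 3 tips (2 branching times)")
    g = np.empty(n - 1)
    g[:-1] = -np.diff(x)
    g[-1] = x[-1]
    kg = np.arange(2, n + 1) * g
    T = kg.sum()
    if T <= 0:
        raise ValueError("total lineage-time T must be positive")
    Ti = np.cumsum(kg)[:-1]
    return float((Ti.mean() - 0.5 * T) / (T * math.sqrt(1.0 / (12 * (n - 2)))))


# ------------------------------------------------------------- simulators

def _piecewise_wait(s, hazard_scale, rates, bounds, rng):
    """Advance forward time ``s`` by one event with hazard
    ``hazard_scale * rate(s)`` where ``rate`` is piecewise-constant with
    breakpoints ``bounds`` (forward times, ascending)."""
    u = rng.exponential()
    seg = int(np.searchsorted(bounds, s, side="right"))
    while True:
        r = hazard_scale * rates[seg]
        end = bounds[seg] if seg < len(bounds) else math.inf
        if r > 0:
            dt = u / r
            if s + dt <= end:
                return s + dt
            u -= (end - s) * r
        if end is math.inf or math.isinf(end):
            if r <= 0:
                raise RuntimeError("zero rate in the final segment: "
                                   "process cannot proceed")
        s = end
        seg += 1


def yule_arrays(n, rng, rates=(1.0,), shift_times=()):
    """Pure-birth tree grown from 2 crown lineages to n tips.

    ``rates`` is a piecewise-constant speciation rate with breakpoints
    ``shift_times`` measured forward from the crown split.  The waiting time
    with k lineages has hazard k*rate(s); the process is observed just before
    the (n+1)-th tip would appear, so the final interval is a complete
    exponential draw.

    Returns ``(parent, age, tips, crown_age)``: flat lists with
    ``parent[child] < child``, node ages measured back from the present
    (tips at 0), and the tip node ids.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    rates = list(rates)
    bounds = list(shift_times)
    if any(r <= 0 for r in rates):
        raise ValueError("speciation rates must be positive")
    if len(bounds) != len(rates) - 1 or any(
            b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("need one ascending shift time between segments")
    parent = [-1, 0, 0]
    etime = [0.0, None, None]       # forward split time of internal nodes
    active = [1, 2]
    s = 0.0
    for k in range(2, n):           # k lineages -> k+1
        s = _piecewise_wait(s, k, rates, bounds, rng)
        i = rng.integers(k)
        v = active[i]
        c = len(parent)
        parent.extend((v, v))
        etime[v] = s
        etime.extend((None, None))
        active[i] = c
        active.append(c + 1)
    present = _piecewise_wait(s, n, rates, bounds, rng)
    age = [present - t if t is not None else 0.0 for t in etime]
    return parent, age, active, present


def bd_arrays(n, lam, mu, rng, max_attempts=100_000):
    """Birth-death tree conditioned (by rejection) on n extant survivors.

    Grown forward from 2 crown lineages; extinct side branches are kept in
    the arrays (as dead leaves) and excluded from the returned tip list, so
    the reconstructed tree is obtained by pruning to the survivors.
    Rejection restarts whenever the clade dies or the crown lineages do not
    both leave survivors.
    """
    if not (lam > mu >= 0):
        raise ValueError("need lam > mu >= 0")
    tot = lam + mu
    pb = lam / tot
    for _ in range(max_attempts):
        parent = [-1, 0, 0]
        etime = [0.0, None, None]
        active = [1, 2]
        s = 0.0
        failed = False
        while len(active) < n:
            k = len(active)
            if k == 0:
                failed = True
                break
            s += rng.exponential(1.0 / (k * tot))
            i = rng.integers(k)
            if rng.random() < pb:
                v = active[i]
                c = len(parent)
                parent.extend((v, v))
                etime[v] = s
                etime.extend((None, None))
                active[i] = c
                active.append(c + 1)
            else:
                v = active.pop(i)
                etime[v] = s        # death time; v stays a (dead) leaf
        if failed:
            continue
        present = s + rng.exponential(1.0 / (n * tot))
        # both crown lineages must have survivors, else the observed crown
        # age would differ from the simulated one
        has = [False] * len(parent)
        for v in active:
            has[v] = True
        for v in range(len(parent) - 1, 0, -1):
            if has[v]:
                has[parent[v]] = True
        if not (has[1] and has[2]):
            continue
        age = [None] * len(parent)
        for v, t in enumerate(etime):
            age[v] = 0.0 if t is None else present - t
        return parent, age, list(active), present
    raise RuntimeError(f"birth-death simulation failed to produce {n} "
                       f"survivors in {max_attempts} attempts")


def bisse_arrays(n, params, root_state, rng, max_attempts=100_000):
    """State-dependent birth-death tree with binary character, conditioned
    on n survivors.  ``params = (lam0, lam1, mu0, mu1, q01, q10)``.

    Returns ``(parent, age, tips, states, crown_age)`` where ``states`` maps
    over all node ids (tip states are read off the survivor entries).
    """
    lam = (params[0], params[1])
    mu = (params[2], params[3])
    q = (params[4], params[5])
    if any(v < 0 for v in params) or lam[0] + lam[1] <= 0:
        raise ValueError("rates must be non-negative with some speciation")
    tot = tuple(lam[i] + mu[i] + q[i] for i in (0, 1))
    for _ in range(max_attempts):
        parent = [-1, 0, 0]
        etime = [0.0, None, None]
        state = [root_state, root_state, root_state]
        active = [1, 2]
        s = 0.0
        failed = False
        while len(active) < n:
            k = len(active)
            if k == 0:
                failed = True
                break
            rate_tot = sum(tot[state[v]] for v in active)
            if rate_tot <= 0:
                failed = True
                break
            s += rng.exponential(1.0 / rate_tot)
            # pick lineage proportional to its total rate
            r = rng.random() * rate_tot
            acc = 0.0
            for i, v in enumerate(active):
                acc += tot[state[v]]
                if r <= acc:
                    break
            st = state[v]
            u = rng.random() * tot[st]
            if u < lam[st]:
                c = len(parent)
                parent.extend((v, v))
                etime[v] = s
                etime.extend((None, None))
                state.extend((st, st))
                active[i] = c
                active.append(c + 1)
            elif u < lam[st] + mu[st]:
                active.pop(i)
                etime[v] = s
            else:
                state[v] = 1 - st
        if failed:
            continue
        k = len(active)
        rate_tot = sum(tot[state[v]] for v in active)
        present = s + (rng.exponential(1.0 / rate_tot) if rate_tot > 0
                       else 1.0 / max(lam))
        has = [False] * len(parent)
        for v in active:
            has[v] = True
        for v in range(len(parent) - 1, 0, -1):
            if has[v]:
                has[parent[v]] = True
        if not (has[1] and has[2]):
            continue
        age = [0.0 if t is None else present - t for t in etime]
        return parent, age, list(active), state, present
    raise RuntimeError(f"BiSSE simulation failed to produce {n} survivors "
                       f"in {max_attempts} attempts")


# --------------------------------------------------------------- pruning

def _subtree_marks(parent, keep):
    """Reverse sweep: for every node, how many of its children lead to a
    kept tip (``deg``) and whether its subtree holds one (``has``)."""
    nn = len(parent)
    has = [False] * nn
    deg = [0] * nn
    for v in keep:
        has[v] = True
    for v in range(nn - 1, 0, -1):
        if has[v]:
            p = parent[v]
            deg[p] += 1
            has[p] = True
    return has, deg


def pruned_branching_times(parent, age, keep):
    """Branching times of the subtree induced by the tips ``keep``.

    The retained internal nodes are exactly those with kept tips on both
    sides (their ages are MRCA ages, which pruning preserves).
    """
    _, deg = _subtree_marks(parent, keep)
    bt = sorted((age[v] for v in range(len(parent)) if deg[v] >= 2),
                reverse=True)
    return np.asarray(bt)


def nearest_retained_ancestor(parent, deg):
    """Forward sweep mapping every node to its closest ancestor that is a
    retained split (``deg >= 2``); the root maps to -1."""
    nn = len(parent)
    nra = [-1] * nn
    for v in range(1, nn):
        p = parent[v]
        nra[v] = p if deg[p] >= 2 else nra[p]
    return nra


def choose_tips(parent, age, tips, m, rng, alpha=0.0):
    """Choose m of ``tips`` to retain, uniformly (alpha=0) or with a bias
    toward a maximally diversified set (alpha=1).

    The diversified end of the scale removes, at each step, one member of
    the shallowest remaining cherry (the most redundant tip); each removal
    is diversified with probability alpha and uniform otherwise, so alpha
    interpolates between random and diversified subsampling.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if m > len(tips):
        raise ValueError("cannot sample more tips than exist")
    if alpha == 0.0:
        idx = rng.choice(len(tips), size=m, replace=False)
        return [tips[i] for i in idx]
    remaining = list(tips)
    while len(remaining) > m:
        if rng.random() < alpha:
            has, deg = _subtree_marks(parent, remaining)
            # youngest retained split
            c = min((v for v in range(len(parent)) if deg[v] >= 2),
                    key=lambda v: age[v])
            nra = nearest_retained_ancestor(parent, deg)
            cherry = [v for v in remaining if nra[v] == c]
            victim = cherry[rng.integers(len(cherry))]
        else:
            victim = remaining[rng.integers(len(remaining))]
        remaining.remove(victim)
    return remaining
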