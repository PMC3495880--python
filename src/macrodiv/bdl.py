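"""Birth-death likelihood (BDL) model suite on branching times.

Six diversification models are fitted to the branching times of an
ultrametric tree and compared by AIC: two rate-constant models (pureBirth,
birth-death) and four rate-variable ones (density-dependent logistic DDL,
density-dependent exponential DDX, and the yule2rate / yule3rate piecewise
pure-birth models whose shifts are only allowed at observed branching
times).  The significance of the AIC improvement of the best rate-variable
model is assessed against a null distribution built from pure-birth trees
simulated at the clade's full richness and pruned to the sampled size.

Conventions
-----------
* ``x_2 > x_3 > ... > x_n`` are node ages before present; ``g_k`` is the
  duration with exactly k lineages; ``T = sum k g_k`` is total lineage time.
* The combinatorial constant ``sum_{k=2}^{n-1} ln k`` is included in every
  pure-birth-family log-likelihood (it is shared across models, so AIC
  differences are unaffected, and it matches the sign conventions of the
  classic LASER-style output).
* Free-parameter counts: pureBirth 1, bd 2, DDL 2, DDX 2, yule2rate 3,
  yule3rate 5 (shift times count as free parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

from . import _core
from .tree import TimeTree, internode_intervals, ages_from_intervals

__all__ = [
    "DiversificationFit",
    "BDLModel",
    "BDLResults",
    "loglik_purebirth",
    "loglik_bd",
    "loglik_density_dependent",
    "loglik_yule_multirate",
    "fit_purebirth",
    "fit_bd",
    "fit_density_dependent",
    "fit_yule_multirate",
    "fit_bdl_suite",
    "delta_aic_significance",
]

MODELS = ("pureBirth", "bd", "DDL", "DDX", "yule2rate", "yule3rate")
N_PARAMS = {"pureBirth": 1, "bd": 2, "DDL": 2, "DDX": 2,
            "yule2rate": 3, "yule3rate": 5}
RC_MODELS = ("pureBirth", "bd")
RV_MODELS = ("DDL", "DDX", "yule2rate", "yule3rate")


def _as_g(data) -> np.ndarray:
    if isinstance(data, TimeTree):
        return data.internode_intervals()
    g = np.asarray(data, dtype=float)
    return g


def _lineage_time(g):
    """T = sum_{k=2}^{n} k g_k."""
    n = g.size + 1
    return float(np.dot(np.arange(2, n + 1), g))


def _ln_const(n):
    """sum_{k=2}^{n-1} ln k, the labelled-history constant."""
    return float(np.sum(np.log(np.arange(2, n))))


# ------------------------------------------------------------ likelihoods

def loglik_purebirth(g, lam: float) -> float:
    """Constant-rate pure-birth log-likelihood; MLE is (n-2)/T."""
    g = _as_g(g)
    if lam <= 0:
        raise ValueError("lam must be positive")
    n = g.size + 1
    return _ln_const(n) + (n - 2) * np.log(lam) - lam * _lineage_time(g)


def loglik_bd(bt, r: float, a: float) -> float:
    """Birth-death log-likelihood on branching times, conditioned on crown
    survival; ``r`` is the net rate (lambda - mu) and ``a`` the extinction
    fraction (mu/lambda).  Reduces exactly to pureBirth at ``a = 0``."""
    if r <= 0:
        raise ValueError("r must be positive")
    if not 0 <= a < 1:
        raise ValueError("a must lie in [0, 1)")
    x = np.asarray(bt, dtype=float)
    n = x.size + 1
    # ln(e^{r x} - a) = r x + ln(1 - a e^{-r x}), stable for large r x
    ln_terms = r * x + np.log1p(-a * np.exp(-r * x))
    return (_ln_const(n) + (n - 2) * np.log(r) + n * np.log1p(-a)
            + r * x[1:].sum() - 2.0 * ln_terms.sum())


def _dd_rates(variant, n, r1, K=None, x=None):
    k = np.arange(2, n + 1)
    if variant == "DDL":
        if K is None or K <= n:
            raise ValueError("DDL needs carrying capacity K > n")
        return r1 * (1.0 - k / K)
    if variant == "DDX":
        if x is None or x < 0:
            raise ValueError("DDX needs exponent x >= 0")
        return r1 * k ** (-float(x))
    raise ValueError("variant must be 'DDL' or 'DDX'")


def loglik_density_dependent(g, variant: str, r1: float,
                             K: float | None = None,
                             x: float | None = None) -> float:
    """Density-dependent pure birth: per-lineage rate lam_k = r1 (1 - k/K)
    (logistic, DDL) or lam_k = r1 k^-x (exponential, DDX).

    DDX with x = 0 and DDL with K -> infinity both reduce to pureBirth.
    """
    g = _as_g(g)
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    n = g.size + 1
    lam_k = _dd_rates(variant, n, r1, K=K, x=x)
    k = np.arange(2, n + 1)
    return float(np.sum(np.log(k[:-1] * lam_k[:-1]))
                 - np.sum(k * lam_k * g))


def _segment_stats(g, shift_ages):
    """Event counts and lineage-time integrals per rate segment.

    Segments are delimited by descending shift ages; a branching event
    exactly at a shift age belongs to the older segment (the event at which
    the new rate takes over).  Shift ages need not coincide with branching
    times here (likelihood evaluation is general); the *fitting* routine
    restricts candidates to observed branching times.
    """
    g = _as_g(g)
    n = g.size + 1
    x = ages_from_intervals(g)                 # x_2 .. x_n descending
    shift_ages = sorted(shift_ages, reverse=True)
    if any(not (0 < s < x[0]) for s in shift_ages):
        raise ValueError("shift ages must lie strictly inside (0, crown age)")
    k = np.arange(2, n + 1)
    x_lower = np.concatenate([x[1:], [0.0]])   # interval k spans [x_{k+1}, x_k]

    def events_ge(b):
        # branching events (excluding the crown split) with age >= b
        return max(int(np.sum(x >= b)) - 1, 0)

    def lineage_time_ge(b):
        # sum_k k * (portion of interval k older than b)
        return float(np.sum(k * np.clip(x - np.maximum(x_lower, b), 0, None)))

    ev, lt = [], []
    prev_e, prev_a = 0, 0.0
    for b in list(shift_ages) + [0.0]:
        e = events_ge(b) if b > 0 else n - 2
        a = lineage_time_ge(b)
        ev.append(e - prev_e)
        lt.append(a - prev_a)
        prev_e, prev_a = e, a
    return np.array(ev), np.array(lt)


def loglik_yule_multirate(g, rates, shift_ages) -> float:
    """Piecewise pure-birth log-likelihood with the given rates per segment
    (oldest first) and shift ages at observed branching times."""
    g = _as_g(g)
    rates = np.asarray(rates, dtype=float)
    if rates.size != len(list(shift_ages)) + 1:
        raise ValueError("need exactly one more rate than shift ages")
    if (rates <= 0).any():
        raise ValueError("rates must be positive")
    n = g.size + 1
    ev, lt = _segment_stats(g, shift_ages)
    return float(_ln_const(n) + np.sum(ev * np.log(rates) - rates * lt))


@dataclass
class DiversificationFit:
    """One fitted diversification model (a column of the comparison table)."""
    model: str
    params: dict
    lnL: float
    k: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return -2.0 * self.lnL + 2.0 * self.k

    def param_string(self) -> str:
        return " ".join(f"{p} = {v:.3f}" for p, v in self.params.items())


# ---------------------------------------------------------------- fitting

def fit_purebirth(g) -> DiversificationFit:
    g = _as_g(g)
    n = g.size + 1
    T = _lineage_time(g)
    lam = (n - 2) / T
    return DiversificationFit("pureBirth", {"r1": lam},
                              loglik_purebirth(g, lam), 1)


def fit_bd(bt) -> DiversificationFit:
    """ML birth-death fit via bounded quasi-Newton on (ln r, logit a),
    cross-checked against the closed-form pure-birth boundary a = 0."""
    x = np.asarray(bt, dtype=float)
    g = internode_intervals(x)
    n = x.size + 1
    lam0 = (n - 2) / _lineage_time(g)

    def nll(theta):
        r = np.exp(theta[0])
        a = expit(theta[1])
        try:
            return -loglik_bd(x, r, a)
        except (ValueError, FloatingPointError):
            return 1e12

    best = None
    for ua in (-2.0, 1.5):
        res = minimize(nll, [np.log(lam0), ua], method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9,
                                "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    r = float(np.exp(best.x[0]))
    a = float(expit(best.x[1]))
    lnL = -best.fun
    # the a = 0 boundary (pure birth) with closed-form rate
    lnL0 = loglik_purebirth(g, lam0)
    if lnL0 >= lnL or a < 1e-6:
        # at a = 0 the rate MLE is the closed-form pure-birth one
        r, a, lnL = lam0, 0.0, lnL0
    return DiversificationFit("bd", {"r1": r, "a": a}, float(lnL), 2)


def fit_density_dependent(g, variant: str) -> DiversificationFit:
    """Profile fit: for a fixed K (DDL) or x (DDX) the rate has a closed
    form, so the fit is a 1-D search over the shape parameter."""
    g = _as_g(g)
    n = g.size + 1
    k = np.arange(2, n + 1)

    def profile(shape):
        if variant == "DDL":
            c = 1.0 - k / shape
        else:
            c = k ** (-shape)
        denom = float(np.sum(k * c * g))
        r1 = (n - 2) / denom
        lnL = (float(np.sum(np.log(k[:-1] * c[:-1] * r1)))
               - r1 * denom)
        return r1, lnL

    if variant == "DDL":
        los, his = np.log(n + 1e-3 * n + 1.0), np.log(1e4 * n)
        grid = np.linspace(los, his, 24)
    elif variant == "DDX":
        los, his = 0.0, 8.0
        grid = np.linspace(los, his, 24)
    else:
        raise ValueError("variant must be 'DDL' or 'DDX'")

    def nll(s):
        shape = np.exp(s) if variant == "DDL" else s
        try:
            return -profile(shape)[1]
        except (ValueError, ZeroDivisionError, FloatingPointError):
            return 1e12

    vals = [nll(s) for s in grid]
    s0 = grid[int(np.argmin(vals))]
    lo = max(los, s0 - (grid[1] - grid[0]))
    hi = min(his, s0 + (grid[1] - grid[0]))
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    s_best = res.x if res.fun <= min(vals) else s0
    shape = float(np.exp(s_best)) if variant == "DDL" else float(s_best)
    r1, lnL = profile(shape)
    params = ({"r1": r1, "K": shape} if variant == "DDL"
              else {"r1": r1, "x": shape})
    return DiversificationFit(variant, params, float(lnL), 2)


def fit_yule_multirate(g, m: int) -> DiversificationFit:
    """Profile the yule2rate (m=2) or yule3rate (m=3) likelihood over all
    admissible shift placements at observed branching times, using the
    closed-form per-segment rate MLEs r_j = events_j / lineage-time_j."""
    if m not in (2, 3):
        raise ValueError("m must be 2 or 3")
    g = _as_g(g)
    n = g.size + 1
    if n - 3 < m - 1:
        raise ValueError("too few branching times for the requested shifts")
    x = ages_from_intervals(g)
    kg = np.arange(2, n + 1) * g
    cum = np.concatenate([[0.0], np.cumsum(kg)])
    T = cum[-1]
    C = _ln_const(n)

    def seg(e, A):
        # sup_r [e ln r - r A] at r = e/A
        return e * (np.log(e / A) - 1.0)

    # candidate shifts x_i, i = 3..n-1 (1-based index i), so every segment
    # keeps at least one branching event
    i = np.arange(3, n)                    # shift index for x_i
    A1 = cum[i - 2]                        # sum_{k=2}^{i-1} k g_k
    e1 = i - 2
    if m == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            lnL = C + seg(e1, A1) + seg(n - i, T - A1)
        lnL = np.where(np.isfinite(lnL), lnL, -np.inf)
        b = int(np.argmax(lnL))
        ib = i[b]
        r1 = e1[b] / A1[b]
        r2 = (n - ib) / (T - A1[b])
        return DiversificationFit(
            "yule2rate", {"r1": float(r1), "r2": float(r2),
                          "st": float(x[ib - 2])}, float(lnL[b]), 3)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mask = jj > ii
    Ai = cum[ii - 2]
    Aj = cum[jj - 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        lnL = (C + seg(ii - 2, Ai) + seg(jj - ii, Aj - Ai)
               + seg(n - jj, T - Aj))
    lnL = np.where(mask & np.isfinite(lnL), lnL, -np.inf)
    b = np.unravel_index(np.argmax(lnL), lnL.shape)
    ib, jb = int(ii[b]), int(jj[b])
    r1 = (ib - 2) / cum[ib - 2]
    r2 = (jb - ib) / (cum[jb - 2] - cum[ib - 2])
    r3 = (n - jb) / (T - cum[jb - 2])
    return DiversificationFit(
        "yule3rate", {"r1": float(r1), "r2": float(r2), "r3": float(r3),
                      "st1": float(x[ib - 2]), "st2": float(x[jb - 2])},
        float(lnL[b]), 5)


# ------------------------------------------------------------ model object

class BDLResults:
    """Comparison of the six fitted diversification models."""

    def __init__(self, fits: dict[str, DiversificationFit]):
        self.fits = fits
        aics = {m: f.aic for m, f in fits.items()}
        self.best_model = min(aics, key=aics.get)
        self.delta_aic = {m: a - aics[self.best_model] for m, a in aics.items()}
        rc = [aics[m] for m in RC_MODELS if m in aics]
        rv = [aics[m] for m in RV_MODELS if m in aics]
        #: AIC improvement of the best rate-variable over the best
        #: rate-constant model (positive when RV fits better)
        self.delta_aic_rc_rv = (min(rc) - min(rv)) if rc and rv else None

    def table(self) -> pd.DataFrame:
        """Four-row table (Parameters / Ln(L) / AIC / dAIC) by model."""
        cols = {}
        for m in MODELS:
            if m not in self.fits:
                continue
            f = self.fits[m]
            cols[m] = {"Parameters": f.param_string(),
                       "Ln(L)": round(f.lnL, 3),
                       "AIC": round(f.aic, 3),
                       "dAIC": round(self.delta_aic[m], 3)}
        return pd.DataFrame(cols)

    def summary(self) -> str:
        out = [self.table().to_string(),
               f"best model: {self.best_model}; "
               f"dAIC (best RC - best RV) = {self.delta_aic_rc_rv:.3f}"]
        return "\n".join(out)


class BDLModel:
    """Diversification model selection on the branching times of a tree.

    Parameters
    ----------
    data
        A :class:`TimeTree` or a descending vector of branching times.
    models
        Subset of the six model names (all by default).
    """

    def __init__(self, data, models=MODELS):
        if isinstance(data, TimeTree):
            self.branching_times = data.branching_times()
        else:
            self.branching_times = np.sort(
                np.asarray(data, dtype=float))[::-1]
        if self.branching_times.size < 3:
            raise ValueError("need at least 4 tips (3 branching times)")
        self.g = internode_intervals(self.branching_times)
        unknown = set(models) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        self.models = tuple(m for m in MODELS if m in models)

    def fit(self) -> BDLResults:
        fits = {}
        for m in self.models:
            try:
                if m == "pureBirth":
                    fits[m] = fit_purebirth(self.g)
                elif m == "bd":
                    fits[m] = fit_bd(self.branching_times)
                elif m in ("DDL", "DDX"):
                    fits[m] = fit_density_dependent(self.g, m)
                elif m == "yule2rate":
                    fits[m] = fit_yule_multirate(self.g, 2)
                else:
                    fits[m] = fit_yule_multirate(self.g, 3)
            except Exception as exc:   # pragma: no cover - defensive
                import warnings
                warnings.warn(f"fit of {m} failed and is excluded: {exc}")
        return BDLResults(fits)


def fit_bdl_suite(data) -> BDLResults:
    """Fit all six models and compare them by AIC."""
    return BDLModel(data).fit()


def delta_aic_significance(observed_delta: float, n_total: int,
                           n_sampled: int, B: int = 5000, seed=None,
                           return_null: bool = False):
    """Monte-Carlo P-value for the AIC improvement of rate-variable models.

    Simulates ``B`` pure-birth trees at the clade's full richness,
    uniformly prunes each to the sampled size, runs the model suite, and
    compares the observed best-RC-minus-best-RV AIC difference to the null
    sample: P = (1 + #{null >= observed}) / (B + 1).  The simulation rate is
    irrelevant (the statistic is scale-invariant), so rate 1 is used.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if not 4 <= n_sampled <= n_total:
        raise ValueError("need 4 <= n_sampled <= n_total")
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        parent, age, tips, _ = _core.yule_arrays(n_total, rng)
        if n_sampled < n_total:
            keep = _core.choose_tips(parent, age, tips, n_sampled, rng)
            bt = _core.pruned_branching_times(parent, age, keep)
        else:
            bt = np.sort(np.asarray([a for a in age if a > 0.0]))[::-1]
        null[b] = BDLModel(bt).fit().delta_aic_rc_rv
    p = float((1.0 + np.count_nonzero(null >= observed_delta)) / (B + 1.0))
    return (p, null) if return_null else p
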