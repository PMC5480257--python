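"""Branching-time diversification analysis: LTT curves, constant and
piecewise pure-birth (Yule) models, a constant-rate birth-death model,
ΔAIC model selection across a tree posterior, and chi-square counts tests.

The likelihood family is the simple unconditioned branching-time
likelihood: for a piecewise-constant speciation rate λ(·),

    logL = Σ_events log λ(t_i)  −  ∫ N(t)·λ(t) dt,

where ``t`` is age before present, events are all internal nodes (the
crown divergence included) and ``N(t)`` is the reconstructed lineage
count. When a stem branch is retained, the interval from the stem age to
the crown age adds exposure with ``N = 1`` and no event. Shift times for
the two- and three-rate Yule models are searched over the observed
branching times (discrete candidates) with closed-form per-segment rates
λ̂ = events / lineage-time. The birth-death model uses the matching
unconditioned reconstructed-process density in a (net rate, extinction
fraction) parameterization, which reduces exactly to the one-rate Yule
likelihood at extinction fraction zero, keeping AIC comparable across the
whole family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .treeio import TimeTree, TreeValidationError

__all__ = [
    "BranchingTimes",
    "RateShiftFit",
    "ModelSelectionTally",
    "ChiSquareResult",
    "branching_times",
    "ltt",
    "ltt_points",
    "plot_ltt",
    "YuleShiftModel",
    "BirthDeathModel",
    "loglike_piecewise_yule",
    "loglike_bd",
    "fit_model",
    "select_model",
    "chisq_gof",
    "MODEL_NAMES",
    "CONSTANT_MODELS",
    "VARIABLE_MODELS",
]

MODEL_NAMES = ("yule1", "bd", "yule2", "yule3")
CONSTANT_MODELS = frozenset({"yule1", "bd"})
VARIABLE_MODELS = frozenset({"yule2", "yule3"})


# ---------------------------------------------------------------------------
# branching times
# ---------------------------------------------------------------------------

@dataclass
class BranchingTimes:
    """Internal-node ages in Myr, crown age first (descending)."""

    ages: np.ndarray
    n_tips: int
    stem_age: Optional[float] = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        if np.any(self.ages <= 0):
            raise ValueError("branching times must be strictly positive")
        if np.any(np.diff(self.ages) > 0):
            raise ValueError("branching times must be sorted descending")
        if len(self.ages) != self.n_tips - 1:
            raise ValueError("need n_tips - 1 branching times for a binary "
                             "crown tree")
        if self.stem_age is not None and self.stem_age < self.ages[0]:
            raise ValueError("stem age must be >= crown age")

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])

    @property
    def start_age(self) -> float:
        return float(self.stem_age if self.stem_age is not None
                     else self.ages[0])


def branching_times(tree: TimeTree, include_stem: bool = False,
                    stem_length: Optional[float] = None) -> BranchingTimes:
    """Extract branching times (node ages) from a binary ultrametric tree.

    ``include_stem`` retains the branch subtending the crown node: its
    length is read from the tree's root edge unless given explicitly.
    """
    if not tree.is_binary():
        raise TreeValidationError("branching times require a binary tree")
    if not tree.is_ultrametric():
        raise TreeValidationError("tree is not ultrametric within tolerance")
    ages = tree.node_ages()
    internal = sorted((a for nd, a in ages.items() if nd.is_internal()),
                      reverse=True)
    bt_ages = np.maximum(np.asarray(internal), 1e-12)
    stem_age = None
    if include_stem:
        if stem_length is None:
            stem_length = tree.stem_length
        if stem_length is None:
            raise ValueError("include_stem requested but the tree has no "
                             "root edge length and none was given")
        stem_age = float(bt_ages[0] + stem_length)
    return BranchingTimes(ages=bt_ages, n_tips=tree.n_tips,
                          stem_age=stem_age)


# ---------------------------------------------------------------------------
# lineages through time
# ---------------------------------------------------------------------------

def ltt(trees: Sequence[TimeTree] | TimeTree
        ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-tree step functions: (ages of steps descending incl. 0,
    lineage counts 2..n). The count at age a is the value on [a, prev)."""
    if isinstance(trees, TimeTree):
        trees = [trees]
    out = []
    for t in trees:
        bt = branching_times(t)
        times = np.concatenate([bt.ages, [0.0]])
        counts = np.arange(2, bt.n_tips + 2)
        counts[-1] = bt.n_tips  # value at present
        out.append((times, counts[:len(times)]))
    return out


def ltt_points(trees: Sequence[TimeTree]) -> pd.DataFrame:
    """Long-format LTT table (natural-log lineage counts) for plotting."""
    rows = []
    for i, (times, counts) in enumerate(ltt(list(trees))):
        for t, c in zip(times, counts):
            rows.append((i, float(t), int(c), float(np.log(c))))
    return pd.DataFrame(rows, columns=["tree", "age", "n_lineages",
                                       "log_n_lineages"])


def plot_ltt(trees: Sequence[TimeTree], ax=None, **kwargs):
    """Ensemble LTT plot (log lineage count vs age, age axis reversed)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    kwargs.setdefault("color", "steelblue")
    kwargs.setdefault("alpha", min(1.0, 20.0 / max(len(trees), 1)))
    for times, counts in ltt(list(trees)):
        ax.step(times, np.log(counts), where="post", **kwargs)
    ax.invert_xaxis()
    ax.set_xlabel("age (Myr)")
    ax.set_ylabel("ln(lineages)")
    return ax


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _exposure_intervals(bt: BranchingTimes
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hi, lo, N) triples of the lineage-count step function over age."""
    x = bt.ages
    his, los, ns = [], [], []
    if bt.stem_age is not None and bt.stem_age > x[0]:
        his.append(bt.stem_age)
        los.append(x[0])
        ns.append(1)
    lows = np.concatenate([x[1:], [0.0]])
    his.extend(x.tolist())
    los.extend(lows.tolist())
    ns.extend(range(2, bt.n_tips + 1))
    return np.asarray(his), np.asarray(los), np.asarray(ns)


def _exposure_older_than(bt: BranchingTimes, a: np.ndarray) -> np.ndarray:
    """Total lineage-time at ages > a (vectorized over a)."""
    hi, lo, n = _exposure_intervals(bt)
    a = np.atleast_1d(np.asarray(a, dtype=float))
    overlap = np.clip(hi[None, :] - np.maximum(lo[None, :], a[:, None]),
                      0.0, None)
    return overlap @ n


def _events_older_than(bt: BranchingTimes, a: np.ndarray) -> np.ndarray:
    a = np.atleast_1d(np.asarray(a, dtype=float))
    return (bt.ages[None, :] > a[:, None]).sum(axis=1)


def _segment_stats(bt: BranchingTimes, shifts: Sequence[float]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Events and exposure per rate segment for shift ages (descending).

    Segment j spans ages in (s_{j+1}, s_j]; an event exactly at a shift
    age belongs to the younger segment (the new rate applies from the
    shift on).
    """
    bounds = np.concatenate([[np.inf], np.asarray(shifts, dtype=float),
                             [0.0]])
    cum_e = _events_older_than(bt, bounds)
    cum_a = _exposure_older_than(bt, bounds)
    events = np.diff(cum_e)
    exposure = np.diff(cum_a)
    return events.astype(float), exposure


def loglike_piecewise_yule(bt: BranchingTimes, rates: Sequence[float],
                           shifts: Sequence[float] = ()) -> float:
    """Piecewise pure-birth log-likelihood (rates oldest first)."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) != len(shifts) + 1:
        raise ValueError("need one more rate than shift times")
    ev, ex = _segment_stats(bt, shifts)
    ll = 0.0
    for e, a, lam in zip(ev, ex, rates):
        if e > 0 and lam <= 0:
            return -np.inf
        if e > 0:
            ll += e * np.log(lam)
        ll -= lam * a
    return float(ll)


def _log_p1(t: np.ndarray, r: float, a: float) -> np.ndarray:
    """log probability that a lineage of age t leaves exactly one extant
    descendant, for net rate r and extinction fraction a."""
    return 2.0 * np.log1p(-a) - r * t - 2.0 * np.log1p(-a * np.exp(-r * t))


def loglike_bd(bt: BranchingTimes, r: float, a: float) -> float:
    """Constant-rate birth-death log-likelihood, same event convention as
    the Yule family (reduces to yule1 at a = 0)."""
    if r <= 0 or not 0 <= a < 1:
        return -np.inf
    lam = r / (1.0 - a)
    x = bt.ages
    ll = (len(x) * np.log(lam)
          + _log_p1(np.asarray([bt.start_age]), r, a)[0]
          + _log_p1(x, r, a).sum())
    return float(ll)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass
class RateShiftFit:
    """A fitted diversification model: rates (oldest segment first),
    shift times (descending ages), log-likelihood and AIC."""

    model: str
    rates: tuple[float, ...]
    shift_times: tuple[float, ...]
    logL: float
    aic: float
    n_params: int
    extinction_fraction: Optional[float] = None
    include_stem: bool = False

    def summary(self) -> str:
        lines = [f"model: {self.model}",
                 f"rates (per lineage per Myr): "
                 + ", ".join(f"{r:.4g}" for r in self.rates)]
        if self.shift_times:
            lines.append("shift times (Mya): "
                         + ", ".join(f"{s:.4g}" for s in self.shift_times))
        if self.extinction_fraction is not None:
            lines.append(f"extinction fraction: "
                         f"{self.extinction_fraction:.4g}")
        lines += [f"logL: {self.logL:.6f}",
                  f"AIC: {self.aic:.6f}  (k = {self.n_params})",
                  "conditioning: none (unconditioned branching-time "
                  "likelihood; crown event counted)"]
        return "\n".join(lines)


def _aic(logL: float, k: int) -> float:
    return 2.0 * k - 2.0 * logL


class YuleShiftModel:
    """Pure-birth model with ``n_rates`` piecewise-constant speciation
    rates; shift times are searched over the observed branching times."""

    def __init__(self, bt: BranchingTimes, n_rates: int = 1):
        if n_rates not in (1, 2, 3):
            raise ValueError("n_rates must be 1, 2 or 3")
        if len(bt.ages) < n_rates:
            raise ValueError(
                f"{n_rates}-rate model needs at least {n_rates} branching "
                f"times, got {len(bt.ages)}")
        self.bt = bt
        self.n_rates = n_rates

    def _candidates(self) -> np.ndarray:
        return np.unique(self.bt.ages)[::-1]

    def fit(self) -> RateShiftFit:
        bt = self.bt
        name = f"yule{self.n_rates}"
        k = 2 * self.n_rates - 1
        if self.n_rates == 1:
            ev, ex = _segment_stats(bt, ())
            lam = float(ev.sum() / ex.sum())
            ll = loglike_piecewise_yule(bt, [lam])
            return RateShiftFit(name, (lam,), (), ll, _aic(ll, k), k,
                                include_stem=bt.stem_age is not None)
        best = None
        cands = self._candidates()
        combos = ([(s,) for s in cands] if self.n_rates == 2 else
                  [(s1, s2) for i, s1 in enumerate(cands)
                   for s2 in cands[i + 1:]])
        for shifts in combos:
            ev, ex = _segment_stats(bt, shifts)
            if np.any(ex <= 0):
                continue
            lams = ev / ex
            ll = float(np.sum(np.where(ev > 0, ev * np.log(
                np.where(lams > 0, lams, 1.0)), 0.0)) - np.sum(lams * ex))
            if best is None or ll > best[0] + 1e-12:
                best = (ll, tuple(float(l) for l in lams),
                        tuple(float(s) for s in shifts))
        if best is None:
            raise ValueError("no admissible shift times")
        ll, lams, shifts = best
        return RateShiftFit(name, lams, shifts, ll, _aic(ll, k), k,
                            include_stem=bt.stem_age is not None)


class BirthDeathModel:
    """Constant-rate birth-death model parameterized as (net
    diversification rate r, extinction fraction a = μ/λ)."""

    def __init__(self, bt: BranchingTimes):
        self.bt = bt

    def fit(self) -> RateShiftFit:
        bt = self.bt
        ev, ex = _segment_stats(bt, ())
        lam0 = float(ev.sum() / ex.sum())

        def nll(x):
            ll = loglike_bd(bt, x[0], x[1])
            return -ll if np.isfinite(ll) else 1e300

        best = None
        for a0 in (0.0, 0.5, 0.9):
            res = minimize(nll, np.array([max(lam0 * (1 - a0), 1e-6), a0]),
                           method="L-BFGS-B",
                           bounds=[(1e-9, 10.0), (0.0, 0.9999)])
            if best is None or res.fun < best.fun:
                best = res
        r, a = best.x
        ll = -best.fun
        return RateShiftFit("bd", (float(r),), (), ll, _aic(ll, 2), 2,
                            extinction_fraction=float(a),
                            include_stem=bt.stem_age is not None)


def fit_model(bt: BranchingTimes, model: str) -> RateShiftFit:
    """Fit one of 'yule1', 'bd', 'yule2', 'yule3'."""
    if model == "bd":
        return BirthDeathModel(bt).fit()
    if model in ("yule1", "yule2", "yule3"):
        return YuleShiftModel(bt, int(model[-1])).fit()
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# model selection and counts tests
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionTally:
    """Per-tree best models plus counts per model and per category."""

    best_models: list[str]
    counts: dict[str, int]
    category_counts: dict[str, int]

    @property
    def n_trees(self) -> int:
        return len(self.best_models)


def _best_model(fits: Mapping[str, RateShiftFit], delta_aic: float) -> str:
    """Lowest AIC wins, but a model beats every simpler one only when all
    of them trail by more than ``delta_aic``; ties go to the simpler
    model."""
    items = sorted(fits.values(), key=lambda f: (f.n_params, f.model))
    qualified = [f for f in items
                 if all(g.aic - f.aic > delta_aic
                        for g in items if g.n_params < f.n_params)]
    return min(qualified, key=lambda f: (f.aic, f.n_params, f.model)).model


def select_model(fits_per_tree: Sequence[Mapping[str, RateShiftFit]],
                 delta_aic: float = 4.0) -> ModelSelectionTally:
    best = [_best_model(f, delta_aic) for f in fits_per_tree]
    counts = {m: best.count(m) for m in MODEL_NAMES}
    cats = {
        "constant": sum(1 for b in best if b in CONSTANT_MODELS),
        "variable": sum(1 for b in best if b in VARIABLE_MODELS),
    }
    return ModelSelectionTally(best, counts, cats)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float


def chisq_gof(observed: Sequence[float],
              expected: Optional[Sequence[float]] = None) -> ChiSquareResult:
    """Chi-square goodness of fit, equal expected counts by default."""
    obs = np.asarray(observed, dtype=float)
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if expected is None:
        exp = np.full_like(obs, obs.sum() / len(obs))
    else:
        exp = np.asarray(expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    stat, p = stats.chisquare(obs, exp)
    return ChiSquareResult(float(stat), len(obs) - 1, float(p))
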