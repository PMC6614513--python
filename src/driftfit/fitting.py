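"""Per-subject diffusion-model estimation by RT-quantile multinomial likelihood.

The estimation strategy mirrors the classical quantile-based multinomial
approach: within every condition cell, response times are split by
response side (correct vs. error) and binned at fixed quantiles (default
.1/.3/.5/.7/.9, i.e. six bins per side).  The model's expected probability
of each bin is the defective first-passage CDF difference at the bin
edges; the fitted parameters maximise the multinomial likelihood of the
observed bin counts, summed over cells.

Four nested parameter-freeing schemes are supported (which parameters may
differ between the 8 cells):

========== ============================ ====
name       free per cell                 k
========== ============================ ====
full       a, v, Ter                     24
v_free     v          (a, Ter shared)    10
v_a_free   a, v       (Ter shared)       17
v_ter_free v, Ter     (a shared)         17
========== ============================ ====

All models constrain the starting point to ``z = a/2``; the separate
:func:`bias_check` frees the relative start to test left/right response
symmetry.  Optimisation is a nested profile scheme: cell-specific
parameters are optimised per cell (bounded quasi-Newton or golden-section)
inside an outer simplex/scalar search over the shared parameters, with
jittered moment-based (EZ-style) starting values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .conditions import CELLS
from .core import DDMParams, _fpt_cdf, _hit_upper, simulate_trials
from .errors import FitError
from .selection import bic

__all__ = [
    "ModelSpec",
    "MODELS",
    "CellBins",
    "BinnedData",
    "FitResult",
    "bin_rts",
    "multinomial_loglik",
    "ez_estimate",
    "fit_subject",
    "fit_all_models",
    "bias_check",
    "predictive_check",
]

DEFAULT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
PROB_FLOOR = 1e-10
MIN_SIDE = 12  # fewer observations on a side -> single merged bin

_BOUNDS = {"a": (0.01, 0.5), "v": (-1.0, 1.0), "w": (0.05, 0.95)}


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which diffusion parameters vary across the 8 condition cells."""

    name: str
    cell_free: tuple[str, ...]
    shared: tuple[str, ...]

    @property
    def k(self) -> int:
        """Number of estimated parameters."""
        return len(self.shared) + len(CELLS) * len(self.cell_free)


MODELS: dict[str, ModelSpec] = {
    "full": ModelSpec("full", ("a", "v", "ter"), ()),
    "v_free": ModelSpec("v_free", ("v",), ("a", "ter")),
    "v_a_free": ModelSpec("v_a_free", ("a", "v"), ("ter",)),
    "v_ter_free": ModelSpec("v_ter_free", ("v", "ter"), ("a",)),
}


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass
class CellBins:
    """Observed quantile-bin counts for one condition cell."""

    cell: tuple[str, str, str]
    edges_upper: np.ndarray  # interior edges (s); empty => single bin
    counts_upper: np.ndarray
    edges_lower: np.ndarray
    counts_lower: np.ndarray
    n_scored: int
    n_miss: int
    # cell-level moment summaries used for starting values
    p_correct: float = 0.5
    mean_rt: float = 1.0
    var_rt: float = 0.05
    min_rt: float = 0.5


@dataclass
class BinnedData:
    cells: dict
    quantiles: tuple
    n_scored: int
    n_miss: int
    min_rt: float


def _side_bins(rts: np.ndarray, quantiles) -> tuple[np.ndarray, np.ndarray]:
    n = rts.size
    if n < MIN_SIDE:
        return np.empty(0), np.array([n], dtype=float)
    srt = np.sort(rts)
    edges = np.unique(np.quantile(srt, quantiles))
    counts = np.diff(np.concatenate([[0], np.searchsorted(srt, edges, side="right"), [n]]))
    return edges, counts.astype(float)


def bin_rts(records: pd.DataFrame, quantiles=DEFAULT_QUANTILES) -> BinnedData:
    """Bin one subject's scored RTs by quantiles within cell and response side.

    Sides with fewer than ``MIN_SIDE`` trials collapse to a single bin
    whose expected probability is the whole defective mass of that side
    (so e.g. an all-correct cell still contributes its error-side hit
    probability).  Counts are conserved: per cell they sum to the number
    of scored (non-miss) trials.
    """
    quantiles = tuple(sorted(quantiles))
    cells = {}
    for cell, grp in records.groupby(["beneficiary", "payoff", "difficulty"], sort=False):
        scored = grp[~grp["miss"]]
        if len(scored) == 0:
            raise FitError(f"condition cell {cell} has no scored trials")
        if len(scored) < MIN_SIDE:
            warnings.warn(f"cell {cell}: only {len(scored)} scored trials; bins merged")
        rt = scored["rt_ms"].to_numpy(dtype=float) / 1000.0
        cor = scored["correct"].to_numpy(dtype=bool)
        e_up, c_up = _side_bins(rt[cor], quantiles)
        e_lo, c_lo = _side_bins(rt[~cor], quantiles)
        rc = rt[cor] if cor.any() else rt
        cells[cell] = CellBins(
            cell=cell,
            edges_upper=e_up,
            counts_upper=c_up,
            edges_lower=e_lo,
            counts_lower=c_lo,
            n_scored=len(scored),
            n_miss=int(grp["miss"].sum()),
            p_correct=float(cor.mean()),
            mean_rt=float(rc.mean()),
            var_rt=float(rc.var(ddof=1)) if rc.size > 1 else 0.01,
            min_rt=float(rt.min()),
        )
    if not cells:
        raise FitError("no trials to bin")
    return BinnedData(
        cells=cells,
        quantiles=quantiles,
        n_scored=int(sum(c.n_scored for c in cells.values())),
        n_miss=int(sum(c.n_miss for c in cells.values())),
        min_rt=float(min(c.min_rt for c in cells.values())),
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _side_probs(edges, a, v, z, s, ter, boundary, p_side):
    if edges.size == 0:
        return np.array([p_side])
    F = _fpt_cdf(np.maximum(edges - ter, 0.0), a, v, z, s, boundary)
    return np.diff(np.concatenate([[0.0], F, [p_side]]))


def _cell_nll(bins: CellBins, a, v, ter, s, w=0.5):
    """Negative multinomial log-likelihood of one cell (constants dropped)."""
    z = w * a
    p_up = _hit_upper(a, v, z, s)
    probs = np.concatenate(
        [
            _side_probs(bins.edges_upper, a, v, z, s, ter, "upper", p_up),
            _side_probs(bins.edges_lower, a, v, z, s, ter, "lower", 1.0 - p_up),
        ]
    )
    counts = np.concatenate([bins.counts_upper, bins.counts_lower])
    floored = probs < PROB_FLOOR
    nll = -float(counts @ np.log(np.maximum(probs, PROB_FLOOR)))
    return nll, int(np.count_nonzero(floored & (counts > 0)))


def multinomial_loglik(params: dict, binned: BinnedData) -> float:
    """Total log-likelihood of per-cell :class:`DDMParams` given binned data.

    Additive over cells and bins (``sum count * ln p_bin``); expected bin
    probabilities are floored at ``1e-10`` before the log.  Misses are not
    part of the likelihood.
    """
    total = 0.0
    for cell, bins in binned.cells.items():
        p = params[cell]
        nll, _ = _cell_nll(bins, p.a, p.v, p.ter, p.s, w=p.z / p.a)
        total -= nll
    return total


# ---------------------------------------------------------------------------
# Moment-based starting values (EZ-style closed forms; starts only)
# ---------------------------------------------------------------------------

def ez_estimate(p_correct: float, var_rt: float, mean_rt: float, n: int, s: float):
    """Closed-form moment estimates of (a, v, ter) for an unbiased process.

    Used exclusively to seed the likelihood optimiser.  The edge-corrected
    accuracy enters a logit; degenerate inputs fall back to mild defaults.
    """
    pc = min(max(p_correct, 0.5 + 1.0 / (2.0 * max(n, 2))), 1.0 - 1.0 / (2.0 * max(n, 2)))
    vrt = max(var_rt, 1e-4)
    L = np.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    if x <= 0:
        return 0.1, 0.1, max(0.1, mean_rt - 0.3)
    v = s * x**0.25
    a = s * s * L / v
    y = -v * a / (s * s)
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    ter = mean_rt - mdt
    return float(a), float(v), float(ter)


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one subject."""

    model: str
    subject: int
    params: pd.DataFrame  # per-cell a, v, z, ter, s
    loglik: float
    k: int
    n: int
    bic: float
    converged: bool
    n_miss: int
    floor_hits: int
    n_starts: int
    message: str = ""

    def cell_params(self) -> dict:
        out = {}
        for cell, row in self.params.iterrows():
            out[tuple(cell)] = DDMParams(
                a=row["a"], v=row["v"], z=row["z"], ter=row["ter"], s=row["s"]
            )
        return out


class _Problem:
    """Nested profile-likelihood optimisation for one subject/model."""

    def __init__(self, binned: BinnedData, spec: ModelSpec, s: float, bounds: dict, w_free: bool = False):
        self.binned = binned
        self.spec = spec
        self.s = s
        self.bounds = bounds
        self.w_free = w_free
        self.cells = list(binned.cells)
        self.warm: dict = {}  # cell -> last free-parameter vector
        self.ez = {c: ez_estimate(b.p_correct, b.var_rt, b.mean_rt, b.n_scored, s)
                   for c, b in binned.cells.items()}
        # when Ter is free per cell its upper bound is that cell's own
        # fastest RT, not the subject-wide minimum
        self.cell_ter_hi = {c: b.min_rt - 1e-3 for c, b in binned.cells.items()}

    def _cell_bounds(self, cell) -> dict:
        b = dict(self.bounds)
        if "ter" in self.spec.cell_free:
            b["ter"] = (b["ter"][0], self.cell_ter_hi[cell])
        return b

    # -- assemble per-cell parameter dict from shared + free values -------
    def _cell_theta(self, cell, shared: dict, free_vals: np.ndarray) -> dict:
        theta = dict(shared)
        for name, val in zip(self.spec.cell_free, free_vals):
            theta[name] = val
        theta.setdefault("w", 0.5)
        return theta

    def _nll_cell(self, cell, theta: dict):
        nll, hits = _cell_nll(
            self.binned.cells[cell], theta["a"], theta["v"], theta["ter"], self.s, w=theta["w"]
        )
        return nll, hits

    def _cell_start(self, cell, shared: dict) -> np.ndarray:
        a0, v0, t0 = self.ez[cell]
        defaults = {"a": a0, "v": v0, "ter": t0, "w": 0.5}
        lo_hi = self._cell_bounds(cell)
        return np.array(
            [np.clip(defaults[k], lo_hi[k][0] + 1e-6, lo_hi[k][1] - 1e-6) for k in self.spec.cell_free]
        )

    def _fit_cell(self, cell, shared: dict):
        free = self.spec.cell_free
        cb = self._cell_bounds(cell)
        bnds = [cb[k] for k in free]

        def obj(x):
            return self._nll_cell(cell, self._cell_theta(cell, shared, x))[0]

        starts = []
        if cell in self.warm:
            starts.append(self.warm[cell])
        starts.append(self._cell_start(cell, shared))

        if len(free) == 1:
            res = optimize.minimize_scalar(
                lambda x: obj(np.array([x])), bounds=bnds[0], method="bounded",
                options={"xatol": 1e-6},
            )
            best_x, best_f = np.array([res.x]), res.fun
        else:
            best_x, best_f = None, np.inf
            for x0 in starts[:1] if cell in self.warm else starts:
                res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bnds,
                                        options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-7})
                if res.fun < best_f:
                    best_x, best_f = res.x, res.fun
        self.warm[cell] = best_x
        return best_x, best_f

    def profile(self, shared_vals: np.ndarray):
        """Best achievable NLL for given shared-parameter values."""
        names = self.spec.shared + (("w",) if self.w_free else ())
        shared = dict(zip(names, shared_vals))
        for name, val in shared.items():
            lo, hi = self.bounds[name]
            if not lo <= val <= hi:
                return 1e9 + 1e9 * (abs(val - np.clip(val, lo, hi))), None
        total = 0.0
        sols = {}
        for cell in self.cells:
            x, f = self._fit_cell(cell, shared)
            sols[cell] = x
            total += f
        return total, sols

    def evaluate(self, params: dict):
        """NLL (and floor hits) of an explicit per-cell parameter dict."""
        total, hits = 0.0, 0
        for cell in self.cells:
            p = params[cell]
            nll, h = self._nll_cell(
                cell, {"a": p.a, "v": p.v, "ter": p.ter, "w": p.z / p.a}
            )
            total += nll
            hits += h
        return total, hits


def _result_params(problem: _Problem, shared: dict, sols: dict, s: float) -> pd.DataFrame:
    rows = []
    for cell in problem.cells:
        theta = problem._cell_theta(cell, shared, sols[cell])
        a = theta["a"]
        rows.append((*cell, a, theta["v"], theta["w"] * a, theta["ter"], s))
    df = pd.DataFrame(rows, columns=["beneficiary", "payoff", "difficulty", "a", "v", "z", "ter", "s"])
    return df.set_index(["beneficiary", "payoff", "difficulty"])


def _check_units(binned: BinnedData):
    rts = [b.mean_rt for b in binned.cells.values()]
    if max(rts) > 30.0:
        raise FitError(
            "RTs look like milliseconds after conversion (mean > 30 s); "
            "the trial table must store rt_ms in integer milliseconds"
        )
    if binned.min_rt <= _BOUNDS["a"][0] + 0.1:
        raise FitError(
            f"minimum RT {binned.min_rt:.4f}s leaves no room for the non-decision-time "
            "bound Ter in (0.1, min RT); RT units are probably wrong"
        )


def fit_subject(
    records: pd.DataFrame,
    model: str = "v_free",
    quantiles=DEFAULT_QUANTILES,
    starts: int = 3,
    seed: int = 0,
    s: float = 0.1,
    warm: "FitResult | None" = None,
) -> FitResult:
    """Fit one parameter-freeing scheme to one subject's trials.

    Multi-start bounded optimisation: jittered EZ-style moment estimates
    seed an outer search over the shared parameters with per-cell profile
    optimisation inside.  ``warm`` may carry a simpler nested model's fit;
    its solution is always evaluated as a candidate, which guarantees the
    richer model's maximised likelihood is no worse.  Under every scheme
    the starting point is fixed at ``z = a/2`` exactly.
    """
    spec = MODELS[model]
    subjects = records["subject"].unique()
    if len(subjects) != 1:
        raise FitError(f"fit_subject expects a single subject, got {len(subjects)}")
    binned = bin_rts(records, quantiles)
    _check_units(binned)
    rng = np.random.default_rng(seed)

    ter_hi = binned.min_rt - 1e-3
    bounds = dict(_BOUNDS)
    bounds["ter"] = (0.1, ter_hi)
    if ter_hi <= bounds["ter"][0]:
        raise FitError(f"minimum RT {binned.min_rt:.3f}s is below the Ter lower bound")

    prob = _Problem(binned, spec, s, bounds)
    ez = np.array(list(prob.ez.values()))
    a0 = float(np.clip(np.median(ez[:, 0]), 0.02, 0.4))
    t0 = float(np.clip(np.median(ez[:, 2]), 0.11, ter_hi - 1e-3))

    shared_names = spec.shared
    best_f, best_sols, best_shared, n_ok = np.inf, None, None, 0

    def _starts():
        yield {"a": a0, "ter": t0}
        for _ in range(max(starts - 1, 0)):
            yield {
                "a": float(np.clip(a0 * np.exp(rng.normal(0, 0.25)), 0.011, 0.45)),
                "ter": float(np.clip(t0 + rng.normal(0, 0.05), 0.105, ter_hi - 1e-3)),
            }

    if not shared_names:
        # fully cell-separable: independent per-cell fits, multi-start
        total, sols = prob.profile(np.empty(0))
        for _ in range(max(starts - 1, 0)):
            prob.warm = {
                c: prob.warm[c] * np.exp(rng.normal(0, 0.15, size=prob.warm[c].size))
                for c in prob.warm
            }
            t2, s2 = prob.profile(np.empty(0))
            if t2 < total:
                total, sols = t2, s2
        best_f, best_sols, best_shared, n_ok = total, sols, {}, 1
    elif len(shared_names) == 1:
        name = shared_names[0]
        for st in _starts():
            res = optimize.minimize_scalar(
                lambda x: prob.profile(np.array([x]))[0],
                bounds=bounds[name], method="bounded", options={"xatol": 1e-5},
            )
            f, sols = prob.profile(np.array([res.x]))
            n_ok += int(res.success)
            if f < best_f:
                best_f, best_sols, best_shared = f, sols, {name: float(res.x)}
    else:
        for st in _starts():
            x0 = np.array([st[n] for n in shared_names])
            res = optimize.minimize(
                lambda x: prob.profile(x)[0], x0, method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 250},
            )
            f, sols = prob.profile(res.x)
            n_ok += int(res.success)
            if f < best_f:
                best_f, best_sols, best_shared = f, sols, dict(zip(shared_names, res.x))

    if best_sols is None:
        raise FitError(f"all {starts} starts failed for model {model!r}")

    params = _result_params(prob, {**best_shared, "w": 0.5}, best_sols, s)
    loglik = -best_f
    floor_hits = prob.evaluate(
        {tuple(c): DDMParams(a=r["a"], v=r["v"], z=r["z"], ter=r["ter"], s=r["s"])
         for c, r in params.iterrows()}
    )[1]

    # a nested (simpler) model's optimum is a feasible point of this model:
    # keep whichever is better, so nesting holds by construction
    if warm is not None:
        warm_nll, warm_hits = prob.evaluate(warm.cell_params())
        if warm_nll < best_f:
            loglik = -warm_nll
            params = warm.params.copy()
            floor_hits = warm_hits

    n = binned.n_scored
    return FitResult(
        model=model,
        subject=int(subjects[0]),
        params=params,
        loglik=float(loglik),
        k=spec.k,
        n=n,
        bic=bic(loglik, spec.k, n),
        converged=bool(n_ok > 0),
        n_miss=binned.n_miss,
        floor_hits=int(floor_hits),
        n_starts=starts,
        message="" if n_ok > 0 else "no optimizer start reported success",
    )


def fit_all_models(
    records: pd.DataFrame,
    models=("v_free", "v_a_free", "v_ter_free", "full"),
    quantiles=DEFAULT_QUANTILES,
    starts: int = 3,
    seed: int = 0,
    s: float = 0.1,
) -> dict:
    """Fit several schemes to one subject, warm-starting up the hierarchy.

    ``v_free`` is fitted first; richer models receive it (and the best
    intermediate model, for ``full``) as warm candidates, which enforces
    the nesting of maximised likelihoods.
    """
    out: dict[str, FitResult] = {}
    order = [m for m in ("v_free", "v_a_free", "v_ter_free", "full") if m in models]
    for m in order:
        if m == "v_free":
            warm = None
        elif m == "full":
            cands = [out[x] for x in ("v_a_free", "v_ter_free", "v_free") if x in out]
            warm = max(cands, key=lambda r: r.loglik) if cands else None
        else:
            warm = out.get("v_free")
        out[m] = fit_subject(records, m, quantiles=quantiles, starts=starts, seed=seed, s=s, warm=warm)
    return {m: out[m] for m in models}


# ---------------------------------------------------------------------------
# Starting-point symmetry check
# ---------------------------------------------------------------------------

def bias_check(
    records: pd.DataFrame,
    quantiles=DEFAULT_QUANTILES,
    starts: int = 2,
    seed: int = 0,
    s: float = 0.1,
) -> dict:
    """Estimate the starting point separately for left and right trials.

    For each stimulus direction the subset of trials is fitted with a
    shared boundary, non-decision time and *free* relative start ``w``
    (drift per cell).  With symmetric responding both sides return
    ``z ~ a/2``; a start shifted toward one boundary splits them.  Returns
    ``{"z_left", "z_right", "a_left", "a_right", "w_left", "w_right"}``.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for side in ("left", "right"):
        sub = records[records["direction"] == side]
        binned = bin_rts(sub, quantiles)
        _check_units(binned)
        bounds = dict(_BOUNDS)
        bounds["ter"] = (0.1, binned.min_rt - 1e-3)
        spec = ModelSpec("bias", ("v",), ("a", "ter"))
        prob = _Problem(binned, spec, s, bounds, w_free=True)
        ez = np.array(list(prob.ez.values()))
        a0 = float(np.clip(np.median(ez[:, 0]), 0.02, 0.4))
        t0 = float(np.clip(np.median(ez[:, 2]), 0.11, binned.min_rt - 2e-3))
        best = None
        for i in range(starts):
            jit = rng.normal(0, [0.15, 0.03, 0.05]) if i else np.zeros(3)
            x0 = np.array([a0 * np.exp(jit[0]), np.clip(t0 + jit[1], 0.105, binned.min_rt - 2e-3), 0.5 + jit[2]])
            res = optimize.minimize(
                lambda x: prob.profile(x)[0], x0, method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 300},
            )
            if best is None or res.fun < best.fun:
                best = res
        a_hat, ter_hat, w_hat = best.x
        w_hat = float(np.clip(w_hat, *_BOUNDS["w"]))
        out[f"a_{side}"] = float(a_hat)
        out[f"w_{side}"] = w_hat
        out[f"z_{side}"] = w_hat * float(a_hat)
        out[f"ter_{side}"] = float(ter_hat)
    return out


# ---------------------------------------------------------------------------
# Posterior predictive simulation
# ---------------------------------------------------------------------------

def predictive_check(
    fit: FitResult,
    records: pd.DataFrame,
    rng: np.random.Generator,
    deadline_ms: float = 2000.0,
    step: float = 5e-4,
):
    """Simulate data from the fitted parameters and compare to the observed.

    Runs the diffusion process per cell with the estimated parameters on
    the subject's own trial counts; returns ``(simulated, summary)`` where
    ``summary`` has per-cell observed/simulated accuracy and RT-quantile
    discrepancies (correct responses, at the fit's quantiles).
    """
    qs = DEFAULT_QUANTILES
    sim_rows, sum_rows = [], []
    deadline_s = deadline_ms / 1000.0
    for cell, grp in records.groupby(["beneficiary", "payoff", "difficulty"], sort=False):
        p = fit.cell_params()[cell]
        n = len(grp)
        bnd, dt = simulate_trials(p, n, rng, step=step, max_time=deadline_s - p.ter)
        rt = p.ter + dt
        miss = (bnd == 0) | (rt > deadline_s)
        correct = (bnd == 1) & ~miss
        for c, m, r in zip(correct, miss, rt):
            sim_rows.append((fit.subject, *cell, bool(c), bool(m), np.nan if m else r * 1000.0))
        scored = grp[~grp["miss"]]
        obs_acc = scored["correct"].mean()
        sim_acc = correct[~miss].mean() if (~miss).any() else np.nan
        obs_rt = scored.loc[scored["correct"], "rt_ms"].to_numpy(dtype=float)
        sim_rt = rt[correct] * 1000.0
        dq = (
            np.quantile(sim_rt, qs) - np.quantile(obs_rt, qs)
            if obs_rt.size and sim_rt.size
            else np.full(len(qs), np.nan)
        )
        sum_rows.append((*cell, n, float(obs_acc), float(sim_acc), *dq))
    simulated = pd.DataFrame(
        sim_rows, columns=["subject", "beneficiary", "payoff", "difficulty", "correct", "miss", "rt_ms"]
    )
    summary = pd.DataFrame(
        sum_rows,
        columns=["beneficiary", "payoff", "difficulty", "n", "acc_observed", "acc_predicted"]
        + [f"d_rt_q{int(q * 100)}" for q in qs],
    )
    return simulated, summary
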