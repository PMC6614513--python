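"""Descriptive and inferential statistics for the factorial task.

Implements the analysis chain applied to behavior and to fitted
parameters alike: per-cell summaries (sensitivity, decimal-log RT split
by correct/error), Lilliefors normality screening with Monte-Carlo
p-values, repeated-measures ANOVAs for fully within-subject two-level
factorial layouts, unadjusted Fisher-LSD pairwise comparisons, and
Cohen's d effect sizes.

With exclusively two-level factors, every rmANOVA effect (main or
interaction) is a one-degree-of-freedom contrast, and its F statistic is
exactly the square of the paired t on the per-subject contrast scores
(``F_{1,n-1} = t_{n-1}^2``).  The implementation computes effects that
way, which makes the equivalence hold to machine precision and keeps the
statistics free of sphericity concerns.

"Sensitivity" follows the task's operational usage: the proportion of
correct direction judgments per cell (misses score as incorrect).  A true
signal-detection d' (z of rightward-response rate on rightward minus
leftward stimuli) is available separately as :func:`dprime_sdt`.
"""

from __future__ import annotations

import itertools
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conditions import FACTORS
from .errors import DegenerateDataError

__all__ = [
    "summarize_cells",
    "dprime_sdt",
    "lilliefors",
    "lilliefors_statistic",
    "rm_anova",
    "contrast_f",
    "lsd_posthoc",
    "cohens_d",
]

#: Sign conventions for per-subject contrast scores: first-listed level is +1.
_LEVEL_SIGN = {
    "beneficiary": {"self": 1, "other": -1},
    "payoff": {"high": 1, "low": -1},
    "difficulty": {"easy": 1, "difficult": -1},
}


# ---------------------------------------------------------------------------
# Cell summaries
# ---------------------------------------------------------------------------

def summarize_cells(records: pd.DataFrame, fits: dict | None = None) -> pd.DataFrame:
    """Per-subject, per-cell summary table.

    Sensitivity is correct/(all trials of the cell), so a miss counts as
    an error; RT means are decimal logs of the trial RTs in ms, computed
    separately for correct and error responses and absent (NaN) when a
    side has no trials.  If ``fits`` maps subject -> FitResult, the fitted
    ``log10_v`` per cell is joined in.
    """
    rows = []
    for (sid, *cell), grp in records.groupby(
        ["subject", "beneficiary", "payoff", "difficulty"], sort=True
    ):
        scored = grp[~grp["miss"]]
        rt = scored["rt_ms"].to_numpy(dtype=float)
        cor = scored["correct"].to_numpy(dtype=bool)
        log_rt = np.log10(rt)
        rows.append(
            {
                "subject": sid,
                "beneficiary": cell[0],
                "payoff": cell[1],
                "difficulty": cell[2],
                "n_trials": len(grp),
                "n_miss": int(grp["miss"].sum()),
                "sensitivity": float(grp["correct"].sum() / len(grp)),
                "log_rt_correct": float(log_rt[cor].mean()) if cor.any() else np.nan,
                "log_rt_error": float(log_rt[~cor].mean()) if (~cor).any() else np.nan,
                "mean_rt_correct": float(rt[cor].mean()) if cor.any() else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    counts = table.groupby("subject").size()
    bad = counts[counts != 8]
    if len(bad):
        raise ValueError(f"subjects missing condition cells: {dict(bad)}")
    if fits is not None:
        frames = []
        for sid, fr in fits.items():
            p = fr.params.reset_index()
            p["subject"] = sid
            with np.errstate(invalid="ignore"):
                p["log10_v"] = np.log10(p["v"].where(p["v"] > 0))
            if (p["v"] <= 0).any():
                warnings.warn(f"subject {sid}: non-positive fitted drift; log10_v set NaN")
            frames.append(p[["subject", "beneficiary", "payoff", "difficulty", "log10_v", "a", "ter"]])
        table = table.merge(pd.concat(frames), on=["subject", "beneficiary", "payoff", "difficulty"], how="left")
    return table


def dprime_sdt(records: pd.DataFrame) -> pd.DataFrame:
    """Signal-detection d' per subject and cell (secondary metric).

    Treats "rightward" as the signal: d' = z(P(resp right | right)) -
    z(P(resp right | left)), with the standard 1/(2N) edge correction.
    """
    rows = []
    for (sid, *cell), grp in records.groupby(
        ["subject", "beneficiary", "payoff", "difficulty"], sort=True
    ):
        scored = grp[~grp["miss"]]
        out = {}
        for d in ("right", "left"):
            sub = scored[scored["direction"] == d]
            n = max(len(sub), 1)
            p = (sub["response"] == "right").mean() if len(sub) else 0.5
            out[d] = np.clip(p, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
        rows.append(
            {
                "subject": sid,
                "beneficiary": cell[0],
                "payoff": cell[1],
                "difficulty": cell[2],
                "dprime": float(sps.norm.ppf(out["right"]) - sps.norm.ppf(out["left"])),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lilliefors normality test (Monte-Carlo null)
# ---------------------------------------------------------------------------

def lilliefors_statistic(x: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to a normal with estimated mean and SD."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("constant sample: normality test undefined")
    z = sps.norm.cdf((x - x.mean()) / sd)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - z, z - (i - 1) / n)))


@lru_cache(maxsize=32)
def _lilliefors_null(n: int, n_null: int, seed: int) -> np.ndarray:
    """Simulated null distribution of the statistic (distribution-free)."""
    rng = np.random.default_rng(seed)
    sample = rng.standard_normal((n_null, n))
    sample.sort(axis=1)
    mu = sample.mean(axis=1, keepdims=True)
    sd = sample.std(axis=1, ddof=1, keepdims=True)
    z = sps.norm.cdf((sample - mu) / sd)
    i = np.arange(1, n + 1)
    d = np.maximum(i / n - z, z - (i - 1) / n).max(axis=1)
    d.sort()
    return d

def lilliefors(x, n_null: int = 10_000, seed: int = 12345) -> tuple[float, float]:
    """Lilliefors test of composite normality; returns ``(statistic, p)``.

    The p-value comes from a Monte-Carlo null of ``n_null`` standard-normal
    samples of the same size (fixed seed, cached per sample size), using
    the add-one estimator ``p = (1 + #{D0 >= D}) / (n_null + 1)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise DegenerateDataError("Lilliefors test needs n >= 5")
    d = lilliefors_statistic(x)
    null = _lilliefors_null(x.size, n_null, seed)
    exceed = null.size - np.searchsorted(null, d, side="left")
    return d, float((1 + exceed) / (n_null + 1))


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA via per-subject contrasts
# ---------------------------------------------------------------------------

def contrast_f(scores: np.ndarray) -> tuple[float, float, int]:
    """F, p, df2 for a one-df within-subject contrast (t-squared identity)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    se = scores.std(ddof=1) / np.sqrt(n)
    if se == 0:
        raise DegenerateDataError("zero-variance contrast")
    f = float((scores.mean() / se) ** 2)
    p = float(sps.f.sf(f, 1, n - 1))
    return f, p, n - 1


def _wide(cells: pd.DataFrame, dv: str, factors) -> tuple[np.ndarray, list]:
    levels = [FACTORS[f] for f in factors]
    combos = list(itertools.product(*levels))
    piv = cells.pivot_table(index="subject", columns=list(factors), values=dv, aggfunc="mean")
    piv = piv.dropna(axis=0, how="any")
    missing = [c for c in combos if (c if len(c) > 1 else c[0]) not in piv.columns]
    if missing:
        raise ValueError(f"incomplete within-subject layout; missing cells: {missing}")
    mat = np.column_stack(
        [piv[c if len(c) > 1 else c[0]].to_numpy(dtype=float) for c in combos]
    )
    return mat, combos


def rm_anova(cells: pd.DataFrame, dv: str, factors=("beneficiary", "payoff", "difficulty"),
             d_method: str = "av") -> pd.DataFrame:
    """Repeated-measures ANOVA for a fully within-subject 2^k layout.

    Every main effect and interaction is computed as a per-subject
    contrast score (difference of the subject's means over the +1 and -1
    cells, with interaction signs multiplying); the F statistic is the
    squared paired t on those scores, ``df = (1, n-1)``.  Cohen's d uses
    the averaged-SD convention by default (``d_method="diff"`` divides by
    the SD of the difference scores instead).

    Returns one row per effect: F, df, p, Cohen's d and the two marginal
    means entering the contrast.
    """
    mat, combos = _wide(cells, dv, factors)
    n = mat.shape[0]
    if n < 2:
        raise DegenerateDataError("rmANOVA needs at least 2 subjects")
    rows = []
    for r in range(1, len(factors) + 1):
        for eff in itertools.combinations(range(len(factors)), r):
            signs = np.array(
                [
                    np.prod([_LEVEL_SIGN[factors[i]][combo[i]] for i in eff])
                    for combo in combos
                ]
            )
            plus = mat[:, signs > 0].mean(axis=1)
            minus = mat[:, signs < 0].mean(axis=1)
            f, p, df2 = contrast_f(plus - minus)
            rows.append(
                {
                    "effect": ":".join(factors[i] for i in eff),
                    "F": f,
                    "df1": 1,
                    "df2": df2,
                    "p": round(p, 6),
                    "cohens_d": cohens_d(plus, minus, method=d_method),
                    "mean_plus": float(plus.mean()),
                    "mean_minus": float(minus.mean()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher LSD post hocs and effect sizes
# ---------------------------------------------------------------------------

def lsd_posthoc(cells: pd.DataFrame, dv: str, factors=("beneficiary", "payoff"),
                omnibus_p: float | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Unadjusted pairwise comparisons among the cells of a layout.

    Fisher's LSD procedure: pairwise paired t tests with no multiplicity
    correction, gated on a significant omnibus effect.  If ``omnibus_p``
    is supplied and not significant the table is empty (with a warning),
    matching the procedure's protected logic.  The error term is the
    paired-contrast SD (repeated-measures-safe), not a pooled
    between-cell MSE.
    """
    if omnibus_p is not None and omnibus_p > alpha:
        warnings.warn(
            f"omnibus p={omnibus_p:.4f} > alpha={alpha}: LSD comparisons not protected; "
            "returning empty table"
        )
        return pd.DataFrame(
            columns=["cell_1", "cell_2", "mean_1", "mean_2", "diff", "t", "df", "p", "cohens_d"]
        )
    mat, combos = _wide(cells, dv, factors)
    n = mat.shape[0]
    rows = []
    for i, j in itertools.combinations(range(len(combos)), 2):
        d = mat[:, i] - mat[:, j]
        sd = d.std(ddof=1)
        if sd == 0:
            t, p = (0.0, 1.0)
        else:
            t = float(d.mean() / (sd / np.sqrt(n)))
            p = float(2 * sps.t.sf(abs(t), n - 1))
        rows.append(
            {
                "cell_1": "/".join(combos[i]),
                "cell_2": "/".join(combos[j]),
                "mean_1": float(mat[:, i].mean()),
                "mean_2": float(mat[:, j].mean()),
                "diff": float(d.mean()),
                "t": t,
                "df": n - 1,
                "p": round(p, 6),
                "cohens_d": cohens_d(mat[:, i], mat[:, j]) if sd > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def cohens_d(x, y, method: str = "av") -> float:
    """Cohen's d for paired condition scores.

    ``method="av"`` (default): mean difference over the average of the two
    condition SDs, ``(mx - my) / sqrt((sx^2 + sy^2) / 2)``.
    ``method="diff"``: mean difference over the SD of the difference
    scores.  The two diverge when conditions are highly correlated; both
    are legitimate conventions for within-subject designs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    if method == "av":
        denom = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    elif method == "diff":
        denom = (x - y).std(ddof=1)
    else:
        raise ValueError(f"unknown Cohen's d method {method!r}")
    if denom == 0 or not np.isfinite(denom):
        if mx == my:
            return 0.0
        raise DegenerateDataError("zero variance: Cohen's d undefined")
    return float((mx - my) / denom)
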