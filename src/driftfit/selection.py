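"""BIC computation and two-level model comparison.

Model comparison happens at two levels, mirroring standard practice for
per-subject diffusion fits: (i) the BIC summed over subjects ranks the
candidate parameter-freeing schemes for the cohort, and (ii) a per-subject
tally counts how many individuals each scheme fits best.  BIC is always
computed per subject (never on pooled likelihoods), with ``n`` the number
of scored (non-miss) trials of that subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["bic", "select", "SelectionReport"]

#: |delta BIC| below this is treated as a tie (broken toward fewer parameters).
TIE_TOL = 0.01


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian Information Criterion ``-2 loglik + k ln(n)``.

    ``k`` is the number of estimated parameters, ``n`` the number of
    observations entering the likelihood (scored trials).
    """
    if n <= 0:
        raise ValueError("BIC requires n > 0")
    if k < 1:
        raise ValueError("BIC requires k >= 1")
    return float(-2.0 * loglik + k * np.log(n))


@dataclass
class SelectionReport:
    """Outcome of the two-level BIC comparison across subjects."""

    bic_sums: pd.Series  # model -> summed BIC
    per_subject: pd.DataFrame  # subject x model BIC + best column
    best_counts: pd.Series  # model -> number of subjects best fitted
    winner: str
    ties: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["BIC sums across subjects:"]
        for m, v in self.bic_sums.sort_values().items():
            flag = "  <- winner" if m == self.winner else ""
            lines.append(f"  {m:12s} {v:12.1f}{flag}")
        lines.append("Per-subject best-model counts:")
        for m, c in self.best_counts.items():
            lines.append(f"  {m:12s} {int(c):3d}")
        if self.ties:
            lines.append(f"Ties (|dBIC| < {TIE_TOL}) broken toward fewer parameters: {self.ties}")
        return "\n".join(lines)


def select(fits: dict) -> SelectionReport:
    """Rank models by summed BIC and tally per-subject best models.

    ``fits`` maps subject -> {model name -> FitResult}.  Every subject
    must carry the same model set.  Per subject, ties within ``TIE_TOL``
    are broken toward the model with fewer parameters and flagged.
    """
    subjects = sorted(fits)
    if not subjects:
        raise ValueError("no fits supplied")
    models = sorted(fits[subjects[0]])
    for s in subjects:
        missing = [m for m in models if m not in fits[s]]
        extra = [m for m in fits[s] if m not in models]
        if missing or extra:
            raise ValueError(f"subject {s}: inconsistent model set (missing {missing}, extra {extra})")

    rows, best, ties = [], {}, []
    for s in subjects:
        bics = {m: fits[s][m].bic for m in models}
        ks = {m: fits[s][m].k for m in models}
        lo = min(bics.values())
        cand = [m for m in models if bics[m] - lo < TIE_TOL]
        pick = min(cand, key=lambda m: (ks[m], m))
        if len(cand) > 1:
            ties.append((s, tuple(sorted(cand))))
        best[s] = pick
        rows.append({"subject": s, **bics, "best": pick})

    per_subject = pd.DataFrame(rows).set_index("subject")
    bic_sums = per_subject[models].sum()
    best_counts = pd.Series(
        {m: sum(1 for s in subjects if best[s] == m) for m in models}, name="n_best"
    )
    winner = str(bic_sums.idxmin())
    return SelectionReport(
        bic_sums=bic_sums,
        per_subject=per_subject,
        best_counts=best_counts,
        winner=winner,
        ties=ties,
    )
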