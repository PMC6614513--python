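"""Synthetic factorial sessions and simulated trial-level datasets.

The module generates session designs with the task's combinatorial
constraints (4 blocks x 208 trials; 26 trials of each of the 8
Beneficiary x Payoff x Difficulty cells per block; left/right motion
balanced within block with no more than three consecutive trials sharing a
direction) and simulates trial records by running the diffusion process of
:mod:`driftfit.core` with cell-specific parameters under a 2,000 ms
response deadline.

The default scenario is drift-only: all cells of a subject share the
boundary separation, starting point, non-decision time and noise scale,
and only the drift rate differs between cells, on a decimal-log scale
(easy/difficult means -0.76/-0.84, self/other -0.78/-0.82, no payoff main
effect).  Subjects differ by a single normal log10-drift offset.
Alternative scenarios free the non-decision time or the boundary across
difficulty levels, for model-recovery experiments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .conditions import CELLS, DIRECTIONS
from .core import DDMParams, simulate_trials
from .errors import DatasetFormatError, DesignError, ParameterError

__all__ = [
    "ScenarioConfig",
    "SubjectScenario",
    "default_scenario",
    "generate_design",
    "sample_cohort",
    "simulate_subject",
    "simulate_cohort",
    "write_dataset",
    "read_dataset",
    "max_run_length",
]

SCHEMA_VERSION = "driftfit-trials v1"

REQUIRED_COLUMNS = (
    "subject",
    "block",
    "trial",
    "beneficiary",
    "payoff",
    "difficulty",
    "direction",
    "iti_ms",
    "response",
    "correct",
    "rt_ms",
    "miss",
)


# ---------------------------------------------------------------------------
# Session design
# ---------------------------------------------------------------------------

def max_run_length(directions) -> int:
    """Length of the longest run of identical consecutive entries."""
    best = run = 0
    prev = None
    for d in directions:
        run = run + 1 if d == prev else 1
        prev = d
        best = max(best, run)
    return best


def _constrained_directions(rng, n_left, n_right, max_run, carry_dir, carry_run, max_retries):
    """Balanced direction sequence with a run-length bound.

    Sequential urn draws: at each position a direction is sampled with
    probability proportional to its remaining count, excluding any
    direction that would create a run longer than ``max_run`` (runs carry
    over from the previous block via ``carry_dir``/``carry_run``).  Dead
    ends (the only legal direction has no remaining trials) restart the
    sequence; a whole-sequence rejection sampler would be hopeless here
    because balanced 208-trial sequences almost surely contain a run of
    four.
    """
    for _ in range(max_retries):
        counts = {"left": n_left, "right": n_right}
        seq = []
        run_dir, run_len = carry_dir, carry_run
        ok = True
        for _pos in range(n_left + n_right):
            allowed = [d for d in DIRECTIONS if counts[d] > 0]
            if run_len >= max_run and run_dir in allowed and len(allowed) > 1:
                allowed.remove(run_dir)
            elif run_len >= max_run and allowed == [run_dir]:
                ok = False
                break
            weights = np.array([counts[d] for d in allowed], dtype=float)
            d = allowed[rng.choice(len(allowed), p=weights / weights.sum())]
            seq.append(d)
            counts[d] -= 1
            run_len = run_len + 1 if d == run_dir else 1
            run_dir = d
        if ok:
            return seq, run_dir, run_len
    raise DesignError(
        f"could not build a direction sequence obeying run length <= {max_run} "
        f"within {max_retries} attempts"
    )


def generate_design(
    rng: np.random.Generator,
    n_blocks: int = 4,
    trials_per_cell_per_block: int = 26,
    max_run: int = 3,
    iti_range_ms: tuple[int, int] = (800, 1200),
    max_retries: int = 100_000,
) -> pd.DataFrame:
    """Generate one subject's pseudo-randomised session design.

    Returns a frame with one row per trial (columns ``block``, ``trial``,
    ``beneficiary``, ``payoff``, ``difficulty``, ``direction``,
    ``iti_ms``).  Defaults give 4 x 208 = 832 trials, 104 per cell, 26 per
    cell per block, directions 50/50 within block, and no more than
    ``max_run`` consecutive trials sharing a direction (enforced across
    block boundaries as well).  Raises :class:`DesignError` rather than
    silently relaxing a constraint.
    """
    rows = []
    carry_dir, carry_run = None, 0
    per_block = 8 * trials_per_cell_per_block
    for block in range(1, n_blocks + 1):
        cells = np.repeat(np.arange(8), trials_per_cell_per_block)
        rng.shuffle(cells)
        half = per_block // 2
        dirs, carry_dir, carry_run = _constrained_directions(
            rng, half, per_block - half, max_run, carry_dir, carry_run, max_retries
        )
        itis = rng.integers(iti_range_ms[0], iti_range_ms[1] + 1, size=per_block)
        for i, (ci, d, iti) in enumerate(zip(cells, dirs, itis), start=1):
            b, p, diff = CELLS[ci]
            rows.append((block, i, b, p, diff, d, int(iti)))
    return pd.DataFrame(
        rows,
        columns=["block", "trial", "beneficiary", "payoff", "difficulty", "direction", "iti_ms"],
    )


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Population-level generating structure for a synthetic cohort.

    Drift rates are specified on a decimal-log scale as a grand mean plus
    additive factor effects: ``log10 v = log_v_mean
    + log_v_difficulty * (easy ? +1 : -1)
    + log_v_beneficiary * (self ? +1 : -1)
    + log_v_payoff * (high ? +1 : -1) + subject offset``.
    ``ter_difficulty`` / ``a_difficulty`` add ``+effect`` on difficult and
    ``-effect`` on easy trials to the non-decision time (s) or boundary,
    for generating structures where those parameters vary.
    """

    a: float = 0.08
    ter: float = 0.90
    s: float = 0.1
    z_frac: float = 0.5  # start position toward the *right* boundary
    deadline_ms: float = 2000.0
    log_v_mean: float = -0.80
    log_v_difficulty: float = 0.04
    log_v_beneficiary: float = 0.02
    log_v_payoff: float = 0.0
    between_subject_sd: float = 0.08
    ter_difficulty: float = 0.0
    a_difficulty: float = 0.0
    name: str = "drift_only"

    def __post_init__(self):
        if self.between_subject_sd < 0:
            raise ParameterError("between_subject_sd must be >= 0")
        if not 0 < self.z_frac < 1:
            raise ParameterError("z_frac must lie strictly between 0 and 1")
        if self.deadline_ms / 1000.0 <= self.ter + abs(self.ter_difficulty):
            raise ParameterError("deadline must exceed the non-decision time")
        if self.a - abs(self.a_difficulty) <= 0:
            raise ParameterError("a_difficulty too large: boundary must stay positive")
        if self.ter - abs(self.ter_difficulty) < 0:
            raise ParameterError("ter_difficulty too large: Ter must stay non-negative")

    # -- named generating schemes used by recovery experiments ------------
    @classmethod
    def drift_only(cls, **overrides) -> "ScenarioConfig":
        return cls(**{"name": "drift_only", **overrides})

    @classmethod
    def ter_varying(cls, ter_difficulty: float = 0.04, **overrides) -> "ScenarioConfig":
        return cls(ter_difficulty=ter_difficulty, name="ter_varying", **overrides)

    @classmethod
    def a_varying(cls, a_difficulty: float = 0.008, **overrides) -> "ScenarioConfig":
        return cls(a_difficulty=a_difficulty, name="a_varying", **overrides)

    @classmethod
    def null(cls, **overrides) -> "ScenarioConfig":
        """No condition effects at all (type-I error calibration)."""
        return cls(
            log_v_difficulty=0.0,
            log_v_beneficiary=0.0,
            log_v_payoff=0.0,
            name="null",
            **overrides,
        )

    def cell_log_v(self, cell: tuple[str, str, str]) -> float:
        b, p, d = cell
        return (
            self.log_v_mean
            + self.log_v_difficulty * (1 if d == "easy" else -1)
            + self.log_v_beneficiary * (1 if b == "self" else -1)
            + self.log_v_payoff * (1 if p == "high" else -1)
        )

    def cell_params(self, cell: tuple[str, str, str], subject_offset: float = 0.0) -> DDMParams:
        _, _, d = cell
        sgn = 1 if d == "difficult" else -1
        a = self.a + sgn * self.a_difficulty
        ter = self.ter + sgn * self.ter_difficulty
        v = 10.0 ** (self.cell_log_v(cell) + subject_offset)
        return DDMParams(a=a, v=v, z=a / 2.0, ter=ter, s=self.s)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        extra = set(raw) - known
        if extra:
            raise ParameterError(f"unknown scenario keys: {sorted(extra)}")
        return cls(**raw)


def default_scenario(**overrides) -> ScenarioConfig:
    """The calibrated drift-only scenario (the package's study conditions)."""
    return ScenarioConfig.drift_only(**overrides)


@dataclass(frozen=True)
class SubjectScenario:
    """One subject's generating parameters: a DDMParams per condition cell."""

    subject: int
    params: dict  # cell tuple -> DDMParams
    deadline_ms: float = 2000.0
    z_frac: float = 0.5

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for cell, p in self.params.items():
            rows.append(
                (self.subject, *cell, p.a, p.v, np.log10(p.v), p.ter)
            )
        return pd.DataFrame(
            rows,
            columns=["subject", "beneficiary", "payoff", "difficulty", "a", "v", "log10_v", "ter"],
        )


def sample_cohort(
    scenario: ScenarioConfig, n_subjects: int, rng: np.random.Generator
) -> list[SubjectScenario]:
    """Draw per-subject generating parameters from the scenario population."""
    out = []
    for sid in range(1, n_subjects + 1):
        offset = rng.normal(0.0, scenario.between_subject_sd) if scenario.between_subject_sd else 0.0
        params = {cell: scenario.cell_params(cell, offset) for cell in CELLS}
        out.append(
            SubjectScenario(
                subject=sid,
                params=params,
                deadline_ms=scenario.deadline_ms,
                z_frac=scenario.z_frac,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    design: pd.DataFrame,
    subject: SubjectScenario,
    rng: np.random.Generator,
    step: float = 5e-4,
) -> pd.DataFrame:
    """Simulate one subject's session.

    Trials are run in *direction coding*: the upper boundary is the right
    response, drift is ``+v`` on rightward and ``-v`` on leftward trials,
    and the start sits at ``z_frac * a`` from the left boundary (0.5 =
    unbiased).  A trial whose response would land after the deadline is a
    miss: no RT, response ``"miss"``, scored incorrect.
    """
    deadline_s = subject.deadline_ms / 1000.0
    n = len(design)
    response = np.empty(n, dtype=object)
    rt_ms = np.full(n, np.nan)

    # batch trials sharing a boundary (and hence start point)
    cell_of_row = list(zip(design["beneficiary"], design["payoff"], design["difficulty"]))
    a_of_row = np.array([subject.params[c].a for c in cell_of_row])
    v_of_row = np.array([subject.params[c].v for c in cell_of_row])
    ter_of_row = np.array([subject.params[c].ter for c in cell_of_row])
    sgn = np.where(design["direction"].to_numpy() == "right", 1.0, -1.0)

    for a in np.unique(a_of_row):
        idx = np.flatnonzero(a_of_row == a)
        ref = DDMParams(
            a=a,
            v=v_of_row[idx[0]],
            z=subject.z_frac * a,
            ter=0.0,
            s=next(iter(subject.params.values())).s,
        )
        max_time = deadline_s - ter_of_row[idx].min()
        bnd, dt = simulate_trials(
            ref, idx.size, rng, step=step, max_time=max_time, v=sgn[idx] * v_of_row[idx]
        )
        rt = ter_of_row[idx] + dt
        miss = (bnd == 0) | (rt > deadline_s)
        resp = np.where(bnd == 1, "right", "left").astype(object)
        resp[miss] = "miss"
        response[idx] = resp
        rt_ms[idx] = np.where(miss, np.nan, np.round(rt * 1000.0))

    records = design.copy()
    records.insert(0, "subject", subject.subject)
    records["response"] = response
    records["miss"] = response == "miss"
    records["correct"] = (records["response"] == records["direction"]) & ~records["miss"]
    records["rt_ms"] = pd.array(rt_ms, dtype="Int64")
    return records[list(REQUIRED_COLUMNS)]


def simulate_cohort(
    scenario: ScenarioConfig,
    n_subjects: int,
    rng: np.random.Generator,
    step: float = 5e-4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns ``(records, truth)`` tables.

    Each subject gets a freshly randomised design.  ``truth`` holds the
    generating parameters per subject and cell, retained for parameter-
    recovery analyses.
    """
    subjects = sample_cohort(scenario, n_subjects, rng)
    rec_frames, truth_frames = [], []
    for subj in subjects:
        design = generate_design(rng)
        rec_frames.append(simulate_subject(design, subj, rng, step=step))
        truth_frames.append(subj.truth_frame())
    return (
        pd.concat(rec_frames, ignore_index=True),
        pd.concat(truth_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def write_dataset(records: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV with a schema-version stamp."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise DatasetFormatError(f"trial table lacks required columns: {missing}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        records.to_csv(fh, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_dataset`.

    The round trip is lossless for every schema field.  Malformed rows
    raise :class:`DatasetFormatError` carrying the file line number.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    header_offset = 0
    while header_offset < len(lines) and lines[header_offset].startswith("#"):
        header_offset += 1
    try:
        df = pd.read_csv(io.StringIO("".join(lines[header_offset:])))
    except Exception as exc:  # pandas raises various parser errors
        raise DatasetFormatError(f"{path}: unparseable CSV ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required column(s) {missing}")

    def _line(i: int) -> int:  # 1-based file line of data row i
        return header_offset + 2 + i

    for col, levels in (
        ("beneficiary", {"self", "other"}),
        ("payoff", {"high", "low"}),
        ("difficulty", {"easy", "difficult"}),
        ("direction", {"left", "right"}),
        ("response", {"left", "right", "miss"}),
    ):
        bad = ~df[col].isin(levels)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise DatasetFormatError(
                f"{path}, line {_line(i)}: invalid value {df[col].iloc[i]!r} in column {col!r}"
            )
    try:
        df["rt_ms"] = pd.array(df["rt_ms"], dtype="Int64")
    except Exception as exc:
        raise DatasetFormatError(f"{path}: non-integer rt_ms value ({exc})") from exc
    df["miss"] = df["miss"].astype(bool)
    df["correct"] = df["correct"].astype(bool)
    bad_rt = df["rt_ms"].isna() != df["miss"]
    if bad_rt.any():
        i = int(np.flatnonzero(bad_rt.to_numpy())[0])
        raise DatasetFormatError(
            f"{path}, line {_line(i)}: rt_ms must be empty exactly when miss is true"
        )
    return df[list(REQUIRED_COLUMNS)]
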