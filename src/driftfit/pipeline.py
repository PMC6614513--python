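"""End-to-end orchestration: generate -> fit -> select -> stats -> report.

Also hosts the two validation experiments that justify the whole
analysis: parameter recovery (fit synthetic cohorts whose generating
parameters are known and quantify bias/RMSE/correlation) and model
recovery (simulate under different generating structures and check that
BIC selection identifies the right parameter-freeing scheme).

Randomness is organised as named substreams: the master seed is combined
with a stable hash of the stage name (``generate``, ``fit``, ``stats``,
``predict`` ...), so changing what one stage consumes never perturbs
another stage's draws.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .conditions import CELLS
from .fitting import DEFAULT_QUANTILES, fit_all_models, predictive_check
from .selection import SelectionReport, select
from .stats import rm_anova, summarize_cells
from .synth import ScenarioConfig, default_scenario, generate_design, sample_cohort, simulate_subject, write_dataset

__all__ = [
    "RunConfig",
    "PipelineResult",
    "stage_rng",
    "run_full_pipeline",
    "run_recovery_experiment",
    "run_model_recovery",
    "RecoveryReport",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage.

    The stage name is hashed (sha256, first 4 bytes) and combined with the
    master seed in a SeedSequence, giving reproducible, mutually
    independent streams per stage.
    """
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    n_subjects: int = 38
    scenario: ScenarioConfig = field(default_factory=default_scenario)
    models: tuple = ("v_free", "v_a_free", "v_ter_free", "full")
    quantiles: tuple = DEFAULT_QUANTILES
    starts: int = 2
    predictive: bool = True
    verbose: bool = False

    def manifest(self) -> dict:
        d = asdict(self)
        d["scenario"] = asdict(self.scenario)
        d["package"] = {"driftfit": __version__, "numpy": np.__version__, "pandas": pd.__version__}
        return d

    @classmethod
    def from_manifest(cls, manifest: dict) -> "RunConfig":
        d = {k: v for k, v in manifest.items() if k in cls.__dataclass_fields__}
        d["scenario"] = ScenarioConfig(**manifest["scenario"])
        d["models"] = tuple(d.get("models", ()))
        d["quantiles"] = tuple(d.get("quantiles", DEFAULT_QUANTILES))
        return cls(**d)


@dataclass
class PipelineResult:
    config: RunConfig
    records: pd.DataFrame
    truth: pd.DataFrame
    fits: dict  # subject -> {model -> FitResult}
    selection: SelectionReport
    cells: pd.DataFrame
    anovas: dict  # dv -> rmANOVA table
    predictive: pd.DataFrame | None
    timings: dict

    def fit_table(self, model: str) -> pd.DataFrame:
        frames = []
        for sid, per_model in self.fits.items():
            fr = per_model[model]
            p = fr.params.reset_index()
            p.insert(0, "subject", sid)
            p["loglik"] = fr.loglik
            p["k"] = fr.k
            p["n"] = fr.n
            p["bic"] = fr.bic
            p["converged"] = fr.converged
            frames.append(p)
        return pd.concat(frames, ignore_index=True)

    def write(self, out_dir) -> None:
        """Write every artefact as delimited text plus a YAML manifest."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(self.records, out / "dataset.csv")
        self.truth.to_csv(out / "truth.csv", index=False)
        for m in self.config.models:
            self.fit_table(m).to_csv(out / f"fits_{m}.csv", index=False)
        self.selection.per_subject.to_csv(out / "selection_bic.csv")
        (out / "selection.txt").write_text(self.selection.summary() + "\n")
        self.cells.to_csv(out / "cells.csv", index=False)
        for dv, tab in self.anovas.items():
            tab.to_csv(out / f"anova_{dv}.csv", index=False)
        if self.predictive is not None:
            self.predictive.to_csv(out / "predictive.csv", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.config.manifest(), fh, sort_keys=True)


def _simulate(config: RunConfig):
    rng = stage_rng(config.seed, "generate")
    subjects = sample_cohort(config.scenario, config.n_subjects, rng)
    recs, truths = [], []
    for subj in subjects:
        design = generate_design(rng)
        recs.append(simulate_subject(design, subj, rng))
        truths.append(subj.truth_frame())
    return pd.concat(recs, ignore_index=True), pd.concat(truths, ignore_index=True)


def run_full_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate a cohort, fit every model, select by BIC, run the statistics.

    Stage errors propagate with a stage label.  Identical configs produce
    identical results (and byte-identical files via
    :meth:`PipelineResult.write`).
    """
    timings = {}
    t0 = time.perf_counter()
    try:
        records, truth = _simulate(config)
    except Exception as exc:
        raise RuntimeError(f"[generate] stage failed: {exc}") from exc
    timings["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fits = {}
    try:
        for sid, grp in records.groupby("subject"):
            fits[int(sid)] = fit_all_models(
                grp, models=config.models, quantiles=config.quantiles,
                starts=config.starts, seed=config.seed + int(sid),
            )
            if config.verbose:
                msgs = {m: f"{f.bic:.1f}" for m, f in fits[int(sid)].items()}
                print(f"  subject {sid}: BIC {msgs}")
    except Exception as exc:
        raise RuntimeError(f"[fit] stage failed: {exc}") from exc
    timings["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        report = select(fits)
    except Exception as exc:
        raise RuntimeError(f"[select] stage failed: {exc}") from exc
    timings["select"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        stat_model = "v_free" if "v_free" in config.models else report.winner
        cells = summarize_cells(records, {s: fits[s][stat_model] for s in fits})
        anovas = {
            "sensitivity": rm_anova(cells, "sensitivity"),
            "log_rt_correct": rm_anova(cells, "log_rt_correct"),
            "log10_v": rm_anova(cells, "log10_v"),
        }
        if not cells["log_rt_error"].isna().any():
            anovas["log_rt_error"] = rm_anova(cells, "log_rt_error")
        if "full" in config.models:
            full_cells = summarize_cells(records, {s: fits[s]["full"] for s in fits})
            anovas["full_a"] = rm_anova(full_cells, "a")
            anovas["full_ter"] = rm_anova(full_cells, "ter")
    except Exception as exc:
        raise RuntimeError(f"[stats] stage failed: {exc}") from exc
    timings["stats"] = time.perf_counter() - t0

    predictive = None
    if config.predictive:
        t0 = time.perf_counter()
        try:
            rng = stage_rng(config.seed, "predict")
            frames = []
            for sid, grp in records.groupby("subject"):
                _, summary = predictive_check(
                    fits[int(sid)][stat_model], grp, rng,
                    deadline_ms=config.scenario.deadline_ms,
                )
                summary.insert(0, "subject", sid)
                frames.append(summary)
            predictive = pd.concat(frames, ignore_index=True)
        except Exception as exc:
            raise RuntimeError(f"[predict] stage failed: {exc}") from exc
        timings["predict"] = time.perf_counter() - t0

    return PipelineResult(
        config=config, records=records, truth=truth, fits=fits,
        selection=report, cells=cells, anovas=anovas, predictive=predictive,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Truth-vs-estimate comparison for a recovery experiment."""

    comparison: pd.DataFrame  # one row per subject x cell
    metrics: pd.DataFrame  # one row per trials-per-cell level

    def summary(self) -> str:
        cols = [
            "trials_per_cell", "r_pooled", "r_subject", "r_cell",
            "bias_log_v", "rmse_log_v", "bias_a", "bias_ter",
        ]
        return self.metrics[cols].to_string(index=False)


def _recovery_metrics(cmp: pd.DataFrame) -> dict:
    lt = np.log10(cmp["v_true"].to_numpy(dtype=float))
    le = np.log10(cmp["v_est"].to_numpy(dtype=float))
    by_subj = (
        pd.DataFrame({"s": cmp["subject"], "lt": lt, "le": le}).groupby("s").mean()
    )
    by_cell = (
        pd.DataFrame(
            {"c": [f"{b}/{p}/{d}" for b, p, d in zip(cmp["beneficiary"], cmp["payoff"], cmp["difficulty"])],
             "lt": lt, "le": le}
        ).groupby("c").mean()
    )
    return {
        "r_pooled": float(np.corrcoef(lt, le)[0, 1]),
        "r_subject": float(np.corrcoef(by_subj["lt"].to_numpy(), by_subj["le"].to_numpy())[0, 1]),
        "r_cell": float(np.corrcoef(by_cell["lt"].to_numpy(), by_cell["le"].to_numpy())[0, 1]),
        "bias_log_v": float((le - lt).mean()),
        "rmse_log_v": float(np.sqrt(((le - lt) ** 2).mean())),
        "bias_a": float((cmp["a_est"] - cmp["a_true"]).mean()),
        "rmse_a": float(np.sqrt(((cmp["a_est"] - cmp["a_true"]) ** 2).mean())),
        "bias_ter": float((cmp["ter_est"] - cmp["ter_true"]).mean()),
        "rmse_ter": float(np.sqrt(((cmp["ter_est"] - cmp["ter_true"]) ** 2).mean())),
    }


def run_recovery_experiment(
    config: RunConfig,
    trials_per_cell=(104,),
    model: str = "v_free",
) -> RecoveryReport:
    """Parameter recovery: fit cohorts whose generating parameters are known.

    For each trials-per-cell level a fresh cohort is simulated (sessions
    are built from blocks of 208 trials, so levels must be multiples of
    26) and fitted with ``model``; metrics compare fitted and true
    parameters on the decimal-log drift scale.  Correlations are reported
    pooled over subject x cell, per subject (mean over cells) and per
    cell (mean over subjects).
    """
    frames, rows = [], []
    for tpc in trials_per_cell:
        if tpc % 26:
            raise ValueError("trials_per_cell must be a multiple of 26 (block structure)")
        n_blocks = tpc // 26
        rng = stage_rng(config.seed, f"recovery-{tpc}")
        subjects = sample_cohort(config.scenario, config.n_subjects, rng)
        cmp_rows = []
        for subj in subjects:
            design = generate_design(rng, n_blocks=n_blocks)
            rec = simulate_subject(design, subj, rng)
            fit = fit_all_models(
                rec, models=(model,), quantiles=config.quantiles,
                starts=config.starts, seed=config.seed + subj.subject,
            )[model]
            est = fit.params.reset_index()
            est["subject"] = subj.subject
            cmp = subj.truth_frame().merge(
                est, on=["subject", "beneficiary", "payoff", "difficulty"],
                suffixes=("_true", "_est"),
            )
            cmp_rows.append(cmp)
        cmp = pd.concat(cmp_rows, ignore_index=True)
        cmp["trials_per_cell"] = tpc
        frames.append(cmp)
        rows.append({"trials_per_cell": tpc, **_recovery_metrics(cmp)})
    return RecoveryReport(
        comparison=pd.concat(frames, ignore_index=True),
        metrics=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Model recovery
# ---------------------------------------------------------------------------

_SCHEMES = {
    "drift_only": ScenarioConfig.drift_only,
    "ter_varying": ScenarioConfig.ter_varying,
    "a_varying": ScenarioConfig.a_varying,
}

#: Which fitted model *should* win under each generating scheme.
EXPECTED_WINNER = {
    "drift_only": "v_free",
    "ter_varying": "v_ter_free",
    "a_varying": "v_a_free",
}


def run_model_recovery(
    config: RunConfig,
    schemes=("drift_only", "ter_varying"),
) -> dict:
    """Model recovery: can BIC selection identify the generating structure?

    For each named generating scheme, a cohort is simulated, all models in
    ``config.models`` are fitted per subject, and the two-level BIC
    comparison is run.  Returns ``{scheme: SelectionReport}``; the
    confusion summary is available via :func:`confusion_table`.
    """
    out = {}
    for scheme in schemes:
        scenario = _SCHEMES[scheme]()
        cfg = RunConfig(
            seed=config.seed, n_subjects=config.n_subjects, scenario=scenario,
            models=config.models, quantiles=config.quantiles,
            starts=config.starts, predictive=False,
        )
        rng = stage_rng(cfg.seed, f"model-recovery-{scheme}")
        subjects = sample_cohort(scenario, cfg.n_subjects, rng)
        fits = {}
        for subj in subjects:
            design = generate_design(rng)
            rec = simulate_subject(design, subj, rng)
            fits[subj.subject] = fit_all_models(
                rec, models=cfg.models, quantiles=cfg.quantiles,
                starts=cfg.starts, seed=cfg.seed + subj.subject,
            )
        out[scheme] = select(fits)
    return out


def confusion_table(reports: dict) -> pd.DataFrame:
    """Scheme-by-model table of per-subject best-fit counts."""
    rows = []
    for scheme, rep in reports.items():
        rows.append(
            {"scheme": scheme, "winner": rep.winner, "expected": EXPECTED_WINNER.get(scheme),
             **{f"n_best_{m}": int(c) for m, c in rep.best_counts.items()}}
        )
    return pd.DataFrame(rows)
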