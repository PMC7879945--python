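"""Simulation benchmark: recovery of the true grouping under label noise.

Runs the two pre-filtering strategies over grids of simulated conditions and
scores each fitted model's predictions against the *true* group labels:

* V1 — :class:`~invsel.screening.InvertedRoleSelector` (univariate LRT with
  the classification as predictor, multiplicity adjustment, inverted-role CV
  ranking), then a backward-stepwise GLM on the retained features.
* V2 — :class:`~invsel.baseline.CVRankSelector` (standard univariate CV of
  models predicting the classification), top-n capped at the sample count,
  then the same backward-stepwise GLM.

Both train on the *observed* (noisy) labels; the AUC is always computed
against the error-free ground truth, with the median-based automatic
orientation of the ROC tooling the benchmark mirrors.  A condition where V1
retains zero features is recorded as an unsuccessful fit — an informative
outcome, since those conditions are the ones whose labels carry no signal.

Three scenario families are provided as presets:

* ``binary_2group`` — two true groups, binary ratings corrupted by per-group
  Bernoulli probabilities (prob1, prob2) over a 4x4 probability grid and a
  3x3 (mean_diff, sd) effect grid: 144 conditions.
* ``semiquant_kgroup`` — graduated ground truth (k equidistant populations)
  rated on the matching k-category scale with graded Bernoulli errors.
* ``semiquant_2group`` — two true groups rated on a finer 3-5 category scale
  with graded errors.

The effect grid is a reconstruction: mean differences {1, 2, 3} crossed with
standard deviations {1, 2, 3}, spanning weak (ratio 1/3) to strong (ratio 3)
effects; it is fully overridable through :class:`GridConfig`.
"""

from __future__ import annotations

import itertools
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import CVRankSelector
from .exceptions import InvalidConfigError
from .metrics import auc_binary, auc_multiclass, auc_ranks
from .screening import (
    InvertedRoleSelector,
    _cv_inverted_batch,
    adjust_pvalues,
    filter_significant,
    select_top_v1,
)
from .simulate import SimulationConfig, simulate_dataset
from .stepwise import StepwiseGLM

__all__ = [
    "GridConfig",
    "BenchmarkRecord",
    "run_condition",
    "run_grid",
    "summarize",
    "binary_two_group_grid",
    "semiquant_graduated_grid",
    "semiquant_two_group_grid",
    "large_binary_grid",
]

PROB_LEVELS = (0.1, 0.3, 0.6, 0.9)
DEFAULT_EFFECT_GRID = tuple(
    (float(md), float(sd)) for md in (1.0, 2.0, 3.0) for sd in (1.0, 2.0, 3.0)
)


@dataclass
class GridConfig:
    """One benchmark grid: the cartesian product of its axes."""

    scenario: str  # binary_2group | semiquant_kgroup | semiquant_2group
    n_samples_per_group: tuple = (25,)
    n_features: tuple = (100,)
    prob_grid: tuple = ()  # (prob1, prob2) pairs; prob2 ignored for graded errors
    effect_grid: tuple = DEFAULT_EFFECT_GRID
    categories: tuple = ()  # semiquant scenarios: observed category counts
    adjustments: tuple = ("BH",)
    replicates: int = 1
    master_seed: int = 0
    frac_informative: float = 0.10
    n_samples_total: tuple | None = None  # overrides per-group sizing when set

    def __post_init__(self):
        if self.scenario not in ("binary_2group", "semiquant_kgroup", "semiquant_2group"):
            raise InvalidConfigError(f"unknown scenario: {self.scenario!r}")
        if not self.prob_grid or not self.effect_grid:
            raise InvalidConfigError("prob_grid and effect_grid must be non-empty")
        for pair in self.prob_grid:
            for p in np.atleast_1d(pair):
                if not 0.0 <= float(p) <= 1.0:
                    raise InvalidConfigError("probabilities must lie in [0, 1]")
        if self.scenario != "binary_2group" and not self.categories:
            raise InvalidConfigError("semiquant scenarios need a categories axis")
        if self.replicates < 1:
            raise InvalidConfigError("replicates must be >= 1")

    def conditions(self):
        """Deterministic enumeration of the grid's simulation conditions."""
        cats = self.categories if self.scenario != "binary_2group" else (2,)
        sizes = (
            [("total", n) for n in self.n_samples_total]
            if self.n_samples_total is not None
            else [("per_group", n) for n in self.n_samples_per_group]
        )
        out = []
        for (size_kind, size), n_feat, cat, pair, (md, sd) in itertools.product(
            sizes, self.n_features, cats, self.prob_grid, self.effect_grid
        ):
            pair = tuple(np.atleast_1d(pair).astype(float))
            prob1 = float(pair[0])
            prob2 = float(pair[1]) if len(pair) > 1 else prob1
            if self.scenario == "binary_2group":
                n_groups, encoding = 2, "binary"
            elif self.scenario == "semiquant_2group":
                n_groups, encoding = 2, "semiquant"
            else:
                n_groups, encoding = int(cat), "semiquant"
            n_samples = int(size) if size_kind == "total" else int(size) * n_groups
            out.append(
                dict(
                    n_samples=n_samples,
                    n_features=int(n_feat),
                    n_groups=n_groups,
                    frac_informative=self.frac_informative,
                    mean_diff=float(md),
                    sd=float(sd),
                    prob1=prob1,
                    prob2=prob2,
                    encoding=encoding,
                    n_categories=int(cat),
                )
            )
        return out


@dataclass
class BenchmarkRecord:
    """Outcome of one pipeline variant on one simulated condition."""

    condition_id: str
    variant: str
    adjustment: str
    success: bool
    n_significant: int
    n_selected: int
    auc: float  # NaN when success is False
    fit_time: float
    replicate: int = 0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = asdict(self)
        row.update(row.pop("extra"))
        return row


def _condition_id(params: dict, tag: int) -> str:
    """Unique condition key; ``tag`` is the condition's sub-seed."""
    return (
        f"{params['encoding']}|k{params['n_groups']}|c{params['n_categories']}"
        f"|p{params['prob1']:g}-{params['prob2']:g}|md{params['mean_diff']:g}"
        f"|sd{params['sd']:g}|n{params['n_samples']}|f{params['n_features']}|s{tag}"
    )


def _evaluate_auc(scores, dataset) -> float:
    if dataset.config.n_groups == 2:
        return auc_binary(scores, dataset.true_labels, direction="auto")
    return auc_multiclass(scores, dataset.true_labels, direction="auto")


def _fit_and_score(X, y_observed, dataset, selected_idx, seed) -> tuple[bool, float, int]:
    model = StepwiseGLM(criterion="aic", random_state=seed)
    with warnings.catch_warnings():
        # candidate sets capped at the sample count routinely alias one
        # column in the saturated initial model; that is expected here
        warnings.simplefilter("ignore", UserWarning)
        model.fit(X[:, selected_idx], y_observed)
    if not model.converged_:
        return False, float("nan"), 0
    auc = _evaluate_auc(model.predict_scores(X[:, selected_idx]), dataset)
    return True, auc, len(model.terms_)


def _run_dataset(dataset, adjustments, variants, seed) -> list[BenchmarkRecord]:
    """Run the requested pipeline variants on one simulated condition.

    A condition whose observed labels collapse to a single value (possible
    at extreme error probabilities) cannot be modelled by either pipeline;
    it is recorded as a failed fit for every variant, which is how the
    benchmark counts "no model" outcomes.
    """
    X = dataset.features
    y_obs = dataset.observed_labels.astype(float)
    cid = _condition_id(asdict_params(dataset.config), dataset.config.seed)
    records = []
    cache: dict[tuple, tuple] = {}
    if np.ptp(y_obs) == 0:
        for variant in variants:
            adjs = adjustments if variant == "V1" else ["none"]
            for adj in adjs:
                records.append(
                    BenchmarkRecord(
                        condition_id=cid, variant=variant, adjustment=adj,
                        success=False, n_significant=0, n_selected=0,
                        auc=float("nan"), fit_time=0.0, seed=seed,
                    )
                )
        return records
    if "V1" in variants:
        # share the raw LRT p-values across adjustment methods
        raw_p = None
        for adj in adjustments:
            t0 = time.perf_counter()
            sel = InvertedRoleSelector(adjust=adj, random_state=seed)
            if raw_p is None:
                sel.fit(X, y_obs)
                raw_p = sel.raw_p_
            else:
                sel.n_features_in_ = X.shape[1]
                sel.raw_p_ = raw_p
                sel.adjusted_p_ = adjust_pvalues(raw_p, adj)
                sel.significant_idx_ = filter_significant(sel.adjusted_p_, sel.alpha)
                sel.cv_error_ = np.full(X.shape[1], np.nan)
                if sel.significant_idx_.size:
                    errs = _cv_inverted_batch(
                        X[:, sel.significant_idx_], y_obs, None, sel.cv, seed
                    )
                    sel.cv_error_[sel.significant_idx_] = errs
                    sel.selected_idx_ = select_top_v1(errs, X.shape[0], sel.significant_idx_)
                else:
                    sel.selected_idx_ = np.array([], dtype=int)
                sel.n_selected_ = int(sel.selected_idx_.size)
            if sel.n_selected_ == 0:
                success, auc, n_terms = False, float("nan"), 0
            else:
                key = ("V1", tuple(sel.selected_idx_))
                if key not in cache:
                    cache[key] = _fit_and_score(X, y_obs, dataset, sel.selected_idx_, seed)
                success, auc, n_terms = cache[key]
            records.append(
                BenchmarkRecord(
                    condition_id=cid,
                    variant="V1",
                    adjustment=adj,
                    success=success,
                    n_significant=int(sel.significant_idx_.size),
                    n_selected=sel.n_selected_,
                    auc=auc,
                    fit_time=time.perf_counter() - t0,
                    seed=seed,
                )
            )
    if "V2" in variants:
        t0 = time.perf_counter()
        sel = CVRankSelector(random_state=seed).fit(X, y_obs)
        success, auc, n_terms = _fit_and_score(X, y_obs, dataset, sel.selected_idx_, seed)
        records.append(
            BenchmarkRecord(
                condition_id=cid,
                variant="V2",
                adjustment="none",
                success=success,
                n_significant=X.shape[1],
                n_selected=sel.n_selected_,
                auc=auc,
                fit_time=time.perf_counter() - t0,
                seed=seed,
            )
        )
    return records


def asdict_params(config: SimulationConfig) -> dict:
    return dict(
        n_samples=config.n_samples,
        n_features=config.n_features,
        n_groups=config.n_groups,
        mean_diff=config.mean_diff,
        sd=config.sd,
        prob1=config.prob1,
        prob2=config.prob2,
        encoding=config.encoding,
        n_categories=config.n_categories,
    )


def run_condition(
    config: SimulationConfig, variant: str, adjustment: str = "BH", seed: int | None = None
) -> BenchmarkRecord:
    """Simulate one condition and run one pipeline variant on it."""
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": int(seed)})
    dataset = simulate_dataset(config)
    recs = _run_dataset(
        dataset,
        adjustments=[adjustment] if variant == "V1" else [],
        variants=[variant],
        seed=config.seed,
    )
    return recs[0]


def _sub_seed(master_seed: int, cond_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(cond_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(
    grid: GridConfig,
    variants=("V1", "V2"),
    out_path: str | Path | None = None,
    resume: bool = False,
    log=None,
) -> pd.DataFrame:
    """Run every condition x replicate of a grid; returns a record table.

    With ``out_path`` the table is written incrementally (TSV) after each
    condition, and ``resume=True`` skips conditions already present in an
    existing file, so an interrupted run keeps its partial results.
    """
    conditions = grid.conditions()
    done: set[tuple] = set()
    rows: list[dict] = []
    out_path = Path(out_path) if out_path is not None else None
    if resume and out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path, sep="\t")
        rows = prev.to_dict("records")
        done = {(r["condition_id"],) for r in rows}
    for idx, params in enumerate(conditions):
        for rep in range(grid.replicates):
            seed = _sub_seed(grid.master_seed, idx, rep)
            cfg = SimulationConfig(seed=seed, **params)
            cid = _condition_id(params, seed)
            if (cid,) in done:
                continue
            dataset = simulate_dataset(cfg)
            recs = _run_dataset(dataset, grid.adjustments, variants, seed)
            for rec in recs:
                rec.replicate = rep
                row = rec.to_row()
                row.update(params)
                rows.append(row)
                if log is not None:
                    log(
                        f"condition={rec.condition_id} variant={rec.variant} "
                        f"adj={rec.adjustment} success={rec.success} "
                        f"auc={rec.auc:.3f} seconds={rec.fit_time:.2f}"
                    )
            if out_path is not None:
                pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
    return pd.DataFrame(rows)


def _variant_stats(sub: pd.DataFrame) -> dict:
    ok = sub[sub["success"]]
    stats = {
        "n_conditions": int(len(sub)),
        "n_success": int(len(ok)),
        "fit_fraction": float(len(ok) / len(sub)) if len(sub) else 0.0,
    }
    if len(ok):
        aucs = ok["auc"].to_numpy()
        stats.update(
            median_auc=float(np.median(aucs)),
            min_auc=float(np.min(aucs)),
            max_auc=float(np.max(aucs)),
            n_auc_le_half=int(np.sum(aucs <= 0.5)),
            frac_auc_le_half=float(np.mean(aucs <= 0.5)),
        )
    return stats


def summarize(table: pd.DataFrame, rank_seed: int = 0) -> dict:
    """Aggregate a benchmark record table into the headline statistics.

    Per variant (V1 split by adjustment): counts and fractions of successful
    fits, median/range of AUC over successes, the count and fraction of
    models at or below AUC 0.5 (inclusive), the V1 fit fraction relative to
    V2, median AUC ranks (average and random tie handling) over conditions
    where both variants fit, and stratified medians.  Strata with zero
    successful fits are omitted rather than reported as zero.
    """
    if table.empty:
        raise InvalidConfigError("cannot summarize an empty record table")
    out: dict = {"variants": {}}
    v2 = table[table["variant"] == "V2"]
    n_v2_success = int(v2["success"].sum()) if len(v2) else 0
    if len(v2):
        out["variants"]["V2"] = _variant_stats(v2)
    for adj, sub in table[table["variant"] == "V1"].groupby("adjustment"):
        key = f"V1_{adj}"
        out["variants"][key] = _variant_stats(sub)
        if n_v2_success:
            out["variants"][key]["fit_fraction_vs_v2"] = float(
                sub["success"].sum() / n_v2_success
            )
        # paired AUC ranks on conditions where both variants fit
        merged = pd.merge(
            sub[sub["success"]][["condition_id", "auc"]],
            v2[v2["success"]][["condition_id", "auc"]],
            on="condition_id",
            suffixes=("_v1", "_v2"),
        )
        if len(merged):
            pair = merged[["auc_v1", "auc_v2"]].to_numpy()
            for tie in ("average", "random"):
                ranks = auc_ranks(pair, tie_method=tie, seed=rank_seed)
                out["variants"][key][f"median_rank_{tie}"] = {
                    "V1": float(np.median(ranks[:, 0])),
                    "V2": float(np.median(ranks[:, 1])),
                }
    # stratified medians over successful fits
    strata: dict = {}
    for col in ("prob1", "prob2", "n_categories", "mean_diff", "sd"):
        if col not in table.columns or table[col].nunique() <= 1:
            continue
        level: dict = {}
        for val, sub in table[table["success"]].groupby(col):
            entry = {}
            for (variant, adj), vsub in sub.groupby(["variant", "adjustment"]):
                name = variant if variant == "V2" else f"V1_{adj}"
                entry[name] = {
                    "n_success": int(len(vsub)),
                    "median_auc": float(vsub["auc"].median()),
                }
            if entry:
                level[f"{val:g}" if isinstance(val, float) else str(val)] = entry
        if level:
            strata[col] = level
    out["strata"] = strata
    return out


def relative_fit_fraction_by_stratum(
    table: pd.DataFrame, stratum_col: str, adjustment: str = "BH"
) -> dict:
    """Per-stratum successful-V1-fit count divided by successful-V2-fit count."""
    out = {}
    for val, sub in table.groupby(stratum_col):
        v1 = sub[(sub["variant"] == "V1") & (sub["adjustment"] == adjustment)]
        v2 = sub[sub["variant"] == "V2"]
        n2 = int(v2["success"].sum())
        if n2:
            out[val] = float(v1["success"].sum() / n2)
    return out


# ---------------------------------------------------------------------------
# preset grids reproducing the benchmark's scenario families


def binary_two_group_grid(
    n_per_group=25, n_features=100, adjustments=("BH", "bonferroni"),
    replicates=1, master_seed=0,
) -> GridConfig:
    """Two true groups, binary ratings: 16 probability pairs x 9 effects."""
    return GridConfig(
        scenario="binary_2group",
        n_samples_per_group=(n_per_group,),
        n_features=(n_features,),
        prob_grid=tuple(itertools.product(PROB_LEVELS, PROB_LEVELS)),
        adjustments=tuple(adjustments),
        replicates=replicates,
        master_seed=master_seed,
    )


def semiquant_graduated_grid(
    categories=tuple(range(3, 11)), n_samples=50, n_features=100,
    adjustments=("BH",), replicates=1, master_seed=0,
) -> GridConfig:
    """Graduated ground truth: k groups rated on the matching k-point scale."""
    return GridConfig(
        scenario="semiquant_kgroup",
        n_samples_total=(n_samples,),
        n_features=(n_features,),
        prob_grid=tuple((p,) for p in PROB_LEVELS),
        categories=tuple(categories),
        adjustments=tuple(adjustments),
        replicates=replicates,
        master_seed=master_seed,
    )


def semiquant_two_group_grid(
    categories=(3, 4, 5), n_samples=50, n_features=100,
    adjustments=("BH",), replicates=1, master_seed=0,
) -> GridConfig:
    """Two true groups rated on a finer semi-quantitative scale.

    Observed ratings are per-group binomial redraws on the c-point scale, so
    the probability axis is the full (prob1, prob2) grid as in the binary
    scenario.
    """
    return GridConfig(
        scenario="semiquant_2group",
        n_samples_total=(n_samples,),
        n_features=(n_features,),
        prob_grid=tuple(itertools.product(PROB_LEVELS, PROB_LEVELS)),
        categories=tuple(categories),
        adjustments=tuple(adjustments),
        replicates=replicates,
        master_seed=master_seed,
    )


def large_binary_grid(
    n_per_group=(50,), n_features=(2000,), adjustments=("bonferroni",),
    replicates=1, master_seed=0,
) -> GridConfig:
    """Scaled-up binary scenario: weakly informative 0.1/0.3 probability corners.

    The probability axis uses the mixed pairs (0.1, 0.3) and (0.3, 0.1) —
    labels that carry weak but non-zero information — with Bonferroni
    adjustment, larger feature counts and larger groups.
    """
    return GridConfig(
        scenario="binary_2group",
        n_samples_per_group=tuple(np.atleast_1d(n_per_group).astype(int)),
        n_features=tuple(np.atleast_1d(n_features).astype(int)),
        prob_grid=((0.1, 0.3), (0.3, 0.1)),
        adjustments=tuple(adjustments),
        replicates=replicates,
        master_seed=master_seed,
    )


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
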