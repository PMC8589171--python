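"""Repeated cross-validated benchmarking of treatment-selection policies.

The evaluation protocol: fix one cohort; for each repetition draw a fresh
shuffled k-fold split (every method sees byte-identical splits within a
repetition), train each method on the training folds, predict the full
patient-by-treatment surface on the held-out fold, score it, and average
the fold scores into one sample per method and repetition.  Methods are
then compared on the per-repetition samples with median / median absolute
deviation summaries and a Friedman omnibus test followed by pairwise
Wilcoxon signed-rank tests with Bonferroni correction (normality screened
per method with Shapiro-Wilk, which is why the nonparametric route is
taken at all).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import KFold

from .estimators import DPNNPolicy, KMNNPolicy
from .metrics import (
    classification_metrics,
    mean_reciprocal_rank,
    recommend_from_matrix,
    remission_policy_loss,
    retrospective_remission_rate,
)
from .synthetic import Cohort, SyntheticConfig, generate_cohort

__all__ = [
    "FoldSplit",
    "kfold_split",
    "evaluate_fold",
    "run_experiment",
    "aggregate",
    "compare_methods",
    "sensitivity_sweep",
    "grid_search",
]

METRIC_COLUMNS = ["mrr", "rpl", "rr", "auc", "sensitivity", "specificity", "ppv", "npv"]


@dataclass(frozen=True)
class FoldSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    fold_id: int
    n_folds: int


def kfold_split(n: int, n_folds: int, seed: int | None = None) -> list[FoldSplit]:
    """Shuffled k-fold partition of 0..n-1; test folds tile the index set."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError("need at least one sample per fold")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        FoldSplit(train_indices=tr, test_indices=te, fold_id=i, n_folds=n_folds)
        for i, (tr, te) in enumerate(kf.split(np.arange(n)))
    ]


def evaluate_fold(
    model, cohort: Cohort, split: FoldSplit, mrr_convention: str = "shifted"
) -> dict[str, float]:
    """Fit ``model`` on the training fold and score the test fold.

    Returns one metric record; MRR/RPL are NaN when the cohort carries no
    counterfactual surface.
    """
    train = cohort.subset(split.train_indices)
    test = cohort.subset(split.test_indices)
    model.fit(train.X, train.y, treatment=train.t)
    pred = model.predict_all(test.X)
    recommended, _ = recommend_from_matrix(pred)
    rec: dict[str, float] = {}
    if test.P_true is not None:
        rec["mrr"] = mean_reciprocal_rank(pred, test.P_true, convention=mrr_convention)
        rec["rpl"] = remission_policy_loss(pred, test.P_true)
    else:
        rec["mrr"] = rec["rpl"] = float("nan")
    rr, support = retrospective_remission_rate(recommended, test.t, test.y)
    rec["rr"] = rr
    rec["rr_support"] = support
    received_probs = pred[np.arange(test.n_patients), test.t]
    rec.update(classification_metrics(received_probs, test.y))
    return rec


def run_experiment(
    cohort: Cohort | SyntheticConfig,
    methods: dict[str, object],
    n_repetitions: int = 100,
    n_folds: int = 5,
    master_seed: int = 0,
    mrr_convention: str = "shifted",
    regenerate_each_repetition: bool = False,
) -> pd.DataFrame:
    """Repeated k-fold evaluation of every method on identical splits.

    ``methods`` maps a name to an unfitted estimator; each fold gets a
    fresh clone with a deterministic random_state.  Returns one row per
    method and repetition, fold scores averaged (zero-support RR folds
    dropped from the RR average).  A method failure on a repetition is
    warned about and recorded as missing; the run continues.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    if len(set(methods)) != len(methods):
        raise ValueError("method names must be unique")
    base_cohort = cohort if isinstance(cohort, Cohort) else None
    config = cohort if isinstance(cohort, SyntheticConfig) else None
    if base_cohort is None and config is not None and not regenerate_each_repetition:
        base_cohort = generate_cohort(config)

    rows = []
    for rep in range(n_repetitions):
        rep_seed = int((master_seed + rep) % 2**31)
        if regenerate_each_repetition:
            import dataclasses

            co = generate_cohort(dataclasses.replace(config, seed=rep_seed))
        else:
            co = base_cohort
        splits = kfold_split(co.n_patients, n_folds, seed=rep_seed)
        for name, proto in methods.items():
            fold_recs = []
            try:
                for split in splits:
                    model = clone(proto)
                    if "random_state" in model.get_params():
                        model.set_params(
                            random_state=int((rep_seed * 1009 + split.fold_id) % 2**31)
                        )
                    fold_recs.append(evaluate_fold(model, co, split, mrr_convention))
            except Exception as exc:  # keep the benchmark alive on one failure
                warnings.warn(f"method {name!r} failed on repetition {rep}: {exc}")
                rows.append({"method": name, "repetition": rep})
                continue
            df = pd.DataFrame(fold_recs)
            row = {"method": name, "repetition": rep}
            for col in METRIC_COLUMNS:
                row[col] = float(df[col].mean(skipna=True))
            row["rr_support"] = float(df["rr_support"].sum())
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate(samples: pd.DataFrame) -> pd.DataFrame:
    """Median and MAD (unscaled median absolute deviation) per method and
    metric, the robust summary used for reporting."""
    if samples.empty:
        raise ValueError("no samples to aggregate")
    records = []
    for method, grp in samples.groupby("method", sort=False):
        rec = {"method": method, "n_samples": len(grp)}
        for col in METRIC_COLUMNS:
            if col not in grp:
                continue
            vals = grp[col].dropna().to_numpy()
            if len(vals) == 0:
                rec[f"{col}_median"] = rec[f"{col}_mad"] = float("nan")
            else:
                med = float(np.median(vals))
                rec[f"{col}_median"] = med
                rec[f"{col}_mad"] = float(np.median(np.abs(vals - med)))
        records.append(rec)
    return pd.DataFrame(records)


def compare_methods(
    samples: pd.DataFrame, metric: str, significance: float = 0.01
) -> dict:
    """Nonparametric method comparison on paired per-repetition samples.

    Shapiro-Wilk per method (normality screen), Friedman omnibus across
    methods, and — when the omnibus is significant — pairwise Wilcoxon
    signed-rank tests with Bonferroni correction over all method pairs.
    Repetitions with a missing value for any method are dropped from the
    omnibus (pairwise tests use pairwise-complete repetitions); the count
    is reported.
    """
    wide = samples.pivot(index="repetition", columns="method", values=metric)
    methods = list(wide.columns)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    complete = wide.dropna()
    report: dict = {
        "metric": metric,
        "n_repetitions": int(len(wide)),
        "n_complete": int(len(complete)),
        "shapiro": {},
        "pairwise": {},
    }
    for m in methods:
        vals = wide[m].dropna().to_numpy()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            stat, p = stats.shapiro(vals)
            report["shapiro"][m] = {"statistic": float(stat), "p_value": float(p)}
        else:
            report["shapiro"][m] = {"statistic": float("nan"), "p_value": float("nan")}
    arrays = [complete[m].to_numpy() for m in methods]
    if len(methods) >= 3 and len(complete) >= 3 and any(np.ptp(a) > 0 for a in arrays):
        stat, p = stats.friedmanchisquare(*arrays)
        report["friedman"] = {"statistic": float(stat), "p_value": float(p)}
    else:
        report["friedman"] = {"statistic": float("nan"), "p_value": float("nan")}
    pairs = list(itertools.combinations(methods, 2))
    n_tests = len(pairs)
    for a, b in pairs:
        both = wide[[a, b]].dropna()
        diff = both[a].to_numpy() - both[b].to_numpy()
        if len(diff) == 0 or np.allclose(diff, 0):
            p_raw = 1.0
        else:
            p_raw = float(stats.wilcoxon(both[a], both[b]).pvalue)
        p_adj = min(1.0, p_raw * n_tests)
        report["pairwise"][f"{a} vs {b}"] = {
            "p_value": p_raw,
            "p_adjusted": p_adj,
            "significant": bool(p_adj <= significance),
            "n_pairs": int(len(diff)),
        }
    return report


def sensitivity_sweep(
    cohort: Cohort,
    l_values,
    dpnn_params: dict | None = None,
    kmnn_params: dict | None = None,
    n_repetitions: int = 5,
    test_fraction: float = 0.2,
    master_seed: int = 0,
    mrr_convention: str = "shifted",
) -> pd.DataFrame:
    """Mean metrics per prototype count l, for the DPN (and optionally the
    K-means baseline), each l repeated over fresh shuffled train/test
    splits.  Probes how sensitive the methods are to the assumed subgroup
    count."""
    l_values = list(l_values)
    if not l_values:
        raise ValueError("l_values must be nonempty")
    rows = []
    rng = np.random.default_rng(master_seed)
    n_test = max(1, int(round(test_fraction * cohort.n_patients)))
    dpnn_params = {k: v for k, v in (dpnn_params or {}).items() if k != "n_prototypes"}
    if kmnn_params is not None:
        kmnn_params = {k: v for k, v in kmnn_params.items() if k != "n_clusters"}
    for l in l_values:
        methods = {"dpnn": DPNNPolicy(n_prototypes=l, **dpnn_params)}
        if kmnn_params is not None:
            methods["kmnn"] = KMNNPolicy(n_clusters=l, **kmnn_params)
        recs: dict[str, list[dict]] = {m: [] for m in methods}
        for rep in range(n_repetitions):
            perm = rng.permutation(cohort.n_patients)
            split = FoldSplit(perm[n_test:], perm[:n_test], fold_id=rep, n_folds=1)
            seed = int(rng.integers(0, 2**31 - 1))
            for name, proto in methods.items():
                model = clone(proto).set_params(random_state=seed)
                recs[name].append(evaluate_fold(model, cohort, split, mrr_convention))
        for name in methods:
            df = pd.DataFrame(recs[name])
            row = {"method": name, "n_prototypes": l}
            for col in METRIC_COLUMNS:
                row[col] = float(df[col].mean(skipna=True))
            rows.append(row)
    return pd.DataFrame(rows)


def grid_search(
    cohort: Cohort,
    base_estimator,
    param_grid: dict[str, list],
    metric: str = "rpl",
    n_folds: int = 3,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Minimal exhaustive grid driver: cross-validated mean of one metric
    per parameter combination, sorted best-first (RPL ascending, others
    descending)."""
    keys = list(param_grid)
    rows = []
    splits = kfold_split(cohort.n_patients, n_folds, seed=master_seed)
    for values in itertools.product(*(param_grid[k] for k in keys)):
        params = dict(zip(keys, values))
        scores = []
        for split in splits:
            model = clone(base_estimator).set_params(**params)
            if "random_state" in model.get_params():
                model.set_params(random_state=master_seed + split.fold_id)
            scores.append(evaluate_fold(model, cohort, split)[metric])
        rows.append({**params, metric: float(np.nanmean(scores))})
    df = pd.DataFrame(rows)
    return df.sort_values(metric, ascending=(metric == "rpl")).reset_index(drop=True)
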