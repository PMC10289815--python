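"""Repeated hold-out benchmarking, accuracy metrics, GPI ranking.

Each cultivar x trait scenario runs three network variants on identical
70/30 train/test splits repeated five times:

* ``BPNN`` — all 35 colorimetric indexes;
* ``PCA_BPNN`` — scores of the principal components retaining ~85% of
  the training-split variance;
* ``SPCA_BPNN`` — the standardized raw indexes that survive the sparse
  PCA nonzero-loading filter, with per-component cardinality chosen by
  the genetic algorithm.

Per split, accuracy is summarized by R^2 (squared Pearson correlation of
observed and predicted), RMSE with an n-1 denominator, and MAE.  The
three indicators over the five splits are combined per model into the
general performance indicator (GPI): indicators are min-max normalized
over all model x iteration cells of the scenario, and the GPI of a model
is the signed sum of deviations of its cells from the scenario medians
(sign -1 for R^2, +1 for the error metrics), so a larger GPI is better.

All fitting statistics — feature medians for imputation, standardization,
PCA/SPCA loadings, the GA search, and target min-max scaling — are
learned on the training split only.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bpnn import RpropRegressor
from .dimred import (
    FeatureStandardizer,
    GAConfig,
    VarianceCutoffPCA,
    CardinalitySparsePCA,
    ga_select_nnzl,
    select_variables,
)
from .indexes import build_feature_table

__all__ = [
    "MODEL_NAMES",
    "SplitPlan",
    "MetricSet",
    "GPIResult",
    "ResidualDiagnostics",
    "ScenarioReport",
    "UndefinedMetricError",
    "make_split_plan",
    "compute_metrics",
    "compute_gpi",
    "pool_residuals",
    "run_scenario",
]

#: Registration order of the model variants (also the tie-break order).
MODEL_NAMES = ("BPNN", "PCA_BPNN", "SPCA_BPNN")

INDICATORS = ("R2", "RMSE", "MAE")
ALPHA = {"R2": -1.0, "RMSE": 1.0, "MAE": 1.0}


class UndefinedMetricError(ValueError):
    """R^2 is undefined because the observed values have zero variance."""


@dataclass(frozen=True)
class SplitPlan:
    splits: tuple[tuple[np.ndarray, np.ndarray], ...]
    train_fraction: float
    master_seed: int

    def __len__(self) -> int:
        return len(self.splits)


@dataclass(frozen=True)
class MetricSet:
    r_squared: float
    rmse: float
    mae: float
    n_test: int


@dataclass(frozen=True)
class GPIResult:
    gpi: dict[str, float]
    ranks: dict[str, int]
    normalized: pd.DataFrame  # columns model, iteration, indicator, value
    medians: dict[str, float]


@dataclass(frozen=True)
class ResidualDiagnostics:
    residuals: np.ndarray
    fitted: np.ndarray
    mean: float
    sd: float
    iqr: float
    band: tuple[float, float]  # +/- 2 SD about the residual mean
    smooth: np.ndarray  # (m, 2) LOWESS of residual vs fitted


@dataclass
class ScenarioReport:
    cultivar: str
    trait: str
    metrics: pd.DataFrame  # columns model, iteration, R2, RMSE, MAE, n_test
    gpi: GPIResult
    residuals: dict[str, ResidualDiagnostics]
    selected_variables: list[tuple[str, ...]]
    nnzl: list[tuple[int, ...]]
    non_converged: list[tuple[str, int]]
    seeds: dict[str, int] = field(default_factory=dict)

    def mean_r_squared(self) -> pd.Series:
        return self.metrics.groupby("model")["R2"].mean()

    def to_json_dict(self) -> dict:
        return {
            "cultivar": self.cultivar,
            "trait": self.trait,
            "metrics": self.metrics.to_dict(orient="records"),
            "gpi": self.gpi.gpi,
            "ranks": self.gpi.ranks,
            "selected_variables": [list(v) for v in self.selected_variables],
            "nnzl": [list(map(int, v)) for v in self.nnzl],
            "non_converged": [list(x) for x in self.non_converged],
            "seeds": self.seeds,
            "residual_sd": {m: d.sd for m, d in self.residuals.items()},
            "residual_iqr": {m: d.iqr for m, d in self.residuals.items()},
        }


def make_split_plan(
    n: int,
    train_fraction: float = 0.7,
    n_repeats: int = 5,
    master_seed: int = 0,
) -> SplitPlan:
    """Random 70/30-style hold-out splits shared by all model variants."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if n < 10:
        raise ValueError("need at least 10 samples for a hold-out plan")
    rng = np.random.default_rng(master_seed)
    n_train = int(np.floor(train_fraction * n))
    splits = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return SplitPlan(splits=tuple(splits), train_fraction=train_fraction, master_seed=master_seed)


def compute_metrics(observed, predicted) -> MetricSet:
    """R^2 (squared Pearson r), RMSE with n-1 denominator, and MAE."""
    x = np.asarray(observed, dtype=float).ravel()
    y = np.asarray(predicted, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("observed and predicted must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0:
        raise UndefinedMetricError("observed values are constant; R^2 undefined")
    if np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(stats.pearsonr(x, y).statistic ** 2)
    rmse = float(np.sqrt(np.sum((y - x) ** 2) / (n - 1)))
    mae = float(np.mean(np.abs(x - y)))
    return MetricSet(r_squared=r2, rmse=rmse, mae=mae, n_test=n)


def compute_gpi(metrics: pd.DataFrame, model_order=MODEL_NAMES) -> GPIResult:
    """General performance indicator and ranks for one scenario.

    ``metrics`` holds one row per model x iteration with columns
    ``model``, ``iteration``, ``R2``, ``RMSE``, ``MAE``.  Indicators are
    min-max normalized over all cells; a constant indicator is set to 0.5
    everywhere (contributing zero) with a warning.  Ties in the ranking
    are broken by model registration order.
    """
    models = [m for m in model_order if m in set(metrics["model"])]
    long = metrics.melt(
        id_vars=["model", "iteration"],
        value_vars=list(INDICATORS),
        var_name="indicator",
    )
    norm_parts = []
    for ind, grp in long.groupby("indicator"):
        lo, hi = grp["value"].min(), grp["value"].max()
        g = grp.copy()
        if hi == lo:
            warnings.warn(f"indicator {ind} constant across all cells", stacklevel=2)
            g["value"] = 0.5
        else:
            g["value"] = (g["value"] - lo) / (hi - lo)
        norm_parts.append(g)
    norm = pd.concat(norm_parts, ignore_index=True)
    medians = {ind: float(grp["value"].median()) for ind, grp in norm.groupby("indicator")}
    gpi: dict[str, float] = {}
    for m in models:
        total = 0.0
        sub = norm[norm["model"] == m]
        for _, row in sub.iterrows():
            total += ALPHA[row["indicator"]] * (medians[row["indicator"]] - row["value"])
        gpi[m] = total
    order = sorted(models, key=lambda m: (-gpi[m], models.index(m)))
    ranks = {m: order.index(m) + 1 for m in models}
    return GPIResult(gpi=gpi, ranks=ranks, normalized=norm, medians=medians)


def pool_residuals(per_iteration: list[tuple[np.ndarray, np.ndarray]]) -> ResidualDiagnostics:
    """Pool (observed, fitted) test-set pairs over iterations.

    Residuals are observed minus fitted; the summary includes IQR, SD,
    the +/- 2 SD band about the residual mean, and a LOWESS smooth
    (span 0.75) of residual versus fitted value.
    """
    if not per_iteration:
        raise ValueError("need at least one iteration")
    obs = np.concatenate([np.asarray(o, dtype=float).ravel() for o, _ in per_iteration])
    fit = np.concatenate([np.asarray(f, dtype=float).ravel() for _, f in per_iteration])
    res = obs - fit
    mean = float(res.mean())
    sd = float(res.std(ddof=1)) if res.size > 1 else 0.0
    q1, q3 = np.percentile(res, [25, 75])
    if np.ptp(fit) == 0 or np.ptp(res) == 0:
        # degenerate spread: the smooth is the data itself
        order = np.argsort(fit)
        smooth = np.column_stack([fit[order], res[order]])
    else:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        smooth = lowess(res, fit, frac=0.75, return_sorted=True)
    return ResidualDiagnostics(
        residuals=res,
        fitted=fit,
        mean=mean,
        sd=sd,
        iqr=float(q3 - q1),
        band=(mean - 2 * sd, mean + 2 * sd),
        smooth=np.asarray(smooth),
    )


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss]


def run_scenario(
    samples: pd.DataFrame,
    trait: str,
    plan: SplitPlan,
    dialect: str = "interpreted",
    variance_cutoff: float = 0.85,
    ga_config: GAConfig | None = None,
    network_kwargs: dict | None = None,
    master_seed: int = 0,
) -> ScenarioReport:
    """Benchmark the three network variants for one cultivar x trait.

    ``samples`` must carry ``r_mean``/``g_mean``/``b_mean`` and the trait
    column; all rows are assumed to belong to one cultivar.
    """
    if trait not in samples.columns:
        raise KeyError(f"trait column {trait!r} missing from sample table")
    features, _ = build_feature_table(samples, dialect=dialect)
    y = samples[trait].to_numpy(dtype=float)
    cultivar = str(samples["cultivar"].iloc[0]) if "cultivar" in samples.columns else "?"
    network_kwargs = dict(network_kwargs or {})
    net_seeds = _derive_seeds(master_seed, len(plan) * len(MODEL_NAMES))
    ga_seeds = _derive_seeds(master_seed + 1, len(plan))

    rows = []
    per_model_pairs: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        m: [] for m in MODEL_NAMES
    }
    selected_vars: list[tuple[str, ...]] = []
    nnzl_hist: list[tuple[int, ...]] = []
    non_converged: list[tuple[str, int]] = []

    for j, (tr, te) in enumerate(plan.splits):
        f_tr, f_te = features.iloc[tr], features.iloc[te]
        # training-median imputation of undefined-flag entries
        med = f_tr.median().fillna(0.0)
        f_tr = f_tr.fillna(med)
        f_te = f_te.fillna(med)
        std = FeatureStandardizer().fit(f_tr)
        z_tr, z_te = std.transform(f_tr), std.transform(f_te)
        y_tr, y_te = y[tr], y[te]

        pca = VarianceCutoffPCA(variance_cutoff=variance_cutoff).fit(z_tr)
        cfg = dataclasses.replace(ga_config or GAConfig(), seed=ga_seeds[j])
        nnzl = ga_select_nnzl(z_tr, pca.k_retained_, cfg)
        spca = CardinalitySparsePCA(nnzl=nnzl).fit(z_tr)
        retained = select_variables(spca.to_result(z_tr))
        selected_vars.append(retained)
        nnzl_hist.append(tuple(int(v) for v in nnzl))

        inputs = {
            "BPNN": (z_tr.to_numpy(), z_te.to_numpy()),
            "PCA_BPNN": (pca.transform(z_tr), pca.transform(z_te)),
            "SPCA_BPNN": (
                z_tr[list(retained)].to_numpy(),
                z_te[list(retained)].to_numpy(),
            ),
        }
        for mi, model in enumerate(MODEL_NAMES):
            Xtr, Xte = inputs[model]
            net = RpropRegressor(
                random_state=net_seeds[j * len(MODEL_NAMES) + mi], **network_kwargs
            )
            net.fit(Xtr, y_tr)
            if not net.converged_:
                non_converged.append((model, j))
            pred = net.predict(Xte)
            ms = compute_metrics(y_te, pred)
            rows.append(
                {
                    "model": model,
                    "iteration": j,
                    "R2": ms.r_squared,
                    "RMSE": ms.rmse,
                    "MAE": ms.mae,
                    "n_test": ms.n_test,
                }
            )
            per_model_pairs[model].append((y_te, pred))

    metrics = pd.DataFrame(rows)
    gpi = compute_gpi(metrics)
    residuals = {m: pool_residuals(per_model_pairs[m]) for m in MODEL_NAMES}
    return ScenarioReport(
        cultivar=cultivar,
        trait=trait,
        metrics=metrics,
        gpi=gpi,
        residuals=residuals,
        selected_variables=selected_vars,
        nnzl=nnzl_hist,
        non_converged=non_converged,
        seeds={"master_seed": master_seed, "split_seed": plan.master_seed},
    )
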