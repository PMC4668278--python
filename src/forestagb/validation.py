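"""Cross-design validation harness for plot-level AGB predictions.

Given a plot table carrying team labels (``Comm`` for community crews,
``Prof`` for professional crews), the harness evaluates every
training-set/validation-set combination of the two sources plus their
union.  Error statistics per combination are

    RMSE   = sqrt( sum_i (yhat_i - y_i)^2 / N_v )
    D      = sum_i (yhat_i - y_i) / N_v          (mean difference)

with relative forms RMSE % = 100 * RMSE / mean(y_v) and
D % = 100 * D / mean(y_v) (reported as "BIAS %" in the comparison
tables), plus r^2, the squared Pearson correlation between predictions
and field estimates.

Whenever the training set contains the validation plots (self-validation,
or the combined Comm + Prof training set), leave-one-out cross-validation
is used so that no plot predicts itself; a disjoint training set is fit
once and applied directly.  Each cross row is compared against its
baseline (self-validation) row with a two-sample t test on the error
means and a two-sample variance-ratio F test, both two-sided at the 5 %
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import model as agbmodel
from .errors import ConfigError, SchemaError
from .model import ModelConfig
from .presets import RegimePreset
from .synthetic import make_metric_table

#: columns of a plot table that are metadata rather than predictors
META_COLUMNS = ("plot_id", "agb", "team", "site", "ownership", "canopy",
                "x", "y", "radius", "cluster", "outlier_flag")

ALPHA = 0.05


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All non-metadata columns, in table order."""
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# error statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorStats:
    """Prediction error summary for one training/validation combination."""

    n: int
    rmse: float            # Mg/ha
    d: float               # Mg/ha, mean(predicted - field estimate)
    rmse_pct: float        # % of the validation-set mean field estimate
    d_pct: float           # %, the comparison tables' "BIAS %"
    mean_reference: float  # Mg/ha, validation-set mean field estimate
    r2: float              # squared Pearson corr of predictions vs estimates


def error_stats(pred, truth) -> ErrorStats:
    """Compute RMSE, D, their relative forms and r^2.

    The sign convention is prediction minus field estimate, so a negative
    D means under-prediction.  RMSE >= |D| always (Cauchy-Schwarz).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ConfigError("pred and truth must be 1-D arrays of equal length")
    n = pred.size
    if n < 1:
        raise ConfigError("need at least one prediction")
    err = pred - truth
    rmse = float(np.sqrt(np.mean(err ** 2)))
    d = float(np.mean(err))
    ybar = float(np.mean(truth))
    if ybar == 0:
        raise ConfigError("validation mean is zero; relative errors undefined")
    if n >= 2 and np.std(pred) > 0 and np.std(truth) > 0:
        r2 = float(np.corrcoef(pred, truth)[0, 1] ** 2)
    else:
        r2 = float("nan")
    stats_ = ErrorStats(n=n, rmse=rmse, d=d,
                        rmse_pct=100.0 * rmse / ybar,
                        d_pct=100.0 * d / ybar,
                        mean_reference=ybar, r2=r2)
    assert stats_.rmse >= abs(stats_.d) - 1e-9
    return stats_


def r2_explained(pred, truth) -> float:
    """Alternative fit metric: 1 - SSE/SST (can be negative)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    sst = float(np.sum((truth - truth.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((pred - truth) ** 2)) / sst


# ---------------------------------------------------------------------------
# prediction protocols
# ---------------------------------------------------------------------------

def loocv_predict(table: pd.DataFrame, config: ModelConfig | None = None,
                  feature_cols: list[str] | None = None) -> np.ndarray:
    """Leave-one-out predictions: plot i is predicted by a model fitted on
    every other plot.  Output order matches the input row order.

    Leave-out is by plot: if a ``plot_id`` column is present and a plot
    appears in several rows, all of its rows are excluded from the fit
    that predicts it.
    """
    if config is None:
        config = ModelConfig()
    cols = feature_cols if feature_cols is not None else feature_columns(table)
    X = table[cols].to_numpy(float)
    y = table["agb"].to_numpy(float)
    n = len(table)
    if n < 3:
        raise ConfigError("LOOCV needs at least 3 plots")
    ids = table["plot_id"].to_numpy() if "plot_id" in table.columns \
        else np.arange(n)
    preds = np.empty(n)
    for uid in pd.unique(ids):
        held = ids == uid
        fit_ = agbmodel.fit(X[~held], y[~held], config)
        preds[held] = agbmodel.predict(fit_, X[held])
    return preds


def cross_predict(train: pd.DataFrame, valid: pd.DataFrame,
                  config: ModelConfig | None = None,
                  feature_cols: list[str] | None = None) -> np.ndarray:
    """Predict the validation plots from the training set.

    If every validation plot is contained in the training set (matched by
    ``plot_id``) -- the self-validation and combined-training cases --
    leave-one-out predictions on the training set are computed and looked
    up per plot, so no plot ever predicts itself.  Otherwise the model is
    calibrated once on the training set and applied as-is.
    """
    if len(train) == 0 or len(valid) == 0:
        raise ConfigError("training and validation sets must be non-empty")
    if config is None:
        config = ModelConfig()
    cols = feature_cols if feature_cols is not None else feature_columns(train)
    if "plot_id" in train.columns and "plot_id" in valid.columns and \
            set(valid["plot_id"]) <= set(train["plot_id"]):
        loo = loocv_predict(train, config, cols)
        lookup = dict(zip(train["plot_id"], loo))
        return np.array([lookup[pid] for pid in valid["plot_id"]])
    fit_ = agbmodel.fit(train[cols].to_numpy(float),
                        train["agb"].to_numpy(float), config)
    return agbmodel.predict(fit_, valid[cols].to_numpy(float))


# ---------------------------------------------------------------------------
# significance tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    kind: str                  # "t_mean" or "F_variance"
    statistic: float
    p_value: float
    significant_at_5pct: bool


def compare_to_baseline(baseline_errors, alt_errors, *,
                        equal_var: bool = False
                        ) -> tuple[TestResult, TestResult]:
    """Test an alternative error vector against the baseline one.

    Returns ``(t, F)``: a two-sample t test on the error means (Welch by
    default; ``equal_var=True`` switches to the pooled variant) and a
    classical two-sided variance-ratio F test, both at the 5 % level.
    """
    a = np.asarray(baseline_errors, dtype=float)
    b = np.asarray(alt_errors, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("both error vectors need length >= 2")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ConfigError("degenerate (zero-variance) error vector")
    if np.array_equal(a, b):
        t_res = TestResult("t_mean", 0.0, 1.0, False)
    else:
        t_stat, t_p = stats.ttest_ind(b, a, equal_var=equal_var)
        t_res = TestResult("t_mean", float(t_stat), float(t_p),
                           bool(t_p < ALPHA))
    f_stat = vb / va
    dfb, dfa = b.size - 1, a.size - 1
    cdf = stats.f.cdf(f_stat, dfb, dfa)
    f_p = 2.0 * min(cdf, 1.0 - cdf)
    f_p = min(f_p, 1.0)
    f_res = TestResult("F_variance", float(f_stat), float(f_p),
                       bool(f_p < ALPHA))
    return t_res, f_res


# ---------------------------------------------------------------------------
# the comparison grid
# ---------------------------------------------------------------------------

def run_design(table: pd.DataFrame, config: ModelConfig | None = None,
               teams: tuple[str, str] = ("Comm", "Prof"),
               equal_var: bool = False) -> pd.DataFrame:
    """Evaluate the full 2-validation x 3-training comparison grid.

    For each validation source the training set is (a) the same source
    (baseline, LOOCV), (b) the other source (straight cross-prediction)
    and (c) the combined set (LOOCV).  Each non-baseline row carries the
    p-values of the t and F tests of its error vector against the
    baseline's.

    Returns a tidy DataFrame with one row per combination.
    """
    if config is None:
        config = ModelConfig()
    if "team" not in table.columns:
        raise SchemaError("plot table needs a 'team' column")
    cols = feature_columns(table)
    subsets = {}
    for team in teams:
        sub = table[table["team"] == team].reset_index(drop=True)
        if len(sub) < 3:
            raise ConfigError(f"team {team!r} has fewer than 3 plots")
        subsets[team] = sub
    combined = pd.concat([subsets[t] for t in teams], ignore_index=True)
    combined_label = " + ".join(teams)

    # the combined-training LOOCV serves both validation sets; compute once
    combined_loo = dict(zip(combined["plot_id"],
                            loocv_predict(combined, config, cols)))

    rows = []
    for vteam in teams:
        valid = subsets[vteam]
        truth = valid["agb"].to_numpy(float)
        other = [t for t in teams if t != vteam][0]
        plans = [(vteam, True), (other, False), (combined_label, False)]
        baseline_err = None
        for train_label, is_baseline in plans:
            if train_label == combined_label:
                pred = np.array([combined_loo[p] for p in valid["plot_id"]])
            else:
                pred = cross_predict(subsets[train_label], valid, config, cols)
            es = error_stats(pred, truth)
            err = pred - truth
            row = {
                "validation_set": vteam,
                "training_set": train_label,
                "baseline": is_baseline,
                "n": es.n,
                "rmse": es.rmse,
                "rmse_pct": es.rmse_pct,
                "d": es.d,
                "bias_pct": es.d_pct,
                "r2": es.r2,
                "variance_test_p": np.nan,
                "t_test_p": np.nan,
            }
            if is_baseline:
                baseline_err = err
            else:
                t_res, f_res = compare_to_baseline(baseline_err, err,
                                                   equal_var=equal_var)
                row["t_test_p"] = t_res.p_value
                row["variance_test_p"] = f_res.p_value
            rows.append(row)
    return pd.DataFrame(rows)


def render_design_table(design: pd.DataFrame) -> str:
    """Plain-text rendering of a comparison grid."""
    lines = []
    for vteam, grp in design.groupby("validation_set", sort=False):
        lines.append(f"Validation set: {vteam}")
        lines.append(f"  {'Training set':<16}{'RMSE %':>8}{'BIAS %':>8}"
                     f"{'Var p':>8}{'t p':>8}")
        for r in grp.itertuples(index=False):
            label = r.training_set + (" (baseline)" if r.baseline else "")
            varp = "" if np.isnan(r.variance_test_p) else f"{r.variance_test_p:.3f}"
            tp = "" if np.isnan(r.t_test_p) else f"{r.t_test_p:.3f}"
            lines.append(f"  {label:<16}{r.rmse_pct:>8.1f}{r.bias_pct:>8.1f}"
                         f"{varp:>8}{tp:>8}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# ECDF
# ---------------------------------------------------------------------------

class ECDF:
    """Right-continuous empirical CDF of a sample, evaluable anywhere."""

    def __init__(self, values):
        vals = np.asarray(values, dtype=float)
        if vals.size == 0:
            raise ConfigError("ECDF of an empty sample is undefined")
        self._sorted = np.sort(vals)
        self.n = vals.size

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self._sorted, x, side="right") / self.n
        return float(out) if out.ndim == 0 else out

    def table(self, step: float = 10.0) -> pd.DataFrame:
        """Evaluation grid from 0 to the sample maximum, for reports."""
        grid = np.arange(0.0, self._sorted[-1] + step, step)
        return pd.DataFrame({"agb": grid, "cdf": self(grid)})


def ecdf(values) -> ECDF:
    """Construct the empirical CDF of a value sample."""
    return ECDF(values)


# ---------------------------------------------------------------------------
# Monte-Carlo regime replication
# ---------------------------------------------------------------------------

def regime_replication(preset_comm: RegimePreset, preset_prof: RegimePreset,
                       n_comm: int, n_prof: int, n_reps: int, seed: int = 0,
                       config: ModelConfig | None = None) -> dict:
    """Replicate the comparison grid on freshly drawn synthetic samples.

    A single field campaign yields one p-value per grid cell; replicating
    the whole design ``n_reps`` times over independent draws turns those
    into estimable significance *rates*.  Returns, per non-baseline cell,
    the fraction of replicates whose t (and F) test is significant at the
    5 % level and the mean relative bias.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be at least 1")
    if config is None:
        config = ModelConfig()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_reps)
    cells: dict[tuple[str, str], dict[str, list]] = {}
    for rep in range(n_reps):
        s_comm, s_prof = children[rep].spawn(2)
        comm = make_metric_table(preset_comm, n_comm,
                                 seed=int(s_comm.generate_state(1)[0] % 2 ** 31))
        prof = make_metric_table(preset_prof, n_prof,
                                 seed=int(s_prof.generate_state(1)[0] % 2 ** 31))
        comm = comm.assign(team="Comm")
        prof = prof.assign(team="Prof")
        design = run_design(pd.concat([comm, prof], ignore_index=True), config)
        for r in design[~design["baseline"]].itertuples(index=False):
            key = (r.validation_set, r.training_set)
            cell = cells.setdefault(key, {"t_sig": [], "f_sig": [],
                                          "bias_pct": []})
            cell["t_sig"].append(r.t_test_p < ALPHA)
            cell["f_sig"].append(r.variance_test_p < ALPHA)
            cell["bias_pct"].append(r.bias_pct)
    out = {}
    for (vteam, tteam), cell in cells.items():
        out[f"{tteam} -> {vteam}"] = {
            "t_significance_rate": float(np.mean(cell["t_sig"])),
            "f_significance_rate": float(np.mean(cell["f_sig"])),
            "mean_bias_pct": float(np.mean(cell["bias_pct"])),
            "n_reps": n_reps,
        }
    return out
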