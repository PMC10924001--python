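"""Extra Trees recombination prediction with leave-one-chromosome-out (LOCO),
quartile-stratified evaluation, additive feature attributions, and
cross-dataset transfer.

The model is scikit-learn's ExtraTreesRegressor with library-default
hyperparameters (the defaults suffice for this problem class; they remain
overridable through :class:`ModelConfig`). Holding out one whole chromosome
per fold prevents positional leakage between adjacent windows.

Feature attributions are exact additive tree-path contributions: walking each
sample down each tree, the change in the node mean value at every split is
credited to the split feature, so per row

    prediction = base_value + sum_f contribution_f

holds to floating-point precision (base_value = mean of root node values
across trees). Ranking features by mean absolute contribution summarizes the
ensemble the same way additive explanation methods for tree models do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesRegressor

from .errors import ValidationError

DEFAULT_FEATURES = ("cg_s", "chg_s", "chh_s")
TARGET = "rate_s"


@dataclass(frozen=True)
class ModelConfig:
    """Feature subset, seed, and optional hyperparameter overrides."""

    features: tuple[str, ...] = DEFAULT_FEATURES
    seed: int = 0
    model_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.features:
            raise ValidationError("feature subset must be non-empty")

    def new_model(self) -> ExtraTreesRegressor:
        return ExtraTreesRegressor(random_state=self.seed, **self.model_params)


@dataclass
class EvalReport:
    """Per-chromosome metrics, window-level predictions, and attributions."""

    per_chrom: pd.DataFrame  # chrom, n, r2, r, mse, note
    predictions: pd.DataFrame  # chrom, window_index, start, end, rate_s_true, rate_s_pred
    summary: dict  # mean/sd of r2, r, mse over defined chromosomes
    contributions: pd.DataFrame | None = None  # per-row attributions
    contribution_ranking: pd.DataFrame | None = None  # feature, mean_abs, share


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """R^2 (about the truth's own mean; may be negative), Pearson r, MSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mse = float(np.mean((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    note = ""
    if ss_tot == 0.0:
        r2 = np.nan
        r = np.nan
        note = "zero rate variance on held-out chromosome"
    else:
        r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
        if np.std(y_pred) == 0:
            r, note = np.nan, "constant predictions"
        else:
            r = float(stats.pearsonr(y_true, y_pred)[0])
    return {"r2": r2, "r": r, "mse": mse, "note": note}


def _check_features(ct: pd.DataFrame, features: tuple[str, ...], what: str) -> None:
    missing = [f for f in features if f not in ct.columns]
    if missing:
        raise ValidationError(f"{what} table lacks feature columns {missing}")
    if TARGET not in ct.columns:
        raise ValidationError(f"{what} table lacks target column {TARGET}")


def _evaluate_per_chrom(
    model, ct_test: pd.DataFrame, features: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, preds = [], []
    for chrom, sub in ct_test.groupby("chrom", sort=True):
        y_pred = model.predict(sub[list(features)].to_numpy())
        y_true = sub[TARGET].to_numpy(dtype=float)
        m = regression_metrics(y_true, y_pred)
        rows.append({"chrom": chrom, "n": len(sub), **m})
        out = sub[["chrom", "window_index"]].copy()
        for col in ("start", "end"):
            if col in sub.columns:
                out[col] = sub[col].to_numpy()
        out["rate_s_true"] = y_true
        out["rate_s_pred"] = y_pred
        preds.append(out)
    return pd.DataFrame(rows), pd.concat(preds, ignore_index=True)


def _summarize(per_chrom: pd.DataFrame) -> dict:
    ok = per_chrom.dropna(subset=["r2"])
    return {
        "n_chromosomes": int(len(per_chrom)),
        "mean_r2": float(ok["r2"].mean()) if len(ok) else np.nan,
        "sd_r2": float(ok["r2"].std(ddof=1)) if len(ok) > 1 else np.nan,
        "mean_r": float(ok["r"].mean()) if len(ok) else np.nan,
        "sd_r": float(ok["r"].std(ddof=1)) if len(ok) > 1 else np.nan,
        "mean_mse": float(per_chrom["mse"].mean()) if len(per_chrom) else np.nan,
    }


def loco_evaluate(
    ct: pd.DataFrame, cfg: ModelConfig = ModelConfig(), attributions: str = "train"
) -> EvalReport:
    """Leave-one-chromosome-out evaluation of an Extra Trees regressor.

    Each chromosome is predicted by a model trained on all remaining
    chromosomes. Attributions (``"train"``, ``"holdout"`` or ``"none"``) come
    from a final model fit on all chromosomes; with ``"holdout"`` they are
    instead pooled from each fold's held-out rows.
    """
    _check_features(ct, cfg.features, "consensus")
    chroms = sorted(ct["chrom"].unique())
    if len(chroms) < 2:
        raise ValidationError("LOCO evaluation needs at least 2 chromosomes")
    per_rows, preds, holdout_contribs = [], [], []
    for chrom in chroms:
        train = ct[ct["chrom"] != chrom]
        test = ct[ct["chrom"] == chrom]
        model = cfg.new_model()
        model.fit(train[list(cfg.features)].to_numpy(), train[TARGET].to_numpy(dtype=float))
        pc, pr = _evaluate_per_chrom(model, test, cfg.features)
        per_rows.append(pc)
        preds.append(pr)
        if attributions == "holdout":
            contrib, base = tree_path_contributions(model, test[list(cfg.features)].to_numpy())
            cdf = pd.DataFrame(contrib, columns=list(cfg.features))
            cdf.insert(0, "window_index", test["window_index"].to_numpy())
            cdf.insert(0, "chrom", chrom)
            cdf["base_value"] = base
            holdout_contribs.append(cdf)

    per_chrom = pd.concat(per_rows, ignore_index=True)
    predictions = pd.concat(preds, ignore_index=True)
    report = EvalReport(
        per_chrom=per_chrom,
        predictions=predictions,
        summary=_summarize(per_chrom),
    )
    if attributions == "train":
        full = cfg.new_model()
        X = ct[list(cfg.features)].to_numpy()
        full.fit(X, ct[TARGET].to_numpy(dtype=float))
        contrib, base = tree_path_contributions(full, X)
        cdf = pd.DataFrame(contrib, columns=list(cfg.features))
        cdf.insert(0, "window_index", ct["window_index"].to_numpy())
        cdf.insert(0, "chrom", ct["chrom"].to_numpy())
        cdf["base_value"] = base
        report.contributions = cdf
        report.contribution_ranking = contribution_ranking(cdf, cfg.features)
    elif attributions == "holdout":
        report.contributions = pd.concat(holdout_contribs, ignore_index=True)
        report.contribution_ranking = contribution_ranking(report.contributions, cfg.features)
    return report


def transfer_evaluate(
    ct_train: pd.DataFrame, ct_test: pd.DataFrame, cfg: ModelConfig = ModelConfig(),
    normalize: bool = False,
) -> EvalReport:
    """Fit on every chromosome of one dataset, evaluate per chromosome of another.

    No rescaling is applied by default — raw smoothed counts cross datasets
    as-is; ``normalize=True`` z-scores features within each dataset for
    sensitivity analysis.
    """
    _check_features(ct_train, cfg.features, "training")
    _check_features(ct_test, cfg.features, "test")
    tr, te = ct_train, ct_test
    if normalize:
        tr, te = ct_train.copy(), ct_test.copy()
        for df in (tr, te):
            for f in cfg.features:
                sd = df[f].std(ddof=0)
                df[f] = (df[f] - df[f].mean()) / (sd if sd > 0 else 1.0)
    model = cfg.new_model()
    model.fit(tr[list(cfg.features)].to_numpy(), tr[TARGET].to_numpy(dtype=float))
    per_chrom, predictions = _evaluate_per_chrom(model, te, cfg.features)
    return EvalReport(
        per_chrom=per_chrom, predictions=predictions, summary=_summarize(per_chrom)
    )


def quartile_eval(
    predictions: pd.DataFrame, significance_level: float = 0.05
) -> pd.DataFrame:
    """Pearson r between predicted and true rates within chromosome quartiles.

    Each chromosome's windows (ordered by position) split into 4 contiguous
    blocks, remainders going to the earlier blocks (10 -> 3,3,2,2). Blocks
    with fewer than 3 windows or zero variance on either side report NaN with
    a reason.
    """
    rows = []
    for chrom, sub in predictions.groupby("chrom", sort=True):
        sub = sub.sort_values("window_index", kind="stable")
        blocks = np.array_split(np.arange(len(sub)), 4)
        for q, idx in enumerate(blocks, start=1):
            note = ""
            if len(idx) < 3:
                r_val, p_val, note = np.nan, np.nan, "fewer than 3 windows"
            else:
                yt = sub["rate_s_true"].to_numpy(dtype=float)[idx]
                yp = sub["rate_s_pred"].to_numpy(dtype=float)[idx]
                if np.std(yt) == 0 or np.std(yp) == 0:
                    r_val, p_val, note = np.nan, np.nan, "zero variance"
                else:
                    r_val, p_val = stats.pearsonr(yt, yp)
            rows.append(
                {
                    "chrom": chrom,
                    "quartile": f"Q{q}",
                    "n": len(idx),
                    "r": r_val,
                    "p": p_val,
                    "significant": bool(p_val < significance_level)
                    if not np.isnan(p_val)
                    else False,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


def tree_path_contributions(
    model: ExtraTreesRegressor, X: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact additive per-row, per-feature attributions for a tree ensemble.

    For each tree, a sample's prediction is the root value plus the sum of
    value changes along its decision path; each change is credited to the
    feature split at the parent node. Contributions are averaged over trees
    (the ensemble prediction is the tree mean). Returns (contributions with
    shape (n_rows, n_features), base_value).
    """
    if not hasattr(model, "estimators_"):
        raise ValidationError("attributions require a fitted tree-ensemble model")
    X = np.asarray(X, dtype=np.float32)
    n, p = X.shape
    total = np.zeros((n, p))
    base = 0.0
    for est in model.estimators_:
        t = est.tree_
        values = t.value[:, 0, 0]
        base += values[0]
        # parent feature / value delta for every non-root node
        parent_feat = np.full(t.node_count, -1, dtype=np.int64)
        delta = np.zeros(t.node_count)
        for node in range(t.node_count):
            for child in (t.children_left[node], t.children_right[node]):
                if child != -1:
                    parent_feat[child] = t.feature[node]
                    delta[child] = values[child] - values[node]
        # scatter node deltas into a (node_count, p) matrix; one sparse matmul
        # against the decision-path indicator accumulates per-feature sums
        D = np.zeros((t.node_count, p))
        nodes = np.nonzero(parent_feat >= 0)[0]
        D[nodes, parent_feat[nodes]] = delta[nodes]
        path = est.decision_path(X)  # sparse (n, node_count) indicator
        total += path @ D
    n_trees = len(model.estimators_)
    return total / n_trees, base / n_trees


def contribution_ranking(contrib: pd.DataFrame, features: tuple[str, ...]) -> pd.DataFrame:
    """Features ordered by mean |contribution|, with each one's share of the total."""
    mean_abs = contrib[list(features)].abs().mean()
    total = float(mean_abs.sum())
    out = pd.DataFrame(
        {
            "feature": mean_abs.index,
            "mean_abs_contribution": mean_abs.to_numpy(),
            "share": (mean_abs / total).to_numpy() if total > 0 else 0.0,
        }
    ).sort_values("mean_abs_contribution", ascending=False, ignore_index=True)
    return out


def write_report(report: EvalReport, prefix) -> None:
    """Persist metrics, predictions, and attributions as TSV/JSON next to ``prefix``."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    report.per_chrom.to_csv(f"{prefix}.metrics.tsv", sep="\t", index=False)
    report.predictions.to_csv(f"{prefix}.predictions.tsv", sep="\t", index=False)
    with open(f"{prefix}.summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if report.contributions is not None:
        report.contributions.to_csv(f"{prefix}.contributions.tsv", sep="\t", index=False)
    if report.contribution_ranking is not None:
        report.contribution_ranking.to_csv(
            f"{prefix}.contribution_ranking.tsv", sep="\t", index=False
        )
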