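"""Anti-overfitting battery and model-comparison harness.

A network that fits 17 points with 15 features can look good by memorising,
so every model is challenged with randomisation controls: Y-shuffling
(permute the labels, keep the features), X-, Y- and XY-randomisation (replace
features and/or labels with uniform noise).  A sound model loses all skill
under these controls -- shuffled RMSE should blow up and randomised R^2 should
sit near zero.

The harness also runs the five-metric bake-off (one model per selectivity
encoding, compared on a common S% scale) and the pure free-energy baseline
(er predicted directly from computed ddG values), the two comparisons that
frame the neural-network approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import FeatureTable
from .nn import (
    CVResult,
    NNConfig,
    clamp_metric_value,
    evaluate,
    loo_cross_validate,
    regression_metrics,
    train_table,
)
from .selectivity import (
    MajorLabel,
    Metric,
    SelectivityRecord,
    ThermoContext,
    from_metric,
)
from .synth import random_table

__all__ = [
    "RandomizationReport",
    "MetricBakeoff",
    "y_shuffle_test",
    "xy_randomization_test",
    "metric_bakeoff",
    "ddg_baseline",
    "BAKEOFF_METRICS",
]

BAKEOFF_METRICS = (Metric.ee, Metric.er_ratio, Metric.ln_er,
                   Metric.s_select, Metric.r_select)


@dataclass
class RandomizationReport:
    """Per-replicate LOO diagnostics under a randomisation mode, with the
    unrandomised reference run (when one exists) for contrast."""

    mode: str  # y_shuffle | x_random | y_random | xy_random
    replicates: int
    rmse: np.ndarray
    r_squared: np.ndarray       # NaN where degenerate
    reference_rmse: float | None = None
    reference_r_squared: float | None = None

    def __post_init__(self) -> None:
        if len(self.rmse) != self.replicates or len(self.r_squared) != self.replicates:
            raise ValueError("replicate arrays must match the replicate count")
        if np.any(self.rmse < 0):
            raise ValueError("negative RMSE")

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.rmse))

    @property
    def mean_r_squared(self) -> float:
        return float(np.nanmean(self.r_squared))

    @property
    def sd_r_squared(self) -> float:
        return float(np.nanstd(self.r_squared))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "replicates": self.replicates,
            "rmse": self.rmse.tolist(),
            "r_squared": self.r_squared.tolist(),
            "mean_rmse": self.mean_rmse,
            "sd_rmse": self.sd_rmse,
            "mean_r_squared": self.mean_r_squared,
            "sd_r_squared": self.sd_r_squared,
            "reference_rmse": self.reference_rmse,
            "reference_r_squared": self.reference_r_squared,
        }


def _shuffled_labels(t: FeatureTable, perm: np.ndarray) -> FeatureTable:
    ids = t.ligand_ids
    labels = {ids[i]: t.labels[ids[perm[i]]] for i in range(len(ids))}
    return FeatureTable(t.df.copy(), dict(t.provenance), labels)


def y_shuffle_test(
    t: FeatureTable,
    cfg: NNConfig,
    replicates: int = 20,
    seed: int = 0,
    permutations: list[np.ndarray] | None = None,
) -> RandomizationReport:
    """Permute the labels, keep the features, and re-run the full LOO pipeline.

    The label multiset is preserved in every replicate; an explicit list of
    permutations may be supplied (e.g. the identity, as a control that must
    reproduce the reference run exactly).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if t.labels is None:
        raise ValueError("Y-shuffling requires labels")
    t = t.sorted_by_id()
    n = t.n_ligands
    reference = loo_cross_validate(t, cfg)
    rng = np.random.default_rng(seed)
    if permutations is not None and len(permutations) != replicates:
        raise ValueError("need one permutation per replicate")
    rmse = np.empty(replicates)
    r2 = np.empty(replicates)
    for rep in range(replicates):
        perm = (np.asarray(permutations[rep]) if permutations is not None
                else rng.permutation(n))
        try:
            res = loo_cross_validate(_shuffled_labels(t, perm), cfg)
        except Exception as exc:
            raise type(exc)(f"replicate {rep}: {exc}") from exc
        rmse[rep] = res.rmse
        r2[rep] = res.r_squared
    return RandomizationReport("y_shuffle", replicates, rmse, r2,
                               reference.rmse, reference.r_squared)


def xy_randomization_test(
    n: int,
    p: int,
    label_range: tuple[float, float],
    cfg: NNConfig,
    replicates: int = 20,
    seed: int = 0,
    mode: str = "xy_random",
    template: FeatureTable | None = None,
) -> RandomizationReport:
    """LOO on randomised data.

    ``xy_random`` draws both features (uniform on [0, 1]) and labels (uniform
    on ``label_range``) fresh each replicate.  ``x_random`` keeps the template
    table's labels and randomises the features; ``y_random`` the reverse.  A
    well-behaved pipeline shows mean R^2 near zero and RMSE on the order of
    the label standard deviation ((hi-lo)/sqrt(12) for uniform labels).
    """
    if mode not in ("xy_random", "x_random", "y_random"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "xy_random" and (template is None or template.labels is None):
        raise ValueError(f"mode {mode!r} needs a labelled template table")
    if n < 3 or p < 1:
        raise ValueError("need n >= 3 and p >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rmse = np.empty(replicates)
    r2 = np.empty(replicates)
    reference_rmse = reference_r2 = None
    if template is not None and template.labels is not None:
        ref = loo_cross_validate(template, cfg)
        reference_rmse, reference_r2 = ref.rmse, ref.r_squared
    for rep in range(replicates):
        rep_seed = seed + 1000 * rep
        rand = random_table(n, p, label_range, seed=rep_seed)
        if mode == "x_random":
            tmpl = template.sorted_by_id()
            rand = FeatureTable(
                rand.df.iloc[: tmpl.n_ligands].set_axis(tmpl.ligand_ids).copy(),
                {},
                dict(tmpl.labels),
            )
        elif mode == "y_random":
            tmpl = template.sorted_by_id()
            s = np.clip(
                np.random.default_rng(rep_seed).uniform(*label_range, tmpl.n_ligands),
                0.05, 99.95,
            )
            labels = {
                i: SelectivityRecord(float(v), float(100.0 - v))
                for i, v in zip(tmpl.ligand_ids, s)
            }
            rand = FeatureTable(tmpl.df.copy(), dict(tmpl.provenance), labels)
        try:
            res = loo_cross_validate(rand, cfg)
        except Exception as exc:
            raise type(exc)(f"replicate {rep}: {exc}") from exc
        rmse[rep] = res.rmse
        r2[rep] = res.r_squared
    return RandomizationReport(mode, replicates, rmse, r2,
                               reference_rmse, reference_r2)


# ---------------------------------------------------------------------------
# Five-metric bake-off
# ---------------------------------------------------------------------------

@dataclass
class MetricBakeoff:
    """One model per selectivity encoding, compared on the common S% scale."""

    per_metric: dict[Metric, dict] = field(default_factory=dict)
    winner: Metric | None = None

    def to_dict(self) -> dict:
        return {
            "winner": self.winner.value if self.winner else None,
            "per_metric": {
                m.value: {
                    "train_loo": (entry["train_loo"].to_dict()
                              if entry["train_loo"] is not None else None),
                    "validation_rmse_s": entry["validation_rmse_s"],
                    "validation_r_squared_s": entry["validation_r_squared_s"],
                    "n_clamped": entry["n_clamped"],
                }
                for m, entry in self.per_metric.items()
            },
        }


def _prediction_to_s_percent(value: float, metric: Metric) -> tuple[float, bool]:
    clamped, was = clamp_metric_value(value, metric)
    rec = from_metric(clamped, metric, MajorLabel.S)
    return rec.s_percent, was


def metric_bakeoff(
    train: FeatureTable,
    validation: FeatureTable,
    cfg: NNConfig,
    *,
    run_train_loo: bool = True,
) -> MetricBakeoff:
    """Train one model per metric (ee, er, ln er, S%, R%) on the training
    table and compare them on the validation table.

    Every prediction is converted to the S percentage before scoring, so the
    five RMSEs are on a single 0-100 scale; the winner is the metric with the
    lowest validation RMSE (ties resolved toward s_select, then
    alphabetically).  Out-of-domain predictions (negative er ratios etc.) are
    clamped to the nearest valid value and counted, not fatal.
    """
    if train.labels is None or validation.labels is None:
        raise ValueError("bake-off needs labels on both tables")
    missing = set(train.feature_names) ^ set(validation.feature_names)
    if missing:
        raise ValueError(f"feature name mismatch between tables: {sorted(missing)}")
    validation = validation.sorted_by_id()
    observed_s = np.array([validation.labels[i].s_percent
                           for i in validation.ligand_ids])
    out = MetricBakeoff()
    for metric in BAKEOFF_METRICS:
        mcfg = replace(cfg, target_metric=metric)
        loo = loo_cross_validate(train, mcfg) if run_train_loo else None
        model = train_table(train, mcfg)
        report = evaluate(model, validation)
        preds = report["result"].predicted
        s_pred = np.empty(len(preds))
        n_clamped = 0
        for i, v in enumerate(preds):
            s_pred[i], was = _prediction_to_s_percent(float(v), metric)
            n_clamped += was
        rmse, r2, _, _, _ = regression_metrics(observed_s, s_pred)
        out.per_metric[metric] = {
            "train_loo": loo,
            "validation_rmse_s": rmse,
            "validation_r_squared_s": r2,
            "n_clamped": n_clamped,
            "predictions_s": s_pred,
        }
    def _order(m: Metric):
        return (out.per_metric[m]["validation_rmse_s"],
                0 if m is Metric.s_select else 1, m.value)
    out.winner = min(BAKEOFF_METRICS, key=_order)
    return out


# ---------------------------------------------------------------------------
# Pure free-energy baseline
# ---------------------------------------------------------------------------

def ddg_baseline(
    ddg_table: dict[str, float],
    labels: dict[str, SelectivityRecord],
    ctx: ThermoContext | None = None,
    nn_result: CVResult | None = None,
) -> dict:
    """Score the conventional route: er straight from computed ddG values.

    ``ddg_table`` holds signed free-energy gaps in kcal/mol, positive when the
    S transition state is lower (S major); a negative value simply favours the
    R enantiomer and is counted, not rejected.  Predicted S% = 100 K/(1+K)
    with K = exp(ddG/RT) is compared with the experimental S%; the neural
    network's numbers ride along for side-by-side reporting when supplied.
    """
    ctx = ctx or ThermoContext()
    ids = sorted(set(ddg_table) & set(labels))
    if not ids:
        raise ValueError("no overlapping ligand ids between ddG table and labels")
    observed = np.array([labels[i].s_percent for i in ids])
    k = np.exp(np.array([ddg_table[i] for i in ids]) / ctx.rt)
    predicted = 100.0 * k / (1.0 + k)
    n_negative = sum(1 for i in ids if ddg_table[i] < 0)
    rmse, r2, slope, degenerate, cod = regression_metrics(observed, predicted)
    report = {
        "ligand_ids": ids,
        "observed_s": observed.tolist(),
        "predicted_s": predicted.tolist(),
        "rmse": rmse,
        "r_squared": r2,
        "slope": slope,
        "degenerate": degenerate,
        "n_negative_ddg": n_negative,
        "temperature_K": ctx.temperature_K,
    }
    if nn_result is not None:
        report["nn"] = {"rmse": nn_result.rmse, "r_squared": nn_result.r_squared,
                        "slope": nn_result.slope}
    return report
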