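"""Leave-one-patient-out evaluation, metrics, significance, ablation.

Cross-validation is at the patient level: each fold trains the CNN and the
EKI model on all other patients and predicts every IC of the held-out
patient, so each IC is predicted exactly once and no patient contributes to
both sides of a fold.

Metrics follow the SOZ-vs-rest framing per IC: precision = TP/(TP+FP),
sensitivity = TP/(TP+FN), accuracy over the binarized SOZ decision, and F1
as the harmonic mean of precision and sensitivity.  A patient-level
sensitivity (fraction of patients with at least one correctly identified
SOZ IC) is reported alongside.  The knowledge-ablation runner refits the
EKI arm with one expert feature removed at a time (the CNN arm does not
depend on the features, so its per-fold predictions are reused).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .eki import FEATURE_NAMES
from .pipeline import (
    PipelineConfig,
    PrecomputedCohort,
    SozPipeline,
    fit_baseline_3class,
    precompute,
    predict_baseline_3class,
)


@dataclass
class EvaluationReport:
    predictions: pd.DataFrame  # per-IC: truth + final (+ arm outputs)
    metrics: dict
    subgroup_metrics: dict
    patient_sensitivity: float
    variant: str = "full"
    seed: int = 0
    n_folds: int = 0
    extras: dict = field(default_factory=dict)


def f1_from_precision_sensitivity(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (same units as inputs)."""
    if precision + sensitivity == 0:
        return float("nan")
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def compute_metrics(
    predictions: list[str] | np.ndarray,
    truths: list[str] | np.ndarray,
    positive_class: str = "SOZ",
) -> dict:
    """Confusion counts and derived metrics for the positive-vs-rest task.

    Undefined ratios (zero denominators) are reported as NaN and listed in
    ``zero_denominator``.
    """
    pred = np.asarray(predictions)
    truth = np.asarray(truths)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    p = pred == positive_class
    t = truth == positive_class
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return float("nan")
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    out = {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "accuracy": (tp + tn) / len(pred),
        "precision": precision,
        "sensitivity": sensitivity,
        "f1": f1_from_precision_sensitivity(precision, sensitivity)
        if not (np.isnan(precision) or np.isnan(sensitivity))
        else float("nan"),
        "zero_denominator": flags,
    }
    return out


def _patient_sensitivity(df: pd.DataFrame) -> float:
    """Fraction of patients with >= 1 true-SOZ IC correctly called SOZ."""
    hits, n = 0, 0
    for _, g in df.groupby("patient_id"):
        soz = g[g["truth"] == "SOZ"]
        if len(soz) == 0:
            continue
        n += 1
        if (soz["final"] == "SOZ").any():
            hits += 1
    return hits / n if n else float("nan")


def _subgroups(df: pd.DataFrame) -> dict:
    out = {}
    for col in ("age_group", "sex"):
        for value, g in df.groupby(col):
            out[f"{col}={value}"] = compute_metrics(g["final"], g["truth"])
    return out


def _report_from_predictions(
    df: pd.DataFrame, variant: str, seed: int, n_folds: int, extras: dict | None = None
) -> EvaluationReport:
    return EvaluationReport(
        predictions=df,
        metrics=compute_metrics(df["final"], df["truth"]),
        subgroup_metrics=_subgroups(df),
        patient_sensitivity=_patient_sensitivity(df),
        variant=variant,
        seed=seed,
        n_folds=n_folds,
        extras=extras or {},
    )


def _fold_indices(pre: PrecomputedCohort) -> list[tuple[str, np.ndarray, np.ndarray]]:
    patients = pre.table["patient_id"].to_numpy()
    uniq = list(dict.fromkeys(patients))  # stable order
    if len(uniq) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    folds = []
    for pid in uniq:
        test = np.flatnonzero(patients == pid)
        train = np.flatnonzero(patients != pid)
        folds.append((pid, train, test))
    return folds


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 1009 + fold) % (2**31)


def loocv(
    pre: PrecomputedCohort,
    config: PipelineConfig | None = None,
    variant: str = "full",
    dl_cache: dict | None = None,
    progress: bool = False,
) -> EvaluationReport:
    """Leave-one-patient-out evaluation of the full hybrid pipeline.

    ``dl_cache`` (fold -> CNN prediction frame) lets ablation variants
    reuse the CNN arm, which is independent of the expert features; when
    provided and incomplete it is filled in place.
    """
    config = config or pre.pipeline_config
    folds = _fold_indices(pre)
    frames = []
    cache = dl_cache if dl_cache is not None else {}
    for k, (pid, train, test) in enumerate(folds):
        if (pre.table["label"].iloc[train] == "SOZ").sum() < 2:
            raise ValueError(
                f"training union for fold {pid} has <2 SOZ ICs; SMOTE infeasible "
                "(increase cohort size or SOZ fraction)"
            )
        pipe = SozPipeline(config)
        seed = _fold_seed(config.seed, k)
        if k in cache:
            pipe.eki_model = pipe._fit_eki(pre, train, seed)
            dl_frame = cache[k]
            out = _predict_with_dl(pipe, pre, test, dl_frame)
        else:
            pipe.fit(pre, train, seed)
            out = pipe.predict(pre, test)
            cache[k] = out[["ic_id", "dl_label", "p_non_noise"]].copy()
        out["patient_id"] = pid
        out["truth"] = pre.table["label"].iloc[test].to_numpy()
        out["age_group"] = pre.table["age_group"].iloc[test].to_numpy()
        out["sex"] = pre.table["sex"].iloc[test].to_numpy()
        frames.append(out)
        if progress:
            print(f"  fold {k + 1}/{len(folds)} ({pid}) done")
    df = pd.concat(frames)
    return _report_from_predictions(df, variant, config.seed, len(folds))


def _predict_with_dl(
    pipe: SozPipeline, pre: PrecomputedCohort, idx: np.ndarray, dl_frame: pd.DataFrame
) -> pd.DataFrame:
    """EKI + fusion on cached CNN outputs."""
    from . import eki as eki_mod
    from . import fusion as fusion_mod

    feats = pre.feature_matrix(pipe.config.enabled_features)[idx]
    rows = []
    for k, i in enumerate(np.asarray(idx)):
        eki_label, rho, expl = eki_mod.classify_eki(pipe.eki_model, feats[k])
        dl_label = str(dl_frame["dl_label"].iloc[k])
        fused = fusion_mod.FusedLabel(
            ic_id=pre.table["ic_id"].iloc[i],
            dl_label=dl_label,
            eki_label=eki_label,
            rho=rho,
            explanation=expl,
        )
        rows.append(
            {
                "ic_id": fused.ic_id,
                "dl_label": dl_label,
                "p_non_noise": float(dl_frame["p_non_noise"].iloc[k]),
                "eki_label": eki_label,
                "rho": rho,
                "final": fused.final,
                "explanation": fused.explanation,
            }
        )
    return pd.DataFrame(rows, index=np.asarray(idx))


def loocv_baseline(
    pre: PrecomputedCohort,
    config: PipelineConfig | None = None,
    progress: bool = False,
) -> EvaluationReport:
    """Leave-one-patient-out evaluation of the cost-sensitive 3-class CNN."""
    config = config or pre.pipeline_config
    folds = _fold_indices(pre)
    frames = []
    for k, (pid, train, test) in enumerate(folds):
        model = fit_baseline_3class(pre, train, _fold_seed(config.seed, k))
        out = predict_baseline_3class(model, pre, test)
        out["patient_id"] = pid
        out["truth"] = pre.table["label"].iloc[test].to_numpy()
        out["age_group"] = pre.table["age_group"].iloc[test].to_numpy()
        out["sex"] = pre.table["sex"].iloc[test].to_numpy()
        frames.append(out)
        if progress:
            print(f"  baseline fold {k + 1}/{len(folds)} ({pid}) done")
    df = pd.concat(frames)
    return _report_from_predictions(df, "baseline_3class_cnn", config.seed, len(folds))


def eok_delta(
    report_hybrid: EvaluationReport | dict, report_dl: EvaluationReport | dict
) -> dict:
    """Effect of knowledge: per-metric difference (hybrid minus DL-only).

    Both reports must cover the identical set of ICs.
    """
    def unpack(r):
        if isinstance(r, EvaluationReport):
            return r.metrics, set(r.predictions["ic_id"])
        return r, None

    m1, ids1 = unpack(report_hybrid)
    m2, ids2 = unpack(report_dl)
    if ids1 is not None and ids2 is not None and ids1 != ids2:
        raise ValueError("reports cover different test sets")
    keys = ("accuracy", "precision", "sensitivity", "f1")
    return {k: m1[k] - m2[k] for k in keys if k in m1 and k in m2}


def significance_tests(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
) -> dict:
    """KS normality check per method plus a one-sided two-sample t-test
    (alternative: method A greater).

    Identical samples give t-test p = 0.5 (zero observed difference under a
    symmetric null); degenerate zero-variance samples with a non-zero
    difference are reported as p -> 0 or 1 and flagged.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 subgroup samples per method")

    def ks_normal(x):
        sd = x.std(ddof=1)
        if sd == 0:
            return float("nan")
        return float(stats.kstest((x - x.mean()) / sd, "norm").pvalue)

    out = {"ks_p_a": ks_normal(a), "ks_p_b": ks_normal(b)}
    var = a.var(ddof=1) + b.var(ddof=1)
    if var == 0:
        diff = a.mean() - b.mean()
        out["t_p"] = 0.5 if diff == 0 else (0.0 if diff > 0 else 1.0)
        out["degenerate"] = True
    else:
        out["t_p"] = float(stats.ttest_ind(a, b, alternative="greater").pvalue)
        out["degenerate"] = False
    out["alpha"] = 0.05
    out["significant"] = bool(out["t_p"] < 0.05)
    return out


def ablation_suite(
    pre: PrecomputedCohort,
    config: PipelineConfig | None = None,
    features_to_mask: tuple[str, ...] | None = None,
    dl_cache: dict | None = None,
    progress: bool = False,
) -> dict[str, EvaluationReport]:
    """Full LOOCV per knowledge-ablation variant.

    Variants: the full model plus one run per masked feature ("without_X").
    The CNN arm is trained once per fold and shared across variants (pass a
    pre-filled ``dl_cache`` to reuse folds from an earlier run).
    """
    config = config or pre.pipeline_config
    features_to_mask = features_to_mask or FEATURE_NAMES
    for f in features_to_mask:
        if f not in config.enabled_features:
            raise ValueError(f"cannot mask disabled feature {f!r}")
        if len(config.enabled_features) == 1:
            raise ValueError("masking the only enabled feature is not allowed")
    if dl_cache is None:
        dl_cache = {}
    reports = {"full": loocv(pre, config, "full", dl_cache, progress)}
    for f in features_to_mask:
        enabled = tuple(n for n in config.enabled_features if n != f)
        cfg = replace(config, enabled_features=enabled)
        reports[f"without_{f}"] = loocv(pre, cfg, f"without_{f}", dl_cache, progress)
    return reports


def parameter_recovery_study(
    seed: int = 1,
    n_patients: int = 10,
    ics_per_patient: int = 100,
    separation: float = 1.0,
    progress: bool = False,
) -> dict:
    """The full synthetic parameter-recovery experiment in one call.

    Generates the standard study cohort (10 patients x 100 ICs at textbook
    separation), runs hybrid LOOCV, the cost-sensitive 3-class CNN baseline
    on the same folds, and the knowledge-ablation suite (sharing the
    per-fold CNN arm).  Arm accuracies are pooled over held-out folds: the
    CNN arm against the binarized truth, the EKI arm over true RSN/SOZ ICs
    only.
    """
    from . import synthetic as syn
    from .cnn import relabel_for_noise

    cfg = syn.SyntheticConfig(
        seed=seed,
        n_patients=n_patients,
        ics_per_patient=ics_per_patient,
        separation=separation,
    )
    pcfg = PipelineConfig(seed=seed)
    if progress:
        print("precomputing cohort ...")
    pre = precompute(cfg, pcfg, progress)
    dl_cache: dict = {}
    report = loocv(pre, pcfg, "full", dl_cache, progress)
    baseline = loocv_baseline(pre, pcfg, progress)
    ablation = ablation_suite(pre, pcfg, dl_cache=dl_cache, progress=progress)

    df = report.predictions
    binary_truth = np.array(relabel_for_noise(df["truth"].tolist()))
    cnn_accuracy = float(np.mean(df["dl_label"].to_numpy() == binary_truth))
    rs = df[df["truth"].isin(["RSN", "SOZ"])]
    eki_accuracy = float(np.mean(rs["eki_label"].to_numpy() == rs["truth"].to_numpy()))
    return {
        "config": cfg,
        "pipeline_config": pcfg,
        "precomputed": pre,
        "report": report,
        "baseline": baseline,
        "ablation": ablation,
        "ablation_table": ablation_table(ablation),
        "cnn_accuracy": cnn_accuracy,
        "eki_accuracy": eki_accuracy,
        "eok": eok_delta(report, baseline),
    }


def ablation_table(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Accuracy / F1 per variant with absolute and relative F1 change
    against the full model."""
    full_f1 = reports["full"].metrics["f1"]
    rows = []
    for name, r in reports.items():
        f1 = r.metrics["f1"]
        rows.append(
            {
                "variant": name,
                "accuracy": r.metrics["accuracy"],
                "f1": f1,
                "delta_f1": f1 - full_f1,
                "delta_f1_relative": (f1 - full_f1) / full_f1 if full_f1 else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("variant")
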