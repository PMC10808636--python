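"""End-to-end plumbing: feature extraction, cohort precompute, the trained
CNN + EKI pipeline, and the 3-class CNN-only baseline.

Per IC the stages are: locate slice tiles on the native montage, find
retained activation clusters per slice (DBSCAN), derive activation-free
anatomy for slices that carry clusters (two-pass protocol), and assemble
the four expert features together with the CNN input image.  Features and
images are precomputed once per cohort; model fitting and prediction then
operate on index subsets (e.g. cross-validation folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import cnn as cnn_mod
from . import eki as eki_mod
from . import fusion as fusion_mod
from . import montage as montage_mod
from . import spatial as spatial_mod
from . import synthetic as synthetic_mod
from . import temporal as temporal_mod
from .eki import FEATURE_NAMES

FEATURE_COLUMNS = [f"f_{name}" for name in FEATURE_NAMES]


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline (every run logs these)."""

    dbscan: spatial_mod.DbscanParams = field(default_factory=spatial_mod.DbscanParams)
    cnn: cnn_mod.CnnConfig = field(default_factory=cnn_mod.CnnConfig.small)
    rho_threshold: float = fusion_mod.RHO_THRESHOLD
    enabled_features: tuple[str, ...] = FEATURE_NAMES
    smote_k: int = 5
    match_threshold: float = montage_mod.MATCH_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.enabled_features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        if len(self.enabled_features) < 1:
            raise ValueError("at least one expert feature must stay enabled")


def extract_ic_features(
    m: montage_mod.ICMontage,
    ts: temporal_mod.BoldTimecourse,
    dbscan: spatial_mod.DbscanParams | None = None,
    template: np.ndarray | None = None,
    match_threshold: float = montage_mod.MATCH_THRESHOLD,
) -> tuple[eki_mod.ExpertFeatureVector, list[spatial_mod.ActivationCluster]]:
    """The full 4-vector of expert features for one IC, plus its retained
    activation clusters (for localization)."""
    dbscan = dbscan or spatial_mod.DbscanParams()
    if template is None:
        template = synthetic_mod.slice_template()
    slices = montage_mod.extract_brain_slices(m, template, match_threshold)
    slice_clusters = []
    for s in slices:
        mask = montage_mod.activation_mask(s)
        clusters = (
            spatial_mod.dbscan_clusters(mask, dbscan, s.tile_index) if mask.any() else []
        )
        slice_clusters.append((s, clusters))
    f1 = spatial_mod.f_clusters(slice_clusters)
    anatomy_clusters = []
    for s, clusters in slice_clusters:
        if clusters:
            anatomy = montage_mod.detect_anatomy(montage_mod.remove_activation(s))
            anatomy_clusters.append((anatomy, clusters))
    f2 = spatial_mod.f_wm_ventricle(anatomy_clusters)
    summary = temporal_mod.sparsity_summary(ts)
    vec = eki_mod.ExpertFeatureVector(
        np.array([f1, f2, summary.activelet_gini, summary.sine_gini]),
        ic_id=m.ic_id,
    )
    all_clusters = [c for _, cl in slice_clusters for c in cl]
    return vec, all_clusters


def montage_to_cnn_input(
    m: montage_mod.ICMontage, input_size: tuple[int, int]
) -> np.ndarray:
    """CNN input image scaled to [0, 1] float32.

    The default path is the contract resize to 270 x 470.  For smaller
    input sizes (the fast configuration) the native image is first reduced
    by a 4 x 4 local mean — an anti-aliasing prefilter an order of
    magnitude cheaper than the Gaussian resize on the full montage — before
    the final interpolation.
    """
    if tuple(input_size) == montage_mod.RESIZED_SIZE:
        resized = montage_mod.resize_montage(m) if m.native else m
        return resized.pixels.astype(np.float32) / 255.0
    arr = m.pixels.astype(np.float32) / 255.0
    if m.native:
        h, w = arr.shape[:2]
        hb, wb = (h // 4) * 4, (w // 4) * 4
        arr = arr[:hb, :wb].reshape(hb // 4, 4, wb // 4, 4, 3).mean(axis=(1, 3))
    return _sk_resize(arr, input_size, order=1, anti_aliasing=False).astype(np.float32)


@dataclass
class PrecomputedCohort:
    """Per-IC features, metadata and CNN-ready images for one cohort."""

    table: pd.DataFrame
    images: np.ndarray
    pipeline_config: PipelineConfig

    @property
    def n_ics(self) -> int:
        return len(self.table)

    def feature_matrix(self, enabled: tuple[str, ...] | None = None) -> np.ndarray:
        enabled = enabled or tuple(FEATURE_NAMES)
        cols = [f"f_{n}" for n in enabled]
        return self.table[cols].to_numpy(dtype=float)


def precompute(
    source: synthetic_mod.SyntheticConfig | synthetic_mod.SyntheticCohort,
    config: PipelineConfig | None = None,
    progress: bool = False,
) -> PrecomputedCohort:
    """Extract features and CNN inputs for every IC of a cohort.

    Accepts either a materialized cohort or a synthetic config (streamed,
    so native-resolution pixel data is never all in memory at once).
    """
    config = config or PipelineConfig()
    template = synthetic_mod.slice_template()
    if isinstance(source, synthetic_mod.SyntheticCohort):
        stream = (
            (
                {"patient_id": p.patient_id, "age_group": p.age_group, "sex": p.sex},
                m,
                ts,
                lab,
            )
            for p, m, ts, lab in source.all_ics()
        )
    else:
        stream = synthetic_mod.stream_cohort(source)
    rows, images = [], []
    for i, (meta, m, ts, label) in enumerate(stream):
        vec, _ = extract_ic_features(
            m, ts, config.dbscan, template, config.match_threshold
        )
        images.append(montage_to_cnn_input(m, config.cnn.input_size))
        rows.append(
            {
                "patient_id": meta["patient_id"],
                "ic_id": m.ic_id,
                "label": label,
                "age_group": meta["age_group"],
                "sex": meta["sex"],
                **{col: v for col, v in zip(FEATURE_COLUMNS, vec.values)},
            }
        )
        if progress and (i + 1) % 100 == 0:
            print(f"  precompute: {i + 1} ICs")
    return PrecomputedCohort(
        table=pd.DataFrame(rows),
        images=np.stack(images),
        pipeline_config=config,
    )


def load_cohort(path) -> synthetic_mod.SyntheticCohort:
    """Read a cohort written by ``sozloc synth --write-png``: PNG montages,
    a label manifest and long-format time courses."""
    import json
    from pathlib import Path

    from PIL import Image

    path = Path(path)
    manifest = pd.read_csv(path / "manifest.csv")
    series = pd.read_csv(path / "timecourses.csv")
    cfg_file = path / "config.json"
    if cfg_file.exists():
        cfg_dict = json.loads(cfg_file.read_text())
        for key in ("class_proportions", "montage_grid", "native_size"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = synthetic_mod.SyntheticConfig(**cfg_dict)
    else:
        config = synthetic_mod.SyntheticConfig()
    patients: dict[str, synthetic_mod.PatientRecord] = {}
    for row in manifest.itertuples():
        pid = row.patient_id
        if pid not in patients:
            patients[pid] = synthetic_mod.PatientRecord(pid, row.age_group, row.sex)
        m = montage_mod.ICMontage(
            pixels=np.asarray(Image.open(path / f"{row.ic_id}.png"))[..., :3],
            ic_id=row.ic_id,
            patient_id=pid,
            label=row.label,
        )
        ts = temporal_mod.BoldTimecourse(
            samples=series[row.ic_id].to_numpy(),
            tr_seconds=config.tr_seconds,
            ic_id=row.ic_id,
        )
        patients[pid].ics.append((m, ts, row.label))
    return synthetic_mod.SyntheticCohort(config=config, patients=list(patients.values()))


# ---------------------------------------------------------------------------
# trained pipeline
# ---------------------------------------------------------------------------

CLASS_ORDER = ("NOISE", "RSN", "SOZ")


@dataclass
class SozPipeline:
    """The trained pair of models plus the fusion rule."""

    config: PipelineConfig
    cnn_model: cnn_mod.NoiseCnn | None = None
    eki_model: eki_mod.EKIModel | None = None

    def fit(
        self, pre: PrecomputedCohort, train_idx: np.ndarray, seed: int | None = None
    ) -> "SozPipeline":
        seed = self.config.seed if seed is None else seed
        sub = pre.table.iloc[train_idx]
        labels = sub["label"].tolist()
        binary = np.array(
            [1 if b == "NON_NOISE" else 0 for b in cnn_mod.relabel_for_noise(labels)]
        )
        cfg = replace(self.config.cnn, seed=int(seed) % (2**31))
        self.cnn_model = cnn_mod.build_model(cfg)
        cnn_mod.train(self.cnn_model, pre.images[train_idx], binary)
        self.eki_model = self._fit_eki(pre, train_idx, seed)
        return self

    def _fit_eki(
        self, pre: PrecomputedCohort, train_idx: np.ndarray, seed: int
    ) -> eki_mod.EKIModel:
        sub = pre.table.iloc[train_idx]
        keep = sub["label"].isin(["RSN", "SOZ"]).to_numpy()
        feats = pre.feature_matrix(self.config.enabled_features)[train_idx][keep]
        labs = sub["label"][keep].tolist()
        vectors = [
            eki_mod.ExpertFeatureVector(v, feature_names=self.config.enabled_features)
            for v in feats
        ]
        pairs = eki_mod.make_pairs(vectors, labs)
        pairs = eki_mod.balance_with_smote(
            pairs, self.config.smote_k, np.random.default_rng(int(seed) % (2**31))
        )
        return eki_mod.fit_weights(
            pairs, self.config.rho_threshold, self.config.enabled_features
        )

    def predict(self, pre: PrecomputedCohort, idx: np.ndarray) -> pd.DataFrame:
        if self.cnn_model is None or self.eki_model is None:
            raise RuntimeError("pipeline is not fitted")
        p_nonnoise = self.cnn_model.predict_proba(pre.images[idx])
        dl = np.where(p_nonnoise >= 0.5, "NON_NOISE", "NOISE")
        feats = pre.feature_matrix(self.config.enabled_features)[idx]
        rows = []
        for k, i in enumerate(np.asarray(idx)):
            eki_label, rho, expl = eki_mod.classify_eki(self.eki_model, feats[k])
            fused = fusion_mod.FusedLabel(
                ic_id=pre.table["ic_id"].iloc[i],
                dl_label=str(dl[k]),
                eki_label=eki_label,
                rho=rho,
                explanation=expl,
            )
            rows.append(
                {
                    "ic_id": fused.ic_id,
                    "dl_label": fused.dl_label,
                    "p_non_noise": float(p_nonnoise[k]),
                    "eki_label": fused.eki_label,
                    "rho": fused.rho,
                    "final": fused.final,
                    "explanation": fused.explanation,
                }
            )
        return pd.DataFrame(rows, index=np.asarray(idx))


def fit_baseline_3class(
    pre: PrecomputedCohort, train_idx: np.ndarray, seed: int
) -> cnn_mod.NoiseCnn:
    """Cost-sensitive 3-class CNN (the labels-only baseline): same backbone
    with a softmax head and inverse-frequency class weights."""
    labels = pre.table["label"].iloc[train_idx].tolist()
    y = np.array([CLASS_ORDER.index(lab) for lab in labels])
    counts = np.bincount(y, minlength=3).astype(float)
    weights = counts.sum() / np.maximum(counts, 1) / 3.0
    cfg = replace(pre.pipeline_config.cnn, n_classes=3, seed=int(seed) % (2**31))
    model = cnn_mod.build_model(cfg)
    cnn_mod.train(model, pre.images[train_idx], y, class_weights=weights)
    return model


def predict_baseline_3class(
    model: cnn_mod.NoiseCnn, pre: PrecomputedCohort, idx: np.ndarray
) -> pd.DataFrame:
    proba = model.predict_proba(pre.images[idx])
    final = [CLASS_ORDER[k] for k in np.argmax(proba, axis=1)]
    return pd.DataFrame(
        {"ic_id": pre.table["ic_id"].iloc[idx].to_numpy(), "final": final},
        index=np.asarray(idx),
    )
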