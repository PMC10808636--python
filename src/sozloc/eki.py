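"""The expert-knowledge arm: feature balancing, weight fitting, scoring.

Each RSN/SOZ training IC contributes an L2-normalized expert feature vector
``F_hat = F_ex / ||F_ex||`` with target ``y = -1`` (RSN) or ``y = +1``
(SOZ).  Because SOZ ICs are rare (~5% of the data), the minority class is
first balanced by SMOTE: synthetic samples are linear interpolations
between a minority sample and one of its k nearest minority neighbors.

The expert-knowledge weight vector ``omega`` then minimizes

    sum_i (1 - y_i * omega . F_hat_i)^2   subject to   sum_j omega_j = 1,

a linear equality-constrained least-squares problem solved in closed form
(null-space parametrization); among minimizers the minimum-norm one is
returned.  ``omega`` is *not* constrained non-negative — only the sum
constraint is imposed.

An IC's confidence score is ``rho = omega . F / ||F||`` (scale-invariant in
F); the EKI label is SOZ iff rho > 0, the sign rule induced by the +/-1
target coding.  The feature with the largest contribution
``omega_j * F(j)`` explains a SOZ call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

FEATURE_NAMES = ("n_clusters", "wm_ventricle", "activelet_gini", "sine_gini")


@dataclass
class ExpertFeatureVector:
    """The per-IC expert feature vector (enabled features only)."""

    values: np.ndarray
    ic_id: str = ""
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("feature vector must have at least one feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if len(self.feature_names) != self.values.size:
            raise ValueError("feature_names length mismatch")


@dataclass
class TrainingPair:
    """L2-normalized feature vector with the +/-1 class target.

    Real pairs have unit norm; SMOTE-synthesized pairs lie on chords of the
    unit sphere (norm <= 1) and are flagged ``synthetic``.
    """

    f_hat: np.ndarray
    y: int
    synthetic: bool = False

    def __post_init__(self) -> None:
        self.f_hat = np.asarray(self.f_hat, dtype=float).ravel()
        if self.y not in (-1, 1):
            raise ValueError("y must be -1 (RSN) or +1 (SOZ)")
        if not self.synthetic and abs(np.linalg.norm(self.f_hat) - 1.0) > 1e-9:
            raise ValueError("real training pairs must be unit-norm")


@dataclass
class EKIModel:
    omega: np.ndarray
    rho_threshold: float = 0.9
    feature_names: tuple[str, ...] = FEATURE_NAMES
    objective: float = np.nan
    n_pairs: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float).ravel()
        if abs(self.omega.sum() - 1.0) > 1e-9:
            raise ValueError("omega must sum to 1")


def make_pairs(
    features: list[ExpertFeatureVector], labels: list[str]
) -> list[TrainingPair]:
    """Build normalized +/-1 training pairs from RSN/SOZ features."""
    pairs = []
    for f, lab in zip(features, labels):
        if lab not in ("RSN", "SOZ"):
            raise ValueError(f"EKI trains on RSN/SOZ only, got {lab!r}")
        norm = np.linalg.norm(f.values)
        if norm == 0:
            warnings.warn(f"zero feature vector for {f.ic_id!r}; skipped")
            continue
        pairs.append(TrainingPair(f.values / norm, 1 if lab == "SOZ" else -1))
    return pairs


def balance_with_smote(
    pairs: list[TrainingPair],
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = None,
) -> list[TrainingPair]:
    """Equalize class counts by synthesizing minority samples.

    Every synthetic sample lies on the segment between a minority sample
    and one of its ``k`` nearest minority neighbors (``k`` is clipped to
    minority size - 1).  Already-balanced input is returned unchanged.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pos = [p for p in pairs if p.y == 1]
    neg = [p for p in pairs if p.y == -1]
    if len(pos) == len(neg):
        return list(pairs)
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    if len(minority) < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    k = min(k_neighbors, len(minority) - 1)
    X = np.stack([p.f_hat for p in minority])
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]
    out = list(pairs)
    need = len(majority) - len(minority)
    y_min = minority[0].y
    for _ in range(need):
        i = int(rng.integers(len(minority)))
        j = int(nn[i, int(rng.integers(k))])
        u = float(rng.random())
        x = X[i] + u * (X[j] - X[i])
        out.append(TrainingPair(x, y_min, synthetic=True))
    return out


def fit_weights(
    pairs: list[TrainingPair],
    rho_threshold: float = 0.9,
    feature_names: tuple[str, ...] | None = None,
) -> EKIModel:
    """Closed-form equality-constrained least squares for omega.

    Minimizes ``sum_i (1 - y_i omega . f_hat_i)^2`` subject to
    ``sum_j omega_j = 1``; among minimizers the minimum-norm omega is
    returned.  (The constraint-set offset ``1/d`` is orthogonal to the
    orthonormal null-space basis, so the minimum-norm reduced solution from
    lstsq *is* the minimum-norm omega.)
    """
    ys = {p.y for p in pairs}
    if not pairs or ys != {-1, 1}:
        raise ValueError("need at least one pair of each class")
    A = np.stack([p.y * p.f_hat for p in pairs])  # rows: y_i * f_hat_i
    d = A.shape[1]
    if feature_names is None:
        feature_names = (
            FEATURE_NAMES if d == len(FEATURE_NAMES) else tuple(f"f{j}" for j in range(d))
        )
    omega_p = np.full(d, 1.0 / d)
    if d == 1:
        omega = omega_p  # the constraint forces omega = [1]
        resid = 1.0 - A @ omega
        return EKIModel(
            omega, rho_threshold, feature_names, float(resid @ resid), len(pairs)
        )
    N = null_space(np.ones((1, d)))  # orthonormal (d, d-1)
    B = A @ N
    target = 1.0 - A @ omega_p
    # min-norm least squares via SVD; the cutoff is scaled to the *data*
    # matrix so directions of B that are pure rounding noise (exactly
    # collinear features) are treated as null, not inverted
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    tol = max(B.shape) * np.finfo(float).eps * max(1.0, float(np.linalg.norm(A, 2)))
    rank = int(np.sum(s > tol))
    if rank < min(B.shape):
        warnings.warn("degenerate feature geometry; minimum-norm solution returned")
    s_inv = np.where(s > tol, 1.0 / np.where(s > tol, s, 1.0), 0.0)
    z = Vt.T @ (s_inv * (U.T @ target))
    omega = omega_p + N @ z
    resid = 1.0 - A @ omega
    return EKIModel(
        omega,
        rho_threshold,
        feature_names,
        objective=float(resid @ resid),
        n_pairs=len(pairs),
        diagnostics={
            "rank": int(rank),
            "n_synthetic": int(sum(p.synthetic for p in pairs)),
        },
    )


def save_eki(model: EKIModel, path) -> None:
    """Persist omega, threshold, enabled features and fit diagnostics."""
    import json
    from pathlib import Path

    Path(path).write_text(
        json.dumps(
            {
                "omega": model.omega.tolist(),
                "rho_threshold": model.rho_threshold,
                "feature_names": list(model.feature_names),
                "objective": model.objective,
                "n_pairs": model.n_pairs,
                "diagnostics": model.diagnostics,
            },
            indent=2,
        )
    )


def load_eki(path) -> EKIModel:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    return EKIModel(
        omega=np.array(d["omega"]),
        rho_threshold=d["rho_threshold"],
        feature_names=tuple(d["feature_names"]),
        objective=d["objective"],
        n_pairs=d["n_pairs"],
        diagnostics=d.get("diagnostics", {}),
    )


def confidence_score(model: EKIModel, f: ExpertFeatureVector | np.ndarray) -> float:
    """rho = omega . F / ||F|| (L2-normalized, scale-invariant in F);
    zero feature vectors score 0 by convention."""
    values = f.values if isinstance(f, ExpertFeatureVector) else np.asarray(f, float)
    norm = np.linalg.norm(values)
    if norm == 0:
        warnings.warn("zero feature vector; rho defined as 0")
        return 0.0
    return float(model.omega @ (values / norm))


def classify_eki(
    model: EKIModel, f: ExpertFeatureVector | np.ndarray
) -> tuple[str, float, str]:
    """(label, rho, explanation): SOZ iff rho > 0; the explanation is the
    enabled feature with the largest contribution ``omega_j * F(j)``."""
    values = f.values if isinstance(f, ExpertFeatureVector) else np.asarray(f, float)
    rho = confidence_score(model, values)
    contrib = model.omega * values
    explanation = model.feature_names[int(np.argmax(contrib))]
    return ("SOZ" if rho > 0 else "RSN"), rho, explanation
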