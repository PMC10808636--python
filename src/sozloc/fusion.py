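"""Fusion of the DL and EKI arms, and largest-cluster SOZ localization.

The final 3-class label follows the fixed fusion table: when the CNN calls
an IC non-noise, the EKI label (RSN or SOZ) stands; when the CNN calls it
NOISE, only a high-confidence EKI SOZ call (strictly rho > 0.9) overrides,
otherwise NOISE stands.  For each final-SOZ IC, the SOZ is localized as its
largest retained activation cluster across all slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spatial import ActivationCluster

RHO_THRESHOLD = 0.9


@dataclass
class FusedLabel:
    ic_id: str
    dl_label: str  # NOISE / NON_NOISE
    eki_label: str  # RSN / SOZ
    rho: float
    final: str = field(init=False)
    explanation: str | None = None

    def __post_init__(self) -> None:
        self.final = fuse(self.dl_label, self.eki_label, self.rho)
        if self.final != "SOZ":
            self.explanation = None


@dataclass
class SOZLocalization:
    ic_id: str
    clusters: list[ActivationCluster]
    largest: ActivationCluster | None
    unlocalizable_reason: str | None = None

    @property
    def tile_index(self) -> int | None:
        return None if self.largest is None else self.largest.tile_index

    @property
    def centroid(self) -> tuple[float, float] | None:
        return None if self.largest is None else self.largest.centroid


def fuse(
    dl_label: str,
    eki_label: str,
    rho: float,
    threshold: float = RHO_THRESHOLD,
) -> str:
    """The exact fusion table.

    ========== ========== =========== ======
    DL         EKI        rho         final
    ========== ========== =========== ======
    NON_NOISE  SOZ        any         SOZ
    NON_NOISE  RSN        any         RSN
    NOISE      SOZ        > threshold SOZ
    NOISE      SOZ        <= threshold NOISE
    NOISE      RSN        any         NOISE
    ========== ========== =========== ======
    """
    if dl_label not in ("NOISE", "NON_NOISE"):
        raise ValueError(f"invalid DL label {dl_label!r}")
    if eki_label not in ("RSN", "SOZ"):
        raise ValueError(f"invalid EKI label {eki_label!r}")
    if dl_label == "NON_NOISE":
        return eki_label
    if eki_label == "SOZ" and rho > threshold:
        return "SOZ"
    return "NOISE"


def localize_soz(
    soz_ics: list[tuple[str, list[ActivationCluster]]],
) -> list[SOZLocalization]:
    """One localization per SOZ IC: the argmax-size cluster over all
    slices.  Ties break to the lowest tile index, then the lowest centroid
    row.  ICs without any retained cluster are flagged unlocalizable rather
    than dropped."""
    out = []
    for ic_id, clusters in soz_ics:
        if not clusters:
            out.append(
                SOZLocalization(ic_id, [], None, unlocalizable_reason="no_retained_clusters")
            )
            continue
        largest = max(
            clusters,
            key=lambda c: (c.size_px, -c.tile_index, -c.centroid[0]),
        )
        out.append(SOZLocalization(ic_id, list(clusters), largest))
    return out
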