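"""Overlap- and boundary-based segmentation accuracy metrics.

Overlap metrics: Dice similarity coefficient (DSC) and intersection-over-union
(IOU), linked by the identity ``IOU = DSC / (2 - DSC)``.  Boundary metrics:
the 95th-percentile Hausdorff distance (HD95, mm) and the normalised surface
Dice (NSD) at a tolerance ``tau`` in mm.

Conventions (configurable where noted):

* A mask's *surface* is the set of foreground voxels with at least one
  face-adjacent (6-connectivity) non-foreground voxel; distances are Euclidean
  between surface-voxel centres, scaled by the voxel spacing.
* HD95 pools the directed surface distances in both directions and takes the
  95th percentile with linear interpolation (``directed='pooled'``; the
  max-of-directed-percentiles variant is available via ``directed='max'``).
* Both masks empty: DSC/IOU/NSD = 1.0 and HD95 = 0.0, flagged as
  degenerate.  Exactly one empty: DSC/IOU = 0.0, HD95/NSD undefined (NaN,
  flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import LABEL_SCHEME, LabelVolume

#: default NSD tolerance in mm
DEFAULT_NSD_TOL_MM = 2.0

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _check_grids(pred: np.ndarray, ref: np.ndarray) -> None:
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")


def dsc(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)`` of two binary masks.

    Both masks empty returns 1.0 (perfect agreement on absence).
    """
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    _check_grids(pred, ref)
    denom = pred.sum() + ref.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(pred, ref).sum() / denom


def iou(pred: np.ndarray, ref: np.ndarray) -> float:
    """Intersection over union ``|A∩B| / |A∪B|``; both-empty returns 1.0."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    _check_grids(pred, ref)
    union = np.logical_or(pred, ref).sum()
    if union == 0:
        return 1.0
    return np.logical_and(pred, ref).sum() / union


def surface_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with a face-adjacent (6-connectivity) background voxel.

    Voxels on the array border count as surface (the outside is background).
    """
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~interior


def _surface_distances(
    from_mask: np.ndarray, to_mask: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Distances (mm) from each surface voxel of *from_mask* to the nearest
    surface voxel of *to_mask*; exact Euclidean via distance transform."""
    from_surf = surface_mask(from_mask)
    to_surf = surface_mask(to_mask)
    # EDT of the complement of the target surface = distance to nearest
    # target-surface voxel centre
    dist = ndimage.distance_transform_edt(~to_surf, sampling=spacing)
    return dist[from_surf]


def hd95(
    pred: np.ndarray,
    ref: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    directed: str = "pooled",
) -> float:
    """95th-percentile Hausdorff distance in mm between two mask boundaries.

    Robust variant of the Hausdorff distance: trimming to the 95th percentile
    mitigates the impact of boundary outliers.  Returns NaN when either mask
    is empty (undefined, never a number pretending otherwise).
    """
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    _check_grids(pred, ref)
    if not pred.any() or not ref.any():
        return float("nan")
    d_pr = _surface_distances(pred, ref, spacing)
    d_rp = _surface_distances(ref, pred, spacing)
    if directed == "pooled":
        return float(np.percentile(np.concatenate([d_pr, d_rp]), 95))
    if directed == "max":
        return float(max(np.percentile(d_pr, 95), np.percentile(d_rp, 95)))
    raise ValueError(f"unknown directed mode {directed!r}")


def nsd(
    pred: np.ndarray,
    ref: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tau: float = DEFAULT_NSD_TOL_MM,
) -> float:
    """Normalised surface Dice at tolerance *tau* mm.

    Fraction of the combined boundaries lying within *tau* of the other
    mask's boundary:
    ``(|S_pred within tau of S_ref| + |S_ref within tau of S_pred|) /
    (|S_pred| + |S_ref|)``.
    """
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    _check_grids(pred, ref)
    if not pred.any() and not ref.any():
        return 1.0
    if not pred.any() or not ref.any():
        return float("nan")
    d_pr = _surface_distances(pred, ref, spacing)
    d_rp = _surface_distances(ref, pred, spacing)
    hits = (d_pr <= tau).sum() + (d_rp <= tau).sum()
    return float(hits / (d_pr.size + d_rp.size))


@dataclass
class MetricResult:
    """Class-wise accuracy metrics for one (prediction, reference) pair.

    Per-class dictionaries are keyed by label index 0-5.  ``flags`` marks
    classes whose metrics are degenerate (both masks empty -> conventional
    values) or undefined (one mask empty -> NaN boundary metrics).
    """

    dsc: dict[int, float]
    iou: dict[int, float]
    nsd: dict[int, float]
    hd95: dict[int, float]
    tau_mm: float
    weighted_dsc: float
    flags: dict[int, str] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for lab, name in LABEL_SCHEME.items():
            rows.append(
                {
                    "label": lab,
                    "tissue": name,
                    "dsc": self.dsc[lab],
                    "iou": self.iou[lab],
                    "nsd": self.nsd[lab],
                    "hd95_mm": self.hd95[lab],
                    "flag": self.flags.get(lab, ""),
                }
            )
        rows.append(
            {
                "label": -1,
                "tissue": "weighted_mean",
                "dsc": self.weighted_dsc,
                "iou": float("nan"),
                "nsd": float("nan"),
                "hd95_mm": float("nan"),
                "flag": f"tau={self.tau_mm}mm",
            }
        )
        return pd.DataFrame(rows)


def weighted_mean_dsc(per_class_dsc: dict[int, float], ref: LabelVolume) -> float:
    """DSC averaged over foreground classes 1-5, weighted by reference size.

    ``w_c`` is the reference voxel count of class ``c`` divided by the total
    count over classes 1-5; background (0) is excluded from the weights.
    """
    counts = np.bincount(ref.grid.ravel(), minlength=len(LABEL_SCHEME))
    fg = counts[1:].astype(float)
    total = fg.sum()
    if total == 0:
        raise ValueError("reference is all background: weighted mean undefined")
    return float(sum(fg[c - 1] / total * per_class_dsc[c] for c in range(1, 6)))


def classwise_metrics(
    pred: LabelVolume, ref: LabelVolume, tau: float = DEFAULT_NSD_TOL_MM
) -> MetricResult:
    """One-vs-rest DSC/IOU/NSD/HD95 for each class 0-5 plus the weighted mean.

    Aggregation across test subjects is an unweighted mean of per-subject
    results (see :func:`aggregate_metrics`).
    """
    if not pred.same_grid(ref):
        raise ValueError("prediction and reference must share grid and spacing")
    spacing = ref.spacing
    out_dsc: dict[int, float] = {}
    out_iou: dict[int, float] = {}
    out_nsd: dict[int, float] = {}
    out_hd: dict[int, float] = {}
    flags: dict[int, str] = {}
    for lab in LABEL_SCHEME:
        p = pred.class_mask(lab)
        r = ref.class_mask(lab)
        out_dsc[lab] = dsc(p, r)
        out_iou[lab] = iou(p, r)
        out_nsd[lab] = nsd(p, r, spacing, tau)
        out_hd[lab] = hd95(p, r, spacing)
        if not p.any() and not r.any():
            flags[lab] = "both-empty"
        elif not p.any() or not r.any():
            flags[lab] = "one-empty"
    return MetricResult(
        dsc=out_dsc,
        iou=out_iou,
        nsd=out_nsd,
        hd95=out_hd,
        tau_mm=tau,
        weighted_dsc=weighted_mean_dsc(out_dsc, ref),
        flags=flags,
    )


def aggregate_metrics(results: list[MetricResult]) -> MetricResult:
    """Unweighted mean of per-subject metric results (NaN-aware for HD/NSD)."""
    if not results:
        raise ValueError("no results to aggregate")

    def mean_over(key: str, lab: int) -> float:
        vals = np.array([getattr(r, key)[lab] for r in results], dtype=float)
        if np.isnan(vals).all():
            return float("nan")
        return float(np.nanmean(vals))

    labs = list(LABEL_SCHEME)
    return MetricResult(
        dsc={c: mean_over("dsc", c) for c in labs},
        iou={c: mean_over("iou", c) for c in labs},
        nsd={c: mean_over("nsd", c) for c in labs},
        hd95={c: mean_over("hd95", c) for c in labs},
        tau_mm=results[0].tau_mm,
        weighted_dsc=float(np.mean([r.weighted_dsc for r in results])),
    )
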