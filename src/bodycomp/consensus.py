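"""STAPLE expectation-maximisation consensus over multiple raters.

STAPLE (simultaneous truth and performance level estimation) treats the
hidden true segmentation as a latent variable and each rater's mask as a
noisy observation governed by that rater's sensitivity ``p_j`` and
specificity ``q_j``.  EM alternates:

* E-step: per-voxel posterior foreground weight
  ``W_i = a_i / (a_i + b_i)`` with
  ``a_i = pi * prod_j p_j^D_ij (1-p_j)^(1-D_ij)`` and
  ``b_i = (1-pi) * prod_j (1-q_j)^D_ij q_j^(1-D_ij)``;
* M-step: ``p_j = sum_i W_i D_ij / sum_i W_i`` and
  ``q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i)``,

until ``max |dW| < tol``.  The observed-data log-likelihood
``sum_i log(a_i + b_i)`` is tracked and must be non-decreasing.

The six-class problem is handled one-vs-rest: a binary STAPLE per foreground
class (1-5), then per-voxel argmax of the class weights, with background
where every weight is below 0.5 and ties broken to the lowest class index.
This per-class dialect matches how class-wise accuracy is evaluated; it is
not the full multi-label confusion-matrix formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import LabelVolume
from .metrics import classwise_metrics

_EPS = 1e-10
_INIT_PQ = 0.99999

FOREGROUND_CLASSES = (1, 2, 3, 4, 5)


@dataclass
class RaterPerformance:
    """Estimated per-rater operating characteristics from one binary STAPLE."""

    sensitivity: np.ndarray  # p_j, shape (J,)
    specificity: np.ndarray  # q_j, shape (J,)
    iterations: int
    converged: bool
    log_likelihood: list[float] = field(default_factory=list)


@dataclass
class RaterStack:
    """Aligned label volumes of the same anatomy from J raters/models."""

    volumes: list[LabelVolume]
    rater_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("empty rater stack")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if not ref.same_grid(v):
                raise ValueError("rater volumes are not aligned on a common grid")
        if self.rater_ids is None:
            self.rater_ids = [f"R{j + 1}" for j in range(len(self.volumes))]
        if len(self.rater_ids) != len(self.volumes):
            raise ValueError("rater_ids length mismatch")

    def __len__(self) -> int:
        return len(self.volumes)


def e_step(Df: np.ndarray, p: np.ndarray, q: np.ndarray, pi: float) -> tuple[np.ndarray, float]:
    """One STAPLE E-step: posterior foreground weights and the log-likelihood.

    *Df* is the (J, V) 0/1 decision matrix; returns ``(W, sum log(a+b))``.
    """
    pc = np.clip(p, _EPS, 1 - _EPS)
    qc = np.clip(q, _EPS, 1 - _EPS)
    log_a = np.log(pi) + np.log(pc) @ Df + np.log1p(-pc) @ (1.0 - Df)
    log_b = np.log1p(-pi) + np.log1p(-qc) @ Df + np.log(qc) @ (1.0 - Df)
    W = 1.0 / (1.0 + np.exp(np.clip(log_b - log_a, -700, 700)))
    return W, float(np.logaddexp(log_a, log_b).sum())


def staple_binary(
    decisions: list[np.ndarray] | np.ndarray,
    prior: float | None = None,
    tol: float = 1e-6,
    max_iters: int = 100,
) -> tuple[np.ndarray, RaterPerformance]:
    """Binary STAPLE EM over J aligned masks.

    Parameters
    ----------
    decisions
        J binary masks on a common grid.
    prior
        Foreground prior ``pi`` in (0, 1); defaults to the empirical
        foreground fraction of the rater average.
    tol, max_iters
        EM stops when ``max |dW| < tol`` or after *max_iters* iterations.

    Returns
    -------
    weights
        Per-voxel posterior foreground probability, same shape as the masks.
    performance
        Estimated sensitivities/specificities and convergence info.
    """
    D = np.stack([np.asarray(d, dtype=bool) for d in decisions])
    J = D.shape[0]
    shape = D.shape[1:]
    Df = D.reshape(J, -1).astype(np.float64)

    frac = Df.mean()
    if frac in (0.0, 1.0):
        warnings.warn(
            "degenerate stack (all-background or all-foreground); "
            "falling back to majority vote",
            stacklevel=2,
        )
        W = (Df.mean(axis=0) >= 0.5).astype(np.float64)
        perf = RaterPerformance(
            sensitivity=np.full(J, np.nan),
            specificity=np.full(J, np.nan),
            iterations=0,
            converged=True,
        )
        return W.reshape(shape), perf

    pi = float(frac) if prior is None else float(prior)
    if not 0.0 < pi < 1.0:
        raise ValueError("prior must lie in (0, 1)")

    p = np.full(J, _INIT_PQ)
    q = np.full(J, _INIT_PQ)
    W = np.full(Df.shape[1], pi)
    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        W_new, ll = e_step(Df, p, q, pi)
        if ll_trace and ll < ll_trace[-1] - 1e-8 * abs(ll_trace[-1]):
            warnings.warn("EM log-likelihood decreased; numerical trouble", stacklevel=2)
        ll_trace.append(ll)
        delta = float(np.max(np.abs(W_new - W)))
        W = W_new
        sw = W.sum()
        swc = (1.0 - W).sum()
        p = (Df @ W) / sw if sw > 0 else p
        q = ((1.0 - Df) @ (1.0 - W)) / swc if swc > 0 else q
        if delta < tol:
            converged = True
            break

    perf = RaterPerformance(
        sensitivity=p, specificity=q, iterations=it, converged=converged, log_likelihood=ll_trace
    )
    return W.reshape(shape), perf


def staple_multiclass(
    stack: RaterStack,
    tol: float = 1e-6,
    max_iters: int = 100,
    prior: float | None = None,
) -> tuple[LabelVolume, dict[int, RaterPerformance]]:
    """One-vs-rest STAPLE consensus over the six-class scheme.

    Runs a binary STAPLE for each foreground class 1-5; a voxel gets the
    argmax class weight, background when all weights are below 0.5, and ties
    resolve to the lowest class index.
    """
    ref = stack.volumes[0]
    weights = np.zeros((len(FOREGROUND_CLASSES),) + ref.shape)
    perf: dict[int, RaterPerformance] = {}
    for k, lab in enumerate(FOREGROUND_CLASSES):
        masks = [v.class_mask(lab) for v in stack.volumes]
        if not any(m.any() for m in masks):
            weights[k] = 0.0
            continue
        weights[k], perf[lab] = staple_binary(masks, prior=prior, tol=tol, max_iters=max_iters)
    best = np.argmax(weights, axis=0)  # ties -> first (lowest class index)
    labels = np.asarray(FOREGROUND_CLASSES)[best]
    labels = np.where(np.max(weights, axis=0) >= 0.5, labels, 0)
    return LabelVolume(labels.astype(np.int16), ref.spacing, ref.orientation), perf


def compile_test_stack(
    volumes: list[LabelVolume], slices_per_volume: int = 5
) -> LabelVolume:
    """Compile a reader-study test stack of equispaced slices per volume.

    From each of the input volumes (one scan per unique patient) the given
    number of equispaced axial slices is extracted; the slices are
    concatenated into a single stack, so 5 patients at 5 slices each yield a
    25-slice stack for annotation and STAPLE consensus.
    """
    if not volumes:
        raise ValueError("no volumes to compile")
    ref = volumes[0]
    chunks = []
    for vol in volumes:
        if vol.grid.shape[:2] != ref.grid.shape[:2]:
            raise ValueError("in-plane grids differ between volumes")
        nz = vol.grid.shape[2]
        if slices_per_volume > nz:
            raise ValueError("volume has fewer slices than requested")
        idx = np.linspace(0, nz - 1, slices_per_volume).round().astype(int)
        chunks.append(vol.grid[:, :, idx])
    return LabelVolume(np.concatenate(chunks, axis=2), ref.spacing, ref.orientation)


def reader_study(
    stack: RaterStack,
    model_outputs: list[LabelVolume] | None = None,
    model_ids: list[str] | None = None,
    tau: float = 2.0,
) -> pd.DataFrame:
    """Score raters (and optionally models) against the STAPLE consensus.

    The consensus is estimated from the rater stack alone; every rater and
    model segmentation is then evaluated against it with class-wise DSC and
    the reference-weighted mean, and the table is sorted by weighted mean
    (descending) with a 1-based rank.
    """
    consensus, _ = staple_multiclass(stack)
    entries: list[tuple[str, str, LabelVolume]] = [
        ("rater", rid, vol) for rid, vol in zip(stack.rater_ids, stack.volumes)
    ]
    if model_outputs:
        if model_ids is None:
            model_ids = [f"M{j + 1}" for j in range(len(model_outputs))]
        entries += [("model", mid, vol) for mid, vol in zip(model_ids, model_outputs)]

    rows = []
    for kind, ident, vol in entries:
        res = classwise_metrics(vol, consensus, tau=tau)
        row = {"id": ident, "kind": kind, "weighted_dsc": res.weighted_dsc}
        row.update({f"dsc_{lab}": res.dsc[lab] for lab in res.dsc})
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("weighted_dsc", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
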