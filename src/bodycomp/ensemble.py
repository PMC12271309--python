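"""Ensemble combination of model outputs and connected-component cleanup.

Two combination rules: probability *averaging* (argmax of the channel-wise
mean probability) and hard-label *voting* (per-voxel mode).  Ties resolve to
the lowest class index in both, for determinism.

:func:`enumerate_ensembles` reproduces the standard ensemble ladder built
from four base segmentation models: the 4 singletons, 6 pairs, 4 triples and
the full quadruple — 15 configurations in deterministic lexicographic order.

:func:`largest_component` keeps only the largest 26-connected component of
the foreground union (classes 1-5), removing stray regions (e.g. arms)
segmented outside the abdominal region of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage

from .core_io import LabelVolume, ProbabilityVolume


@dataclass(frozen=True)
class EnsembleSpec:
    """One ensemble configuration: member ids and combination method."""

    members: tuple[str, ...]
    method: str = "averaging"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.method not in ("averaging", "voting"):
            raise ValueError(f"unknown ensemble method {self.method!r}")

    @property
    def name(self) -> str:
        return "+".join(self.members)


def _check_aligned(vols) -> None:
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape or not np.allclose(v.spacing, ref.spacing):
            raise ValueError("ensemble members are not aligned on a common grid")


def ensemble_average(members: list[ProbabilityVolume]) -> LabelVolume:
    """Argmax of the channel-wise mean probability; ties -> lowest class."""
    if not members:
        raise ValueError("empty ensemble")
    _check_aligned(members)
    mean = np.mean([m.channels for m in members], axis=0)
    labels = np.argmax(mean, axis=0).astype(np.int16)
    return LabelVolume(labels, members[0].spacing, members[0].orientation)


def ensemble_vote(members: list[LabelVolume]) -> LabelVolume:
    """Per-voxel modal label over members; ties -> lowest class index."""
    if not members:
        raise ValueError("empty ensemble")
    _check_aligned(members)
    stacked = np.stack([m.grid for m in members])
    counts = np.stack([(stacked == lab).sum(axis=0) for lab in range(6)])
    labels = np.argmax(counts, axis=0).astype(np.int16)  # argmax: lowest index on ties
    return LabelVolume(labels, members[0].spacing, members[0].orientation)


def enumerate_ensembles(base: tuple[str, str, str, str] | list[str]) -> list[EnsembleSpec]:
    """All 15 averaging combinations of exactly four base members.

    Singletons first, then pairs, triples and the full ensemble, each block
    in lexicographic member order.
    """
    base = tuple(base)
    if len(base) != 4:
        raise ValueError(f"expected exactly 4 base members, got {len(base)}")
    specs: list[EnsembleSpec] = []
    for size in (1, 2, 3, 4):
        for combo in combinations(base, size):
            specs.append(EnsembleSpec(members=combo, method="averaging"))
    return specs


def largest_component(vol: LabelVolume) -> LabelVolume:
    """Keep only the largest 26-connected component of the foreground union.

    Components are computed on the union of classes 1-5; voxels outside the
    largest component are set to background, labels inside are untouched.
    All-background input is returned unchanged with a warning.
    """
    fg = vol.grid > 0
    if not fg.any():
        warnings.warn("all-background volume: nothing to post-process", stacklevel=2)
        return vol
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    comp, n = ndimage.label(fg, structure=structure)
    if n <= 1:
        return vol
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    grid = np.where(comp == keep, vol.grid, 0).astype(np.int16)
    return LabelVolume(grid, vol.spacing, vol.orientation)
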