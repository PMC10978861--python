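"""Operator seed labels (Phase 2b) and their synthetic emulation.

In the interactive workflow a trained operator paints a handful of axial
slices: femur voxels as foreground, surrounding tissue/pelvis as
background.  Seeds are exchanged as ordinary 8-bit label images on the CT
grid (0 unlabelled, 1 foreground, 2 background) so any viewer can produce
them; the labelling may be generous and imprecise — it only initializes the
per-voxel terms of the graph-cut.

:func:`synth_seeds` emulates that operator for testing: it paints all
voxels well inside the ground-truth mask on a few axial slices as
foreground, and voxels safely outside it (on the same slices) as
background.
"""

from __future__ import annotations

import logging
import os
import warnings

import numpy as np
from scipy import ndimage

from .volume import (
    SEED_BACKGROUND,
    SEED_FOREGROUND,
    SEED_UNLABELLED,
    BinaryMask,
    ImageVolume,
    SeedVolume,
    read_volume,
)

__all__ = ["load_seeds", "synth_seeds"]

log = logging.getLogger(__name__)


def load_seeds(path: str | os.PathLike, reference: ImageVolume) -> SeedVolume:
    """Load a seed label image and validate it against the reference grid.

    Warns (but proceeds) when one of the two seed classes is absent: the
    segmentation then rests entirely on the unlabelled prior.
    """
    vol = read_volume(path)
    reference.require_same_grid(vol, "seed image")
    seeds = SeedVolume(data=vol.data, spacing=vol.spacing, origin=vol.origin)
    n_fg = int(seeds.foreground.sum())
    n_bg = int(seeds.background.sum())
    log.info("seeds from %s: %d foreground, %d background, %d unlabelled",
             path, n_fg, n_bg, seeds.data.size - n_fg - n_bg)
    if n_fg == 0 or n_bg == 0:
        warnings.warn(
            f"seed image {path} has {n_fg} foreground and {n_bg} background "
            "voxels; segmentation will rest on the unlabelled prior",
            RuntimeWarning,
            stacklevel=2,
        )
    return seeds


def synth_seeds(truth: BinaryMask,
                n_slices: int = 3,
                erosion_mm: float = 2.0,
                rng_seed: int = 0,
                dilation_mm: float | None = None,
                fraction: float = 1.0,
                within: BinaryMask | None = None) -> SeedVolume:
    """Emulate sparse operator labelling from a known truth mask.

    Foreground seeds are taken at least ``erosion_mm`` inside the truth
    surface (distance to the nearest non-truth voxel), on ``n_slices``
    evenly spread axial slices; background seeds on the same slices at
    least ``dilation_mm`` (default: ``erosion_mm``) outside the truth,
    optionally restricted to a body mask ``within``.

    ``fraction`` < 1 subsamples the eligible voxels uniformly at random
    (reproducible via ``rng_seed``); the default paints every eligible
    voxel, mimicking generous slice painting.

    Raises
    ------
    ValueError
        If the erosion leaves no eligible foreground voxel on any slice.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if erosion_mm < 0:
        raise ValueError("erosion_mm must be >= 0")
    if not truth.data.any():
        raise ValueError("truth mask is empty")
    if dilation_mm is None:
        dilation_mm = erosion_mm
    spacing = truth.spacing

    # Distance (mm) to nearest voxel outside/inside the truth.
    d_inside = ndimage.distance_transform_edt(truth.data, sampling=spacing)
    d_outside = ndimage.distance_transform_edt(~truth.data, sampling=spacing)
    fg_eligible = truth.data & (d_inside >= erosion_mm)
    bg_eligible = (~truth.data) & (d_outside >= dilation_mm)
    if within is not None:
        truth.require_same_grid(within, "seed body restriction")
        bg_eligible &= within.data

    fg_slices = np.flatnonzero(fg_eligible.any(axis=(1, 2)))
    if fg_slices.size == 0:
        raise ValueError(
            f"erosion of {erosion_mm} mm annihilates the truth on every "
            "axial slice; use a smaller erosion"
        )
    n_pick = min(n_slices, fg_slices.size)
    picked = fg_slices[np.linspace(0, fg_slices.size - 1, n_pick).round().astype(int)]

    labels = np.full(truth.shape, SEED_UNLABELLED, dtype=np.uint8)
    rng = np.random.default_rng(rng_seed)
    for z in picked:
        fg = fg_eligible[z]
        bg = bg_eligible[z]
        if fraction < 1.0:
            fg = fg & (rng.random(fg.shape) < fraction)
            bg = bg & (rng.random(bg.shape) < fraction)
        labels[z][fg] = SEED_FOREGROUND
        labels[z][bg] = SEED_BACKGROUND
    return SeedVolume.like(truth, labels)
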