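"""Gray-matter and network masks, and per-network wDC summaries.

The analysis restricts wDC maps to a two-part network mask — a frontoparietal
submask (hyperconnected in autism in prior large-scale work) and a
sensorimotor submask (hypoconnected).  Each submask is resampled to the BOLD
grid, binarized, and intersected with a common gray-matter mask built by
intersecting all participant-specific gray-matter probability maps at a
probability threshold (default 0.85, strict >).  The standardized wDC values
inside each prepared submask are averaged into one outcome per participant,
condition, and network, and collected into the long table the mixed models
consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import WdcMap
from .errors import (
    ContainmentError,
    DegenerateInputError,
    EmptyNetworkError,
    GridMismatchError,
    ManifestError,
)
from .image_io import MaskVolume, VoxelGrid, resample_mask

log = logging.getLogger(__name__)

GM_PROB_THRESHOLD = 0.85
NETWORKS = ("frontoparietal", "sensorimotor")

#: voxel counts of the original submasks on their native grid; recorded as
#: reference metadata only, never enforced on user-supplied masks
REFERENCE_VOXEL_COUNTS = {"frontoparietal": 4446, "sensorimotor": 2803}


@dataclass
class NetworkMaskPair:
    """The frontoparietal + sensorimotor submask pair (disjoint)."""

    frontoparietal: MaskVolume
    sensorimotor: MaskVolume

    def __post_init__(self) -> None:
        if not self.frontoparietal.grid.compatible_with(self.sensorimotor.grid):
            raise GridMismatchError("network submasks must share one grid")
        if np.any(self.frontoparietal.membership & self.sensorimotor.membership):
            raise DegenerateInputError("network submasks must be disjoint")

    def __iter__(self):
        yield "frontoparietal", self.frontoparietal
        yield "sensorimotor", self.sensorimotor


def build_common_gm_mask(
    gm_prob_maps: Sequence[tuple[VoxelGrid, np.ndarray]],
    prob_threshold: float = GM_PROB_THRESHOLD,
) -> MaskVolume:
    """Intersect participant gray-matter probability maps into a common mask.

    A voxel is in the output iff its gray-matter probability exceeds
    ``prob_threshold`` in every participant map.  An empty intersection is
    returned with a warning; the caller decides whether that is fatal.
    """
    if len(gm_prob_maps) == 0:
        raise DegenerateInputError("need at least one gray-matter probability map")
    grid0 = gm_prob_maps[0][0]
    common = np.ones(grid0.shape, dtype=bool)
    for grid, probs in gm_prob_maps:
        if not grid.compatible_with(grid0):
            raise GridMismatchError("gray-matter maps are on incompatible grids")
        probs = np.asarray(probs, dtype=float)
        if probs.shape != grid0.shape:
            raise GridMismatchError("probability map shape does not match its grid")
        if probs.min() < 0 or probs.max() > 1:
            raise DegenerateInputError("gray-matter probabilities must lie in [0, 1]")
        common &= probs > prob_threshold
    if not common.any():
        log.warning("common gray-matter mask is empty at threshold %g", prob_threshold)
    return MaskVolume(grid0, common, label="common_gm")


def prepare_network_masks(
    pair: NetworkMaskPair,
    target: VoxelGrid,
    common_gm: MaskVolume,
    interpolation: str = "nearest",
) -> NetworkMaskPair:
    """Resample both submasks to the BOLD grid, binarize, intersect with GM.

    Raises :class:`EmptyNetworkError` if either submask ends up empty.
    """
    if not common_gm.grid.compatible_with(target):
        raise GridMismatchError("common GM mask must live on the target grid")
    prepared = {}
    for name, sub in pair:
        res = resample_mask(sub, target, interpolation=interpolation)
        res = res.intersect(common_gm, label=name)
        if res.n_voxels == 0:
            raise EmptyNetworkError(
                f"{name} submask is empty after resampling/GM intersection"
            )
        prepared[name] = res
    return NetworkMaskPair(**prepared)


def mean_wdc_in_mask(wdc_map: WdcMap, submask: MaskVolume) -> float:
    """Mean standardized wDC over the voxels of a submask."""
    if submask.n_voxels == 0:
        raise DegenerateInputError("submask is empty")
    if not submask.grid.compatible_with(wdc_map.mask.grid):
        raise GridMismatchError("submask and wDC map are on incompatible grids")
    if not submask.is_subset_of(wdc_map.mask):
        raise ContainmentError("submask has voxels outside the wDC map's mask")
    # positions of submask voxels within the map's linear value order
    map_idx = wdc_map.mask.linear_indices()
    sub_idx = submask.linear_indices()
    positions = np.searchsorted(map_idx, sub_idx)
    return float(wdc_map.values[positions].mean())


def assemble_long_table(
    maps: Mapping[tuple[str, str], WdcMap],
    masks: NetworkMaskPair,
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Collect per-network mean wDC outcomes into the analysis long table.

    ``maps`` is keyed by (participant_id, condition) and must contain one
    standardized map per QC-passing manifest row; participants missing a
    condition simply contribute fewer rows (the design may be unbalanced).

    Returns a DataFrame with columns participant_id, group, drug, network,
    mfd, mean_wdc.
    """
    rows = []
    seen = set()
    for rec in manifest.itertuples(index=False):
        key = (str(rec.participant_id), rec.condition)
        if key not in maps:
            raise ManifestError(f"no wDC map for session {key}")
        wdc_map = maps[key]
        if not wdc_map.standardized:
            raise DegenerateInputError(f"map for session {key} is not standardized")
        for network, submask in masks:
            row_key = (key[0], rec.condition, network)
            if row_key in seen:
                raise ManifestError(f"duplicate participant x condition x network {row_key}")
            seen.add(row_key)
            rows.append(
                {
                    "participant_id": key[0],
                    "group": rec.group,
                    "drug": rec.condition,
                    "network": network,
                    "mfd": float(rec.mfd),
                    "mean_wdc": mean_wdc_in_mask(wdc_map, submask),
                }
            )
    return pd.DataFrame(rows)


def write_long_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_long_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"participant_id": str})
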