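"""Evaluation of pipeline output against synthetic ground truth."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .detect import TelomereMeasurement
from .simulate import SceneTruth
from .stacks import VoxelSize

__all__ = ["match_to_truth", "coverage_fraction"]


def match_to_truth(
    measurements: Sequence[TelomereMeasurement],
    truth: SceneTruth,
    voxel_size: VoxelSize | None = None,
    max_voxels: float = 1.0,
    accepted_only: bool = True,
) -> list[tuple[int, int]]:
    """Uniquely match measurements to truth spots within a voxel tolerance.

    A measurement matches a truth spot when the per-axis distance between
    its centre of mass and the truth position is at most ``max_voxels``
    voxels (axis-wise, so 80 nm lateral and 200 nm axial at defaults).
    Matching is greedy by increasing distance and one-to-one.

    Returns a list of ``(measurement_index, truth_spot_index)`` pairs.
    """
    vs = voxel_size or VoxelSize()
    spacing = np.asarray(vs.zyx_nm)
    meas_idx = [
        i for i, m in enumerate(measurements) if (m.accepted or not accepted_only)
    ]
    if not meas_idx or not truth.spots:
        return []
    meas_pos = np.array([measurements[i].spot.center_of_mass_nm for i in meas_idx]) / spacing
    true_pos = truth.positions_zyx_nm() / spacing

    diff = meas_pos[:, None, :] - true_pos[None, :, :]
    cheb = np.max(np.abs(diff), axis=-1)
    eucl = np.linalg.norm(diff, axis=-1)
    pairs = np.argwhere(cheb <= max_voxels)
    order = np.argsort(eucl[pairs[:, 0], pairs[:, 1]])
    used_m: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int]] = []
    for mi, ti in pairs[order]:
        if mi in used_m or ti in used_t:
            continue
        used_m.add(int(mi))
        used_t.add(int(ti))
        matches.append((meas_idx[int(mi)], int(ti)))
    return matches


def coverage_fraction(
    measurements: Sequence[TelomereMeasurement],
    truth: SceneTruth,
    voxel_size: VoxelSize | None = None,
) -> float:
    """Fraction of ground-truth telomeres recovered by accepted, matched measurements."""
    if not truth.spots:
        raise ValueError("truth scene has no spots")
    matches = match_to_truth(measurements, truth, voxel_size=voxel_size)
    return len(matches) / len(truth.spots)
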