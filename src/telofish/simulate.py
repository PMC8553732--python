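"""Ground-truthed synthetic confocal scenes for telomere Q-FISH.

Each scene is one nucleus: an ellipsoidal DAPI volume plus a telomere
channel containing point-like spots convolved with an anisotropic
Gaussian approximation of the confocal PSF. The statistical structure
mirrors what the measurement pipeline assumes about real acquisitions:

* spot amplitudes are lognormally distributed (photon counts);
* spots keep a minimum pairwise separation of 200 nm, the resolvability
  bound established by STED imaging of FISH-labelled telomeres;
* photon noise is Poisson;
* background is a constant offset.

The default amplitude distribution is calibrated so its analytic mean
equals 126.3 counts, the wild-type per-nucleus mean brightness the
pipeline is meant to reproduce; the log-scale spread (sigma = 0.5) is an
assumption documented in the methods note. Default spot count is 92
(two telomeres for each of 46 chromosomes) so detection coverage has a
known denominator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stacks import ImageStack, VoxelSize
from .io import write_stack

__all__ = [
    "GeneratorParams",
    "NucleusEllipsoid",
    "SpotTruth",
    "SceneTruth",
    "sample_spot_positions",
    "sample_amplitudes",
    "generate_scene",
    "render_scene",
    "generate_study",
    "default_lognormal_mu",
]

#: Wild-type mean telomere brightness (photon counts) the generator targets.
WT_MEAN_BRIGHTNESS = 126.3
DEFAULT_SIGMA_LOG = 0.5


def default_lognormal_mu(mean_counts: float = WT_MEAN_BRIGHTNESS, sigma_log: float = DEFAULT_SIGMA_LOG) -> float:
    """Natural-log location parameter giving a lognormal the requested mean."""
    if mean_counts <= 0:
        raise ValueError("mean_counts must be positive")
    return math.log(mean_counts) - 0.5 * sigma_log**2


@dataclass(frozen=True)
class NucleusEllipsoid:
    """Axis-aligned ellipsoid in physical coordinates (nm), (z, y, x) order."""

    center_nm: tuple[float, float, float]
    semi_axes_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_nm):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes_nm}")

    def contains(self, pos_zyx_nm: np.ndarray) -> np.ndarray:
        """Vectorized membership test for positions of shape (..., 3)."""
        p = np.asarray(pos_zyx_nm, dtype=float)
        rel = (p - np.asarray(self.center_nm)) / np.asarray(self.semi_axes_nm)
        return np.sum(rel**2, axis=-1) <= 1.0


@dataclass(frozen=True)
class GeneratorParams:
    n_spots_per_nucleus: int = 92
    lognormal_mu: float = field(default_factory=default_lognormal_mu)
    lognormal_sigma: float = DEFAULT_SIGMA_LOG
    min_separation_nm: float = 200.0
    psf_sigma_lateral_nm: float = 120.0
    psf_sigma_axial_nm: float = 300.0
    background_counts: float = 5.0
    dapi_counts: float = 120.0
    nucleus_semi_axes_nm: tuple[float, float, float] = (2500.0, 7000.0, 7000.0)
    shape_zyx: tuple[int, int, int] = (40, 256, 256)
    n_nuclei_per_condition: int = 6
    poisson_noise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots_per_nucleus < 0:
            raise ValueError("n_spots_per_nucleus must be >= 0")
        if self.min_separation_nm < 0:
            raise ValueError("min_separation_nm must be >= 0")
        if self.psf_sigma_lateral_nm <= 0 or self.psf_sigma_axial_nm <= 0:
            raise ValueError("PSF sigmas must be > 0")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")
        if any(a <= 0 for a in self.nucleus_semi_axes_nm):
            raise ValueError("nucleus semi-axes must be > 0")

    def scaled_brightness(self, ratio: float) -> "GeneratorParams":
        """Params with the amplitude mean multiplied by ``ratio`` (same sigma).

        Scaling a lognormal by ``ratio`` shifts mu by ``ln(ratio)``, so the
        whole brightness distribution is rescaled, mirroring uniform
        telomere shortening.
        """
        if ratio <= 0:
            raise ValueError("ratio must be positive")
        return GeneratorParams(**{**asdict(self), "lognormal_mu": self.lognormal_mu + math.log(ratio)})


@dataclass(frozen=True)
class SpotTruth:
    """Ground-truth spot: sub-voxel position (nm) and peak amplitude (counts)."""

    x_nm: float
    y_nm: float
    z_nm: float
    amplitude_counts: float

    def __post_init__(self) -> None:
        if self.amplitude_counts <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def zyx_nm(self) -> tuple[float, float, float]:
        return (self.z_nm, self.y_nm, self.x_nm)


@dataclass
class SceneTruth:
    nucleus: NucleusEllipsoid
    spots: list[SpotTruth]
    params: GeneratorParams
    seed: int

    def positions_zyx_nm(self) -> np.ndarray:
        if not self.spots:
            return np.zeros((0, 3))
        return np.array([s.zyx_nm for s in self.spots], dtype=float)

    def amplitudes(self) -> np.ndarray:
        return np.array([s.amplitude_counts for s in self.spots], dtype=float)

    def validate(self) -> None:
        pos = self.positions_zyx_nm()
        if len(pos) and not np.all(self.nucleus.contains(pos)):
            raise ValueError("truth spot outside parent nucleus ellipsoid")
        if len(pos) > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            iu = np.triu_indices(len(pos), k=1)
            if np.min(d[iu]) < self.params.min_separation_nm - 1e-9:
                raise ValueError("pairwise spot separation below minimum")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": np.arange(len(self.spots)),
                "x_nm": [s.x_nm for s in self.spots],
                "y_nm": [s.y_nm for s in self.spots],
                "z_nm": [s.z_nm for s in self.spots],
                "amplitude_counts": [s.amplitude_counts for s in self.spots],
            }
        )


# total proposal budget for the rejection sampler; generous for n <= 92
_RETRY_BUDGET = 100_000


def sample_spot_positions(
    params: GeneratorParams,
    nucleus: NucleusEllipsoid,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Uniform positions inside the nucleus with a hard minimum separation.

    Rejection sampling: propose uniformly inside the ellipsoid and accept
    a point only if it keeps ``min_separation_nm`` from every accepted
    point. Deterministic for a fixed seed. Raises if the proposal budget
    is exhausted (infeasible packing).

    Returns an array of shape ``(n_spots, 3)`` in (z, y, x) nm.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = params.n_spots_per_nucleus
    if n == 0:
        return np.zeros((0, 3))
    center = np.asarray(nucleus.center_nm)
    semi = np.asarray(nucleus.semi_axes_nm)
    accepted = np.empty((n, 3))
    k = 0
    min_sep2 = params.min_separation_nm**2
    for _ in range(_RETRY_BUDGET):
        # uniform in the unit ball, then anisotropic scaling
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        r = rng.uniform() ** (1.0 / 3.0)
        p = center + semi * (v * r)
        if k and np.min(np.sum((accepted[:k] - p) ** 2, axis=1)) < min_sep2:
            continue
        accepted[k] = p
        k += 1
        if k == n:
            return accepted
    raise RuntimeError(
        f"could not place {n} spots with >= {params.min_separation_nm} nm separation "
        f"inside the nucleus after {_RETRY_BUDGET} proposals; "
        "reduce n_spots_per_nucleus or enlarge the nucleus"
    )


def sample_amplitudes(mu: float, sigma: float, n: int, rng: np.random.Generator | int) -> np.ndarray:
    """I.i.d. lognormal amplitude draws (natural-log parameters)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def generate_scene(params: GeneratorParams, seed: int) -> SceneTruth:
    """Sample a full ground-truth scene (nucleus geometry + spots)."""
    rng = np.random.default_rng(seed)
    voxel = VoxelSize()
    shape = np.asarray(params.shape_zyx)
    extent = (shape - 1) * np.asarray(voxel.zyx_nm)
    nucleus = NucleusEllipsoid(center_nm=tuple(extent / 2.0), semi_axes_nm=params.nucleus_semi_axes_nm)
    pos = sample_spot_positions(params, nucleus, rng)
    amp = sample_amplitudes(params.lognormal_mu, params.lognormal_sigma, params.n_spots_per_nucleus, rng)
    spots = [
        SpotTruth(x_nm=p[2], y_nm=p[1], z_nm=p[0], amplitude_counts=a) for p, a in zip(pos, amp)
    ]
    truth = SceneTruth(nucleus=nucleus, spots=spots, params=params, seed=seed)
    truth.validate()
    return truth


def _paint_spot(canvas: np.ndarray, center_vox: np.ndarray, sigma_vox: np.ndarray, amplitude: float) -> None:
    """Add one peak-normalized anisotropic Gaussian, evaluated on a local window."""
    shape = canvas.shape
    lo = np.maximum(np.floor(center_vox - 4 * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + 4 * sigma_vox).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    profiles = []
    for ax in range(3):
        idx = np.arange(lo[ax], hi[ax], dtype=float)
        profiles.append(np.exp(-((idx - center_vox[ax]) ** 2) / (2.0 * sigma_vox[ax] ** 2)))
    block = amplitude * profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
    canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += block


def render_scene(
    truth: SceneTruth,
    voxel_size: VoxelSize | None = None,
    rng: np.random.Generator | int | None = None,
    quantize: bool = True,
) -> tuple[ImageStack, ImageStack]:
    """Render (dapi, telomere) stacks from a ground-truth scene.

    Telomere channel: constant background plus, for each spot, an
    anisotropic Gaussian with peak normalized to 1 at the (sub-voxel)
    spot centre scaled by the spot amplitude, evaluated at voxel centres.
    DAPI channel: a filled nucleus ellipsoid at ``dapi_counts`` over the
    same background. Poisson noise is applied per channel when enabled,
    and output is quantized to 16-bit unless ``quantize=False``.
    """
    params = truth.params
    voxel = voxel_size or VoxelSize()
    spacing = np.asarray(voxel.zyx_nm)
    shape = tuple(params.shape_zyx)
    sigma_vox = np.array(
        [
            params.psf_sigma_axial_nm / voxel.dz_nm,
            params.psf_sigma_lateral_nm / voxel.dy_nm,
            params.psf_sigma_lateral_nm / voxel.dx_nm,
        ]
    )

    telo = np.full(shape, float(params.background_counts))
    bounds = (np.asarray(shape) - 1) * spacing
    for spot in truth.spots:
        pos = np.asarray(spot.zyx_nm)
        if np.any(pos < 0) or np.any(pos > bounds):
            raise ValueError(f"spot at {tuple(pos)} nm lies outside the stack (bounds {tuple(bounds)} nm)")
        _paint_spot(telo, pos / spacing, sigma_vox, spot.amplitude_counts)

    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * spacing[0],
        np.arange(shape[1]) * spacing[1],
        np.arange(shape[2]) * spacing[2],
        indexing="ij",
    )
    grid = np.stack([zz, yy, xx], axis=-1)
    inside = truth.nucleus.contains(grid)
    dapi = np.full(shape, float(params.background_counts))
    dapi[inside] += params.dapi_counts

    if params.poisson_noise:
        if rng is None:
            rng = np.random.default_rng(truth.seed + 1)
        elif isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        telo = rng.poisson(telo).astype(float)
        dapi = rng.poisson(dapi).astype(float)

    if quantize:
        telo = np.clip(np.rint(telo), 0, 65535).astype(np.uint16)
        dapi = np.clip(np.rint(dapi), 0, 65535).astype(np.uint16)

    return (
        ImageStack(dapi, voxel, channel_name="dapi"),
        ImageStack(telo, voxel, channel_name="telomere"),
    )


def generate_study(
    conditions: Mapping[str, GeneratorParams] | Iterable[tuple[str, GeneratorParams]],
    seed: int,
    out_dir: str | Path | None = None,
) -> dict[str, list[tuple[ImageStack, ImageStack, SceneTruth]]]:
    """Generate a multi-condition study: n_nuclei scene/stack pairs per condition.

    Per-nucleus seeds are spawned deterministically from ``seed``, so the
    same seed reproduces every truth table and noiseless render bitwise.
    If ``out_dir`` is given, TIFF pairs, truth CSVs and a params JSON are
    written there.
    """
    if not isinstance(conditions, Mapping):
        pairs = list(conditions)
        names = [name for name, _ in pairs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate condition names: {sorted(names)}")
        conditions = dict(pairs)
    if not conditions:
        raise ValueError("at least one condition is required")

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    study: dict[str, list[tuple[ImageStack, ImageStack, SceneTruth]]] = {}
    for ci, (name, params) in enumerate(sorted(conditions.items())):
        scenes = []
        for ni in range(params.n_nuclei_per_condition):
            # stable per-(condition, nucleus) seed below 2**31
            child_seed = int(
                np.random.SeedSequence([seed, ci, ni]).generate_state(1, np.uint32)[0] % (2**31)
            )
            truth = generate_scene(params, child_seed)
            dapi, telo = render_scene(truth)
            scenes.append((dapi, telo, truth))
            if out is not None:
                stem = f"{name}_nucleus{ni:02d}"
                write_stack(dapi, out / f"{stem}_dapi.tif")
                write_stack(telo, out / f"{stem}_telomere.tif")
                truth.to_frame().to_csv(out / f"{stem}_truth.csv", index=False)
        study[name] = scenes
        if out is not None:
            (out / f"{name}_params.json").write_text(json.dumps(asdict(params), indent=2))
    return study
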