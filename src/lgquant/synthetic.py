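"""Ground-truthed synthetic lymph-gland confocal stacks.

The generator emulates the data the analysis pipeline was built for: a dense
field of roughly spherical DAPI-stained nuclei in a 3D confocal stack with
anisotropic voxels, membrane/cytoplasmic marker halos around a known subset
of cells, and two dextran dye channels that label all cell surfaces except
that the large (70 kDa) dye is excluded from the niche (PSC) region while
the permeability barrier is intact.

Every scene carries its full ground truth (:class:`GroundTruthScene`):
nucleus positions, radii, region labels and marker memberships, plus the
dye-exclusion ellipsoid.  Ground-truth bookkeeping — e.g. the true
differentiation index ``members / total`` — is exact by construction and is
the oracle for every downstream stage.

Rendering model
---------------
* Nuclei are isotropic Gaussian blobs with ``sigma = radius / 2`` so the
  intensity falls to ~60% of peak at one nuclear radius; this keeps the
  blob profile smooth, as difference-of-Gaussians detection assumes.
* Markers are Gaussian shells centred at the nuclear radius with thickness
  0.25x the radius, emulating surface stains (P1-like) rather than nuclear
  fills — which is why classification samples a search sphere wider than
  the nucleus.
* Dye channels label every cell surface identically; inside the exclusion
  ellipsoid the large-dye signal is multiplied by an attenuation factor
  (default 0 = complete exclusion), the small dye is unaffected.  A constant
  dye background stands in for dye in the surrounding medium.
* Noise: ``Poisson(photon_scale * signal) / photon_scale`` shot noise, plus
  additive Gaussian read noise, clipped to ``[0, saturation_level]``.
  ``photon_scale=None`` (or infinity) gives the noiseless limit.

Determinism: identical ``(params, seed)`` give bit-identical scenes, and
identical ``(scene, noise, seed)`` give bit-identical renders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._errors import PackingError, ValidationError
from .image_io import MultiChannelVolume, RoiMask

__all__ = [
    "NoiseModel", "NOISELESS", "SceneParams", "Nucleus", "GroundTruthScene",
    "sample_scene", "render_scene", "render_barrier_pair", "match_detections",
]

# Random-sequential-addition packings of equal spheres saturate near 38%
# volume fraction; beyond that, rejection sampling cannot terminate.
_RSA_SATURATION = 0.38


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise applied to a rendered scene.

    photon_scale : expected photons at unit intensity (None = noiseless);
    read_sigma : additive Gaussian sigma in intensity units;
    saturation_level : intensities clip at this value, mirroring acquisition
    that sets the out-of-tissue medium to saturation.
    """

    photon_scale: float | None = 2.0
    read_sigma: float = 2.0
    saturation_level: float = 255.0

    def __post_init__(self) -> None:
        if self.photon_scale is not None and not (self.photon_scale > 0):
            raise ValidationError("photon_scale must be positive (or None for noiseless)")
        if self.read_sigma < 0:
            raise ValidationError("read_sigma must be >= 0")

    @property
    def noiseless(self) -> bool:
        return self.photon_scale is None or math.isinf(self.photon_scale)


#: Convenience noiseless model (infinite photons, zero read noise, no clipping).
NOISELESS = NoiseModel(photon_scale=None, read_sigma=0.0, saturation_level=math.inf)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic lymph-gland scene.

    Geometry defaults follow typical confocal acquisitions of the primary
    lobe: ~300 nuclei of radius 2–3 µm in an anisotropic (1.0, 0.3, 0.3) µm
    voxel grid, with a small posterior niche (PSC) marked by an ellipsoidal
    dye-exclusion region.
    """

    shape: tuple[int, int, int] = (40, 192, 192)      # voxels (z, y, x)
    spacing: tuple[float, float, float] = (1.0, 0.3, 0.3)  # µm
    n_nuclei: int = 300
    psc_count: int = 8
    radius_range: tuple[float, float] = (2.0, 3.0)    # µm
    min_separation: float = 6.0                       # µm; 0 disables the check
    marker_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"plasmatocyte": 0.3})
    psc_marker: str | None = "Antp"
    # intensity model
    nuclear_channel: str = "dapi"
    nuclear_amplitude: float = 60.0
    background_base: float = 4.0
    background_gradient: float = 4.0   # added linearly along x across the field
    marker_amplitude: float = 80.0
    marker_background: float = 2.0
    dye_channels: tuple[str, str] = ("dye40", "dye70")  # (small, large)
    dye_amplitude: float = 60.0
    dye_background: float = 6.0
    shell_thickness_factor: float = 0.25   # shell thickness as fraction of radius
    # dye-exclusion (PSC) geometry, fractions of the physical extent / µm
    psc_center_frac: tuple[float, float, float] = (0.5, 0.5, 0.8)
    psc_semiaxes: tuple[float, float, float] = (9.0, 10.0, 10.0)
    attenuation: float = 0.0          # large-dye factor inside the PSC when intact
    max_attempts_per_nucleus: int = 200

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValidationError("shape and spacing must be positive")
        if self.n_nuclei < 0 or self.psc_count < 0 or self.psc_count > self.n_nuclei:
            raise ValidationError("need 0 <= psc_count <= n_nuclei")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValidationError(f"bad radius_range {self.radius_range}")
        for frac in self.marker_fractions.values():
            if not 0 <= frac <= 1:
                raise ValidationError("marker fractions must lie in [0, 1]")
        if not 0 <= self.attenuation <= 1:
            raise ValidationError("attenuation must lie in [0, 1]")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def psc_center_um(self) -> tuple[float, float, float]:
        return tuple(f * e for f, e in zip(self.psc_center_frac, self.extent_um))

    def marker_names(self) -> list[str]:
        names = list(self.marker_fractions)
        if self.psc_marker:
            names.append(self.psc_marker)
        return names


@dataclass(frozen=True)
class Nucleus:
    """One ground-truth nucleus."""

    id: int
    center_um: tuple[float, float, float]   # (z, y, x)
    radius_um: float
    region: str                             # PSC | MZ | CZ | circulating
    markers: frozenset[str] = frozenset()


@dataclass(frozen=True)
class GroundTruthScene:
    """A sampled scene: the oracle for every pipeline stage."""

    params: SceneParams
    nuclei: tuple[Nucleus, ...]
    seed: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.params.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.params.spacing

    def marker_count(self, marker: str) -> int:
        return sum(1 for n in self.nuclei if marker in n.markers)

    def true_index(self, marker: str) -> float:
        """Exact ground-truth differentiation index: members / total."""
        if not self.nuclei:
            raise ValidationError("scene has no nuclei")
        return self.marker_count(marker) / len(self.nuclei)

    def mean_radius_um(self) -> float:
        return float(np.mean([n.radius_um for n in self.nuclei]))

    def exclusion_mask(self, dilate: float = 1.0) -> RoiMask:
        """Boolean grid of the dye-exclusion (PSC) ellipsoid, optionally
        scaled by *dilate* about its centre."""
        mask = _ellipsoid_mask(self.shape, self.spacing, self.params.psc_center_um,
                               tuple(dilate * a for a in self.params.psc_semiaxes))
        return RoiMask(mask, name="PSC")

    def to_dataframe(self) -> pd.DataFrame:
        markers = self.params.marker_names()
        rows = []
        for n in self.nuclei:
            row = {"id": n.id, "z": n.center_um[0], "y": n.center_um[1],
                   "x": n.center_um[2], "radius_um": n.radius_um, "region": n.region}
            for m in markers:
                row[m] = int(m in n.markers)
            rows.append(row)
        return pd.DataFrame(rows)


def _ellipsoid_mask(shape, spacing, center_um, semiaxes_um) -> np.ndarray:
    axes = [(np.arange(n) * s - c) / a
            for n, s, c, a in zip(shape, spacing, center_um, semiaxes_um)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    return zz ** 2 + yy ** 2 + xx ** 2 <= 1.0


def _inside_ellipsoid(p, center, semiaxes) -> bool:
    return sum(((pi - ci) / ai) ** 2 for pi, ci, ai in zip(p, center, semiaxes)) <= 1.0


# ---------------------------------------------------------------------------
# Scene sampling
# ---------------------------------------------------------------------------

def sample_scene(params: SceneParams, seed: int) -> GroundTruthScene:
    """Draw a ground-truth scene: nucleus positions, radii, regions, markers.

    Positions are placed by rejection sampling with a hard minimum pairwise
    separation (when ``min_separation > 0``).  PSC nuclei are placed inside
    the exclusion ellipsoid, all others outside it.  Marker memberships are
    assigned by seeded sampling without replacement so requested counts are
    met exactly: a fraction *f* over *n* nuclei yields ``round(f * n)``
    members.

    Deterministic given ``(params, seed)``.

    Raises
    ------
    PackingError
        If the packing-feasibility bound fails or rejection sampling cannot
        place a nucleus within the attempt budget.
    """
    rng = np.random.default_rng(seed)
    n = params.n_nuclei
    extent = params.extent_um

    if params.min_separation > 0 and n > 0:
        exclusion_vol = n * (4.0 / 3.0) * math.pi * (params.min_separation / 2) ** 3
        box_vol = float(np.prod(extent))
        if exclusion_vol > _RSA_SATURATION * box_vol:
            raise PackingError(
                f"{n} nuclei at min_separation {params.min_separation} µm cannot pack "
                f"into a {extent[0]:.0f}x{extent[1]:.0f}x{extent[2]:.0f} µm volume "
                f"(needs {exclusion_vol:.0f} µm³ of exclusion volume, "
                f"bound {_RSA_SATURATION * box_vol:.0f} µm³)")

    psc_center = params.psc_center_um
    radii = rng.uniform(*params.radius_range, size=n)
    centers: list[tuple[float, float, float]] = []
    placed = np.empty((0, 3))
    budget = params.max_attempts_per_nucleus * max(n, 1)
    attempts = 0
    for i in range(n):
        in_psc = i < params.psc_count
        r = radii[i]
        while True:
            attempts += 1
            if attempts > budget:
                raise PackingError(
                    f"failed to place nucleus {i} after {budget} total attempts; "
                    "reduce n_nuclei or min_separation")
            if in_psc:
                # uniform in the ellipsoid's bounding box, rejected to the inside
                cand = tuple(
                    rng.uniform(c - a, c + a)
                    for c, a in zip(psc_center, params.psc_semiaxes))
                if not _inside_ellipsoid(cand, psc_center, params.psc_semiaxes):
                    continue
                if any(not r <= cand[k] <= extent[k] - r for k in range(3)):
                    continue
            else:
                cand = tuple(rng.uniform(r, e - r) for e in extent)
                # keep non-PSC cells clear of the exclusion region (10% margin);
                # scenes without a niche population use the whole field
                if params.psc_count > 0 and _inside_ellipsoid(
                        cand, psc_center, tuple(1.1 * a for a in params.psc_semiaxes)):
                    continue
            if params.min_separation > 0 and len(centers):
                d2 = np.sum((placed - np.asarray(cand)) ** 2, axis=1)
                if d2.min() < params.min_separation ** 2:
                    continue
            break
        centers.append(cand)
        placed = np.vstack([placed, cand])

    # marker memberships: exact counts, sampled without replacement among
    # non-PSC nuclei (counts are fractions of the full population)
    non_psc = np.arange(params.psc_count, n)
    memberships: dict[int, set[str]] = {i: set() for i in range(n)}
    for marker in sorted(params.marker_fractions):
        k = int(round(params.marker_fractions[marker] * n))
        if k > len(non_psc):
            raise ValidationError(
                f"marker {marker!r} needs {k} members but only {len(non_psc)} "
                "non-PSC nuclei exist")
        chosen = rng.choice(non_psc, size=k, replace=False) if k else []
        for i in chosen:
            memberships[int(i)].add(marker)

    diff_markers = set(params.marker_fractions)
    nuclei = []
    for i in range(n):
        if i < params.psc_count:
            region = "PSC"
            if params.psc_marker:
                memberships[i].add(params.psc_marker)
        else:
            region = "CZ" if memberships[i] & diff_markers else "MZ"
        nuclei.append(Nucleus(id=i, center_um=centers[i], radius_um=float(radii[i]),
                              region=region, markers=frozenset(memberships[i])))
    return GroundTruthScene(params=params, nuclei=tuple(nuclei), seed=int(seed))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _local_window(center_um, reach_um, shape, spacing):
    """Index slices and physical distance grid for a ball around a point."""
    los, his = [], []
    for c, n_, s in zip(center_um, shape, spacing):
        lo = max(0, int(math.ceil((c - reach_um) / s)))
        hi = min(n_ - 1, int(math.floor((c + reach_um) / s)))
        if lo > hi:
            return None, None
        los.append(lo)
        his.append(hi)
    axes = [(np.arange(lo, hi + 1) * s - c)
            for lo, hi, s, c in zip(los, his, spacing, center_um)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    sl = tuple(slice(lo, hi + 1) for lo, hi in zip(los, his))
    return sl, d


def _add_blob(grid, center_um, sigma_um, amplitude, spacing, cutoff=4.0):
    sl, d = _local_window(center_um, cutoff * sigma_um, grid.shape, spacing)
    if sl is not None:
        grid[sl] += amplitude * np.exp(-(d ** 2) / (2.0 * sigma_um ** 2))


def _add_shell(grid, center_um, radius_um, thickness_um, amplitude, spacing, cutoff=3.0):
    sigma = thickness_um / 2.0
    sl, d = _local_window(center_um, radius_um + cutoff * sigma, grid.shape, spacing)
    if sl is not None:
        grid[sl] += amplitude * np.exp(-((d - radius_um) ** 2) / (2.0 * sigma ** 2))


def _background(params: SceneParams) -> np.ndarray:
    nz, ny, nx = params.shape
    ramp = params.background_base + params.background_gradient * (
        np.arange(nx) / max(nx - 1, 1))
    return np.broadcast_to(ramp, (nz, ny, nx)).astype(float).copy()


def _apply_noise(grid: np.ndarray, noise: NoiseModel, rng: np.random.Generator
                 ) -> np.ndarray:
    out = grid
    if not noise.noiseless:
        out = rng.poisson(noise.photon_scale * np.clip(grid, 0, None)
                          ).astype(float) / noise.photon_scale
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=grid.shape)
    lo, hi = 0.0, noise.saturation_level
    if math.isfinite(hi):
        return np.clip(out, lo, hi)
    return np.clip(out, lo, None) if not noise.noiseless or noise.read_sigma > 0 else out


def render_scene(scene: GroundTruthScene, noise: NoiseModel = NOISELESS, *,
                 channels: Sequence[str] | None = None,
                 attenuation: float | None = None,
                 seed: int | None = None) -> MultiChannelVolume:
    """Render a scene to a multi-channel volume.

    Parameters
    ----------
    scene, noise
        The ground truth and the noise model.
    channels
        Channel names to render.  Default: nuclear channel plus all marker
        channels.  Dye channels must be requested explicitly (or via
        :func:`render_barrier_pair`).
    attenuation
        Override the large-dye attenuation inside the exclusion region;
        default is the scene's own value.
    seed
        Noise seed; defaults to a stream derived from the scene seed.
        Identical ``(scene, noise, seed)`` give bit-identical output.
    """
    p = scene.params
    if channels is None:
        channels = [p.nuclear_channel, *sorted(p.marker_fractions)]
        if p.psc_marker:
            channels.append(p.psc_marker)
    att = p.attenuation if attenuation is None else attenuation
    # canonical accumulation order: float sums are order-sensitive, and the
    # render must not depend on nucleus ids or list order
    ordered = sorted(scene.nuclei, key=lambda n: (n.center_um, n.radius_um))

    grids: dict[str, np.ndarray] = {}
    for name in channels:
        if name == p.nuclear_channel:
            g = _background(p)
            for nuc in ordered:
                _add_blob(g, nuc.center_um, nuc.radius_um / 2.0,
                          p.nuclear_amplitude, p.spacing)
        elif name in p.marker_names():
            g = np.full(p.shape, p.marker_background, dtype=float)
            for nuc in ordered:
                if name in nuc.markers:
                    _add_shell(g, nuc.center_um, nuc.radius_um,
                               p.shell_thickness_factor * nuc.radius_um,
                               p.marker_amplitude, p.spacing)
        elif name in p.dye_channels:
            g = np.zeros(p.shape, dtype=float)
            for nuc in ordered:
                _add_shell(g, nuc.center_um, nuc.radius_um,
                           p.shell_thickness_factor * nuc.radius_um,
                           p.dye_amplitude, p.spacing)
            if name == p.dye_channels[1]:  # large dye: attenuated in the PSC
                excl = scene.exclusion_mask().voxels
                g[excl] *= att
            g += p.dye_background
        else:
            raise ValidationError(f"unknown channel {name!r} for this scene")
        grids[name] = g

    rng = np.random.default_rng(
        np.random.SeedSequence([scene.seed, 0xA5]) if seed is None else seed)
    noisy = {name: _apply_noise(grids[name], noise, rng)
             for name in sorted(grids)}
    # preserve requested channel order
    out = {name: noisy[name] for name in channels}
    return MultiChannelVolume(out, spacing=p.spacing,
                              metadata={"scene_seed": scene.seed,
                                        "saturation": noise.saturation_level})


def render_barrier_pair(scene: GroundTruthScene, noise: NoiseModel = NOISELESS,
                        barrier_intact: bool = True, *,
                        seed: int | None = None) -> MultiChannelVolume:
    """Render the dual-dye assay: both dextran channels plus the nuclear one.

    With an intact barrier the large (70 kDa) dye is attenuated inside the
    exclusion region; with a broken barrier both dyes render identically up
    to independent noise.
    """
    p = scene.params
    att = p.attenuation if barrier_intact else 1.0
    return render_scene(
        scene, noise,
        channels=[p.nuclear_channel, *p.dye_channels],
        attenuation=att, seed=seed)


# ---------------------------------------------------------------------------
# Truth matching (for benchmarking the detector)
# ---------------------------------------------------------------------------

def match_detections(scene: GroundTruthScene, detections: Iterable,
                     max_dist_um: float = 2.0) -> pd.DataFrame:
    """Optimally match detections to ground-truth nuclei within a radius.

    Uses a one-to-one assignment minimising total centroid distance
    (Hungarian algorithm); pairs farther apart than *max_dist_um* are
    not matched.  Returns a one-row DataFrame with n_true, n_detected,
    n_matched, recall, precision and the worst matched centroid error in
    voxel units (error along each axis divided by that axis' spacing).
    """
    dets = list(detections)
    truth = np.array([n.center_um for n in scene.nuclei]).reshape(-1, 3)
    found = np.array([d.centroid_um for d in dets]).reshape(-1, 3)
    n_true, n_det = len(truth), len(found)
    if n_true == 0 or n_det == 0:
        n_matched, max_err = 0, math.nan
    else:
        cost = np.linalg.norm(truth[:, None, :] - found[None, :, :], axis=2)
        big = max_dist_um * 1e6
        rows, cols = linear_sum_assignment(np.where(cost <= max_dist_um, cost, big))
        ok = cost[rows, cols] <= max_dist_um
        rows, cols = rows[ok], cols[ok]
        n_matched = len(rows)
        if n_matched:
            err_vox = np.abs(truth[rows] - found[cols]) / np.asarray(scene.spacing)
            max_err = float(err_vox.max())
        else:
            max_err = math.nan
    return pd.DataFrame([{
        "n_true": n_true, "n_detected": n_det, "n_matched": n_matched,
        "recall": n_matched / n_true if n_true else math.nan,
        "precision": n_matched / n_det if n_det else math.nan,
        "max_centroid_error_vox": max_err,
    }])
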