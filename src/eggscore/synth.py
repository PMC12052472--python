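"""Parametric generator of ornamented test surfaces.

Sections are built as height fields z(x, y) over a 10 mm disc — a sum of
Gaussian nodes, Gaussian-profile ridges extruded along a chosen azimuth and
smooth band-limited noise — triangulated on a regular grid.  Height-field
construction guarantees no overhangs (slopes stay in the undirected regime,
like real low-relief eggshell) and band-limited noise keeps the curvature
energy finite as resolution grows.  Amplitudes control relief, node density
and width control complexity, and the ridge/node balance plus ridge azimuth
control directionality, so metric expectations can be engineered by
construction.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .mesh import SurfaceSection, TriangleMesh, submesh, write_mesh

__all__ = [
    "SynthParams",
    "SynthEggParams",
    "make_section",
    "make_vgroove",
    "make_egg",
    "zone_of",
    "write_clutch",
]


@dataclass(frozen=True)
class SynthParams:
    """Generative parameters for one ornamented section (lengths in mm).

    Defaults emulate a moderately ornamented eggshell section: a 10 mm disc
    at 8 grid vertices/mm (~10,000 faces before decimation, comfortably
    above the 5000-face standard), dispersed nodes of ~0.15 mm relief and a
    few pole-to-pole ridges (azimuth 90 = the long-axis convention).
    """

    section_diameter: float = 10.0
    grid_resolution: float = 8.0  # vertices per mm
    node_count: int = 25
    node_amplitude: float = 0.15
    node_width: float = 0.4  # Gaussian sigma
    ridge_count: int = 4
    ridge_amplitude: float = 0.15
    ridge_width: float = 0.35
    ridge_azimuth: float = 90.0  # degrees CCW from +X; 90 = along the long axis
    noise_amplitude: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.section_diameter <= 0:
            raise ParameterError("section_diameter must be positive")
        for name in ("node_amplitude", "ridge_amplitude", "noise_amplitude"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for name in ("node_width", "ridge_width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        # ~2 * resolution^2 * disc area faces before decimation
        approx_faces = (
            2.0
            * self.grid_resolution**2
            * np.pi
            * (self.section_diameter / 2.0) ** 2
        )
        if approx_faces < 5000:
            raise ParameterError(
                f"grid_resolution {self.grid_resolution} yields ~{approx_faces:.0f} "
                "faces, below the 5000-face standard; increase it"
            )


@dataclass(frozen=True)
class SynthEggParams:
    """Parameters for a whole synthetic egg: five zones, >= 30 sections.

    ``zone_overrides`` maps zone (1..5, zone 1 = acute pole) to SynthParams
    field overrides, which is how per-zone gradients (e.g., ornamentation
    fading toward a pole) are expressed.
    """

    specimen_id: str = "synthetic"
    egg_id: str = "egg01"
    egg_length: float = 135.0
    egg_width: float = 90.0
    sections_per_zone: int = 6
    base: SynthParams = SynthParams()
    zone_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.sections_per_zone < 1:
            raise ParameterError("sections_per_zone must be >= 1")
        if self.egg_length <= 0 or self.egg_width <= 0:
            raise ParameterError("egg dimensions must be positive")
        for z in self.zone_overrides:
            if z not in (1, 2, 3, 4, 5):
                raise ParameterError(f"zone_overrides key {z} outside 1..5")


def zone_of(relative_position: float) -> int:
    """Zone (1..5) of a relative position along the long axis.

    0 is the acute pole.  Zones are the five equal-length half-open
    intervals [0, 0.2), ..., [0.8, 1.0]; the upper endpoint closes into
    zone 5.
    """
    if not 0.0 <= relative_position <= 1.0:
        raise ParameterError(f"relative_position {relative_position} outside [0, 1]")
    return min(int(5 * relative_position) + 1, 5)


# ---------------------------------------------------------------------------


def _grid_disc(diameter: float, resolution: float):
    """Regular-grid triangulation of a square, cropped to the disc."""
    r = diameter / 2.0
    n = int(round(diameter * resolution))  # cells per side
    coords = np.linspace(-r, r, n + 1)
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    x = xx.ravel()
    y = yy.ravel()

    def vid(i, j):
        return j * (n + 1) + i

    i_idx, j_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="xy")
    i_idx = i_idx.ravel()
    j_idx = j_idx.ravel()
    v00 = vid(i_idx, j_idx)
    v10 = vid(i_idx + 1, j_idx)
    v01 = vid(i_idx, j_idx + 1)
    v11 = vid(i_idx + 1, j_idx + 1)
    faces = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    return np.column_stack([x, y]), faces, r


def _height_field(xy, params: SynthParams, rng: np.random.Generator):
    x = xy[:, 0]
    y = xy[:, 1]
    r = params.section_diameter / 2.0
    z = np.zeros(len(xy))

    if params.node_count > 0 and params.node_amplitude > 0:
        # uniform over the disc (sqrt radius transform)
        rad = r * np.sqrt(rng.uniform(0, 1, params.node_count))
        ang = rng.uniform(0, 2 * np.pi, params.node_count)
        cx = rad * np.cos(ang)
        cy = rad * np.sin(ang)
        for k in range(params.node_count):
            d2 = (x - cx[k]) ** 2 + (y - cy[k]) ** 2
            z += params.node_amplitude * np.exp(-d2 / (2 * params.node_width**2))

    if params.ridge_count > 0 and params.ridge_amplitude > 0:
        az = np.radians(params.ridge_azimuth)
        # signed distance from the crest line through offset o along (sin, -cos)
        s = x * np.sin(az) - y * np.cos(az)
        offsets = np.linspace(-r, r, params.ridge_count + 2)[1:-1]
        offsets = offsets + rng.uniform(-0.25, 0.25, params.ridge_count) * (
            2 * r / (params.ridge_count + 1)
        )
        for o in offsets:
            z += params.ridge_amplitude * np.exp(
                -((s - o) ** 2) / (2 * params.ridge_width**2)
            )

    if params.noise_amplitude > 0:
        n_waves = 6
        wavelengths = rng.uniform(1.5, 3.0, n_waves)
        azimuths = rng.uniform(0, 2 * np.pi, n_waves)
        phases = rng.uniform(0, 2 * np.pi, n_waves)
        for lam, azw, ph in zip(wavelengths, azimuths, phases):
            proj = x * np.cos(azw) + y * np.sin(azw)
            z += (params.noise_amplitude / np.sqrt(n_waves)) * np.cos(
                2 * np.pi * proj / lam + ph
            )
    return z


def _crop_to_disc(xy, z, faces, r):
    verts = np.column_stack([xy, z])
    mesh = TriangleMesh(verts, faces)
    cent = mesh.face_centroids
    keep = np.hypot(cent[:, 0], cent[:, 1]) <= r
    return submesh(mesh, keep)


def make_section(
    params: SynthParams = SynthParams(),
    specimen_id: str = "synthetic",
    egg_id: str = "egg01",
    zone: int = 1,
    section_id: str = "s000",
) -> SurfaceSection:
    """Generate one ornamented disc section, already in the aligned frame
    (+Z vertical, long axis on +Y)."""
    xy, faces, r = _grid_disc(params.section_diameter, params.grid_resolution)
    rng = np.random.default_rng(params.seed)
    z = _height_field(xy, params, rng)
    z = z - z.mean()
    mesh = _crop_to_disc(xy, z, faces, r)
    if mesh.n_faces < 5000:
        raise ParameterError(
            f"generated section has {mesh.n_faces} faces, below the 5000 standard"
        )
    return SurfaceSection(
        mesh=mesh,
        specimen_id=specimen_id,
        egg_id=egg_id,
        zone=zone,
        section_id=section_id,
        long_axis_azimuth=90.0,
        section_diameter=params.section_diameter,
    )


def make_vgroove(
    diameter: float = 10.0,
    amplitude: float = 0.2,
    period: float = 1.0,
    grid_resolution: float = 8.0,
    crest_azimuth: float = 90.0,
) -> SurfaceSection:
    """Deterministic triangle-wave ridge field (a 'V-groove' surface).

    With ``crest_azimuth`` a multiple of 90 degrees the mesh is built along
    +Y and rotated by an exact permutation matrix, so every face normal's
    azimuth is exactly 0/180 (or 90/270 after a 90-degree rotation): the
    extreme test case for the orientation score.  The wave period is a
    multiple of the grid spacing with crests on grid lines, so no face is
    horizontal.
    """
    n_half = int(round(grid_resolution * period / 2.0))
    if n_half < 1 or not np.isclose(n_half, grid_resolution * period / 2.0):
        raise ParameterError(
            "grid_resolution * period / 2 must be a whole number of cells"
        )
    xy, faces, r = _grid_disc(diameter, grid_resolution)
    t = xy[:, 0] / period
    z = amplitude * (4.0 * np.abs(t - np.round(t)) - 1.0)
    mesh = _crop_to_disc(xy, z - z.mean(), faces, r)

    quarter_turns = crest_azimuth - 90.0
    if np.isclose(quarter_turns % 90.0, 0.0):
        k = int(round(quarter_turns / 90.0)) % 4
        rot = np.linalg.matrix_power(
            np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]), k
        )
    else:
        c = np.cos(np.radians(quarter_turns))
        s = np.sin(np.radians(quarter_turns))
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    mesh = TriangleMesh(mesh.vertices @ rot.T, mesh.faces)
    return SurfaceSection(
        mesh=mesh,
        specimen_id="synthetic",
        egg_id="vgroove",
        zone=1,
        section_id=f"vgroove_az{crest_azimuth:g}",
        long_axis_azimuth=90.0,
        section_diameter=diameter,
    )


def make_egg(params: SynthEggParams = SynthEggParams()) -> list[SurfaceSection]:
    """Generate one synthetic egg as a list of sections across the five zones.

    Each zone gets ``sections_per_zone`` sections (default 6, so 30 per egg,
    the study's minimum per-egg count) at random relative positions within
    the zone; per-zone parameter overrides express gradients along the egg.
    Section seeds are derived from the egg seed, so the whole clutch is
    reproducible.
    """
    master = np.random.SeedSequence(params.seed)
    n_total = 5 * params.sections_per_zone
    child_seeds = (master.generate_state(n_total) & 0x7FFFFFFF).tolist()
    pos_rng = np.random.default_rng(master.spawn(1)[0])

    sections = []
    i = 0
    for zone in range(1, 6):
        overrides = dict(params.zone_overrides.get(zone, {}))
        for _ in range(params.sections_per_zone):
            rel = (zone - 1 + pos_rng.uniform(0.0, 1.0)) / 5.0
            assert zone_of(rel) == zone
            sp = replace(params.base, seed=child_seeds[i], **overrides)
            sections.append(
                make_section(
                    sp,
                    specimen_id=params.specimen_id,
                    egg_id=params.egg_id,
                    zone=zone,
                    section_id=f"{params.egg_id}_z{zone}_s{i:03d}",
                )
            )
            i += 1
    return sections


def write_clutch(sections, out_dir) -> str:
    """Write sections as PLY files plus a manifest CSV; returns the manifest
    path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "filename",
                "section_id",
                "egg_id",
                "specimen_id",
                "zone",
                "long_axis_azimuth",
                "section_diameter",
            ]
        )
        for sec in sections:
            fname = f"{sec.section_id}.ply"
            write_mesh(sec.mesh, os.path.join(out_dir, fname))
            writer.writerow(
                [
                    fname,
                    sec.section_id,
                    sec.egg_id,
                    sec.specimen_id,
                    sec.zone,
                    repr(sec.long_axis_azimuth),
                    repr(sec.section_diameter),
                ]
            )
    return manifest
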