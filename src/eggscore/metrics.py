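"""The three ornamentation metrics and the combined SCORE record.

Complexity is Dirichlet normal energy (DNE): per face, the energy density
``e = tr(G^-1 H)`` of the normal field (G, H the first fundamental forms of
the position and normal maps over the triangle) integrated as ``sum(e * A)``
over retained faces.  Relief is mean slope, the per-face angle from the
horizontal computed from the undirected normal.  Directionality is the
Orientation score: face areas are binned by normal azimuth into eight 45
degree bins and the score contrasts area in the bins flanking the egg's long
axis (1, 4, 5, 8 with the long axis on +Y) against the rest, mapped to
-100..+100 by the normalized difference — positive means ornamentation
running pole to pole.

DNE follows the convention of discarding boundary faces and the largest
0.1% of face contributions (both configurable), which keeps edge effects
and solitary spikes from dominating the integral.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import MetricError, ParameterError, UndefinedOrientationError
from .mesh import SurfaceSection, TriangleMesh, detect_boundary

__all__ = [
    "MetricSettings",
    "FaceEnergy",
    "BinAreas",
    "ScoreRecord",
    "dne",
    "slope",
    "bin_areas",
    "orientation",
    "score",
    "write_score_csv",
    "read_score_csv",
]

ALONG_AXIS_BINS = frozenset({1, 4, 5, 8})


@dataclass(frozen=True)
class MetricSettings:
    """Conventions shared by the three metrics.

    ``long_axis_azimuth`` is the in-plane direction (degrees CCW from +X) of
    the egg's pole-to-pole axis; the default 90 puts it on +Y, under which
    azimuth bins 1, 4, 5 and 8 flank the long axis.  ``bin_count`` and
    ``bin_width`` are fixed by the eight-bin convention.
    """

    dne_outlier_fraction: float = 0.001
    boundary_discard: str = "vertex"  # {vertex, edge, none}
    slope_weighting: str = "unweighted"  # {unweighted, area}
    bin_count: int = 8
    bin_width: float = 45.0
    along_axis_bins: frozenset = ALONG_AXIS_BINS
    long_axis_azimuth: float = 90.0
    vertical_tolerance: float = 1e-9

    def __post_init__(self):
        if self.bin_count * self.bin_width != 360.0:
            raise ParameterError("bin_count * bin_width must equal 360")
        bins = set(self.along_axis_bins)
        if not bins or not bins <= set(range(1, self.bin_count + 1)):
            raise ParameterError("along_axis_bins must be a subset of 1..bin_count")
        if self.boundary_discard not in ("vertex", "edge", "none"):
            raise ParameterError(f"unknown boundary_discard {self.boundary_discard!r}")
        if self.slope_weighting not in ("unweighted", "area"):
            raise ParameterError(f"unknown slope_weighting {self.slope_weighting!r}")
        if not 0.0 <= self.dne_outlier_fraction < 1.0:
            raise ParameterError("dne_outlier_fraction must be in [0, 1)")


@dataclass(frozen=True)
class FaceEnergy:
    """One face's DNE contribution (or the reason it was skipped)."""

    face_index: int
    energy_density: float
    area: float
    skip_reason: str | None = None

    @property
    def contribution(self) -> float:
        return self.energy_density * self.area


@dataclass
class BinAreas:
    """Surface area (mm^2) per azimuth bin plus the excluded vertical area."""

    areas: np.ndarray = field(repr=False)  # index 0 -> bin 1
    excluded_area: float = 0.0

    def area_of(self, bin_index: int) -> float:
        return float(self.areas[bin_index - 1])

    @property
    def total_area(self) -> float:
        return float(self.areas.sum() + self.excluded_area)


@dataclass
class ScoreRecord:
    """One section's (complexity, relief, orientation) triple with metadata."""

    specimen_id: str
    egg_id: str
    zone: int
    section_id: str
    complexity: float
    relief: float
    orientation: float


# ---------------------------------------------------------------------------
# face retention


def _retained_mask(mesh: TriangleMesh, settings: MetricSettings) -> np.ndarray:
    if settings.boundary_discard == "none":
        return np.ones(mesh.n_faces, dtype=bool)
    info = detect_boundary(mesh)
    if settings.boundary_discard == "vertex":
        # any face touching a boundary vertex
        return ~info.boundary_face_flags
    # edge rule: only faces owning an actual boundary edge
    faces = mesh.faces
    flags = info.boundary_vertex_flags
    edge_pairs = flags[faces[:, [0, 1, 1, 2, 2, 0]]].reshape(-1, 3, 2).all(axis=2)
    # a face owns a boundary edge iff two of its vertices share one; confirm
    # against the edge list to avoid flagging faces that merely touch two
    # separate boundary vertices
    from .mesh import _edge_counts

    uniq, counts = _edge_counts(faces)
    boundary_edges = {tuple(e) for e in uniq[counts == 1]}
    out = np.zeros(mesh.n_faces, dtype=bool)
    candidates = np.nonzero(edge_pairs.any(axis=1))[0]
    for fi in candidates:
        f = faces[fi]
        for k in range(3):
            e = tuple(sorted((f[k], f[(k + 1) % 3])))
            if e in boundary_edges:
                out[fi] = True
                break
    return ~out


# ---------------------------------------------------------------------------
# Complexity: Dirichlet normal energy


def dne(
    mesh: TriangleMesh, settings: MetricSettings = MetricSettings()
) -> tuple[float, list[FaceEnergy]]:
    """Total Dirichlet normal energy and the per-face breakdown.

    For each retained face with vertices v1,v2,v3 and vertex normals
    n1,n2,n3: with u = v2-v1, w = v3-v1, nu = n2-n1, nw = n3-n1,
    G = [[u.u, u.w], [u.w, w.w]], H = [[nu.nu, nu.nw], [nu.nw, nw.nw]],
    the density is e = tr(G^-1 H) and the face contributes e*A.  Faces with
    singular G (degenerate geometry) are skipped and recorded, never fatal.
    After boundary discard, the top ``dne_outlier_fraction`` of faces ranked
    by contribution are dropped.
    """
    if mesh.is_empty:
        raise MetricError("cannot compute DNE of an empty mesh")
    v = mesh.vertices
    f = mesh.faces
    vn = mesh.vertex_normals
    areas = mesh.face_areas

    u = v[f[:, 1]] - v[f[:, 0]]
    w = v[f[:, 2]] - v[f[:, 0]]
    nu = vn[f[:, 1]] - vn[f[:, 0]]
    nw = vn[f[:, 2]] - vn[f[:, 0]]
    guu = (u * u).sum(axis=1)
    guw = (u * w).sum(axis=1)
    gww = (w * w).sum(axis=1)
    huu = (nu * nu).sum(axis=1)
    huw = (nu * nw).sum(axis=1)
    hww = (nw * nw).sum(axis=1)
    det = guu * gww - guw * guw
    scale = guu * gww + guw * guw
    singular = det <= 1e-12 * np.maximum(scale, 1e-300)
    e = np.zeros(len(f))
    ok = ~singular
    # tr(G^-1 H) with G^-1 = [[gww, -guw], [-guw, guu]] / det
    e[ok] = (gww[ok] * huu[ok] - 2.0 * guw[ok] * huw[ok] + guu[ok] * hww[ok]) / det[ok]
    e = np.maximum(e, 0.0)  # clamp tiny negative round-off

    retained = _retained_mask(mesh, settings)
    energies: list[FaceEnergy] = []
    for fi in range(len(f)):
        if singular[fi]:
            energies.append(FaceEnergy(fi, 0.0, float(areas[fi]), "singular G"))
        elif not retained[fi]:
            energies.append(FaceEnergy(fi, float(e[fi]), float(areas[fi]), "boundary"))
    keep = retained & ~singular
    if not keep.any():
        raise MetricError("all faces degenerate or discarded; DNE undefined")

    contrib = e * areas
    if settings.dne_outlier_fraction > 0:
        idx = np.nonzero(keep)[0]
        n_drop = int(np.floor(settings.dne_outlier_fraction * len(idx)))
        if n_drop > 0:
            order = idx[np.argsort(contrib[idx])[::-1][:n_drop]]
            keep[order] = False
            for fi in order:
                energies.append(
                    FaceEnergy(int(fi), float(e[fi]), float(areas[fi]), "outlier")
                )
    for fi in np.nonzero(keep)[0]:
        energies.append(FaceEnergy(int(fi), float(e[fi]), float(areas[fi])))
    energies.sort(key=lambda fe: fe.face_index)
    total = float(contrib[keep].sum())
    return total, energies


# ---------------------------------------------------------------------------
# Relief: slope


def slope(
    mesh: TriangleMesh, settings: MetricSettings = MetricSettings()
) -> tuple[float, np.ndarray]:
    """Mean face slope in degrees and the per-face slopes.

    Slope is ``arccos(|n_z|)``: the angle of the face from horizontal under
    the undirected-normal convention, so every value lies in [0, 90].  The
    mean is unweighted over retained faces by default; ``slope_weighting=
    'area'`` switches to the area-weighted mean.
    """
    if mesh.is_empty:
        raise MetricError("cannot compute slope of an empty mesh")
    nz = np.abs(mesh.face_normals[:, 2])
    slopes = np.degrees(np.arccos(np.clip(nz, 0.0, 1.0)))
    retained = _retained_mask(mesh, settings)
    retained &= mesh.face_areas > 0
    if not retained.any():
        raise MetricError("no retained faces; slope undefined")
    if settings.slope_weighting == "area":
        areas = mesh.face_areas[retained]
        mean = float((slopes[retained] * areas).sum() / areas.sum())
    else:
        mean = float(slopes[retained].mean())
    return mean, slopes


# ---------------------------------------------------------------------------
# Directionality: azimuth bin areas and the orientation score


def bin_areas(
    mesh: TriangleMesh, settings: MetricSettings = MetricSettings()
) -> BinAreas:
    """Accumulate retained face area into eight 45-degree azimuth bins.

    A face's azimuth is the direction of its normal's X-Y projection,
    measured counterclockwise from +X and rotated so the configured long
    axis sits on +Y.  Near-vertical normals (projection below
    ``vertical_tolerance``) cannot be assigned a direction and accumulate
    into the excluded area.
    """
    if mesh.is_empty:
        raise MetricError("cannot bin an empty mesh")
    retained = _retained_mask(mesh, settings)
    retained &= mesh.face_areas > 0
    normals = mesh.face_normals[retained]
    areas = mesh.face_areas[retained]
    proj = np.hypot(normals[:, 0], normals[:, 1])
    vertical = proj < settings.vertical_tolerance
    azimuth = np.degrees(np.arctan2(normals[:, 1], normals[:, 0]))
    # rotate the frame so the long axis maps to +Y (azimuth 90)
    azimuth = np.mod(azimuth + (90.0 - settings.long_axis_azimuth), 360.0)
    bins = np.minimum(
        (azimuth // settings.bin_width).astype(int), settings.bin_count - 1
    )
    out = np.zeros(settings.bin_count)
    np.add.at(out, bins[~vertical], areas[~vertical])
    return BinAreas(areas=out, excluded_area=float(areas[vertical].sum()))


def orientation_from_bins(
    bins: BinAreas, settings: MetricSettings = MetricSettings()
) -> float:
    """Map the along/across area split to the -100..+100 orientation score.

    With R = SA_along / SA_across, the score is the normalized difference
    100*(SA_along - SA_across)/(SA_along + SA_across) = 100*(R - 1)/(R + 1):
    the unique smooth, bounded, sign-correct map of the ratio onto the
    published scale.  Isolated here so the transform can be swapped in one
    place.
    """
    along = sum(bins.area_of(b) for b in sorted(settings.along_axis_bins))
    across = float(bins.areas.sum()) - along
    total = along + across
    if total <= 0:
        raise UndefinedOrientationError(
            "all retained area is vertical; orientation undefined"
        )
    return 100.0 * (along - across) / total


def orientation(
    mesh: TriangleMesh, settings: MetricSettings = MetricSettings()
) -> float:
    """Orientation score of a mesh: positive = pole-to-pole ornamentation."""
    return orientation_from_bins(bin_areas(mesh, settings), settings)


# ---------------------------------------------------------------------------
# SCORE


def score(
    section: SurfaceSection, settings: MetricSettings = MetricSettings()
) -> ScoreRecord:
    """Compute the full SCORE triple for one standardized section."""
    s = replace(settings, long_axis_azimuth=section.long_axis_azimuth)
    try:
        complexity, _ = dne(section.mesh, s)
        relief, _ = slope(section.mesh, s)
        omega = orientation(section.mesh, s)
    except MetricError as exc:
        raise MetricError(f"section {section.section_id!r}: {exc}") from exc
    return ScoreRecord(
        specimen_id=section.specimen_id,
        egg_id=section.egg_id,
        zone=section.zone,
        section_id=section.section_id,
        complexity=complexity,
        relief=relief,
        orientation=omega,
    )


SCORE_HEADER = [
    "specimen_id",
    "egg_id",
    "zone",
    "section_id",
    "complexity",
    "relief",
    "orientation",
]


def write_score_csv(records, path, settings: MetricSettings | None = None) -> None:
    """Write SCORE records as CSV; metric settings echoed as '#' comments."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if settings is not None:
            fh.write(f"# boundary_discard={settings.boundary_discard}\n")
            fh.write(f"# dne_outlier_fraction={settings.dne_outlier_fraction}\n")
            fh.write(f"# slope_weighting={settings.slope_weighting}\n")
            fh.write(
                "# along_axis_bins="
                + ",".join(str(b) for b in sorted(settings.along_axis_bins))
                + "\n"
            )
        writer = csv.writer(fh)
        writer.writerow(SCORE_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.specimen_id,
                    r.egg_id,
                    r.zone,
                    r.section_id,
                    repr(r.complexity),
                    repr(r.relief),
                    repr(r.orientation),
                ]
            )


def read_score_csv(path) -> list[ScoreRecord]:
    """Read a SCORE CSV written by :func:`write_score_csv`."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = (line for line in fh if not line.startswith("#"))
        reader = csv.DictReader(rows)
        for row in reader:
            records.append(
                ScoreRecord(
                    specimen_id=row["specimen_id"],
                    egg_id=row["egg_id"],
                    zone=int(row["zone"]),
                    section_id=row["section_id"],
                    complexity=float(row["complexity"]),
                    relief=float(row["relief"]),
                    orientation=float(row["orientation"]),
                )
            )
    return records
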