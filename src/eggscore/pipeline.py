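"""End-to-end orchestration: ingest -> standardize -> SCORE -> statistics.

Mirrors the study workflow: sections are read (or taken in memory), aligned
to the X-Y plane, decimated to the standard 5000 faces, scored, filtered
per egg per metric with the asymmetric IQR rule, aggregated per egg and per
zone, and compared pairwise with exact KS tests combined by harmonic-mean
p-values.  All outputs are deterministic given the config and seed; per-
section failures are logged and never abort a batch.
"""

from __future__ import annotations

import glob as _glob
import logging
import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decimate import decimate
from .errors import EggscoreError, ParameterError
from .mesh import SurfaceSection, align_to_xy, read_mesh
from .metrics import MetricSettings, ScoreRecord, score, write_score_csv
from .stats import (
    METRICS,
    OutlierPolicy,
    bootstrap_mean_diff,
    iqr_filter,
    ks_exact,
    pairwise_compare,
)

logger = logging.getLogger("eggscore")

__all__ = ["RunConfig", "AggregateTable", "run_score", "aggregate", "run_compare"]

FILENAME_PATTERN = re.compile(r"^(?P<egg>[^_]+)_(?P<zone>[1-5])_(?P<id>.+)$")


@dataclass
class RunConfig:
    """Settings for a pipeline run; the seed is always recorded in outputs."""

    inputs: list = field(default_factory=list)  # paths or globs of PLY/STL files
    manifest: str | None = None
    output_dir: str = "."
    pre_aligned: bool = False
    target_faces: int = 5000
    settings: MetricSettings = MetricSettings()
    policy: OutlierPolicy = OutlierPolicy()
    alpha: float = 0.05
    bootstrap_iterations: int = 1000
    seed: int = 0
    group_field: str = "specimen_id"  # taxon-level grouping for run_compare

    def resolve_inputs(self) -> list:
        paths = []
        for pattern in self.inputs:
            hits = sorted(_glob.glob(str(pattern)))
            paths.extend(hits if hits else [str(pattern)])
        return paths


@dataclass
class AggregateTable:
    """Per-egg and per-zone summaries of the SCORE metrics.

    ``per_egg``: one row per egg with each metric's outlier-filtered mean
    and retained/removed counts.  ``per_zone``: one row per (egg, zone) with
    mean, min and max per metric.  Ranges always bracket means.
    """

    per_egg: pd.DataFrame
    per_zone: pd.DataFrame


# ---------------------------------------------------------------------------
# ingest + standardize


def _sections_from_files(config: RunConfig):
    meta = {}
    if config.manifest:
        mdf = pd.read_csv(config.manifest)
        for _, row in mdf.iterrows():
            meta[str(row["filename"])] = row
    for path in config.resolve_inputs():
        base = os.path.basename(path)
        stem = os.path.splitext(base)[0]
        if base in meta or stem in meta:
            row = meta.get(base, meta.get(stem))
            yield path, dict(
                specimen_id=str(row.get("specimen_id", "")),
                egg_id=str(row["egg_id"]),
                zone=int(row["zone"]),
                section_id=str(row.get("section_id", stem)),
                long_axis_azimuth=float(row.get("long_axis_azimuth", 90.0)),
                section_diameter=float(row.get("section_diameter", 10.0)),
            )
        else:
            m = FILENAME_PATTERN.match(stem)
            if not m:
                raise ParameterError(
                    f"{base!r} has no manifest entry and does not match "
                    "<egg>_<zone>_<id>.ply"
                )
            yield path, dict(
                specimen_id="",
                egg_id=m.group("egg"),
                zone=int(m.group("zone")),
                section_id=stem,
                long_axis_azimuth=90.0,
                section_diameter=10.0,
            )


def standardize(section: SurfaceSection, config: RunConfig) -> SurfaceSection:
    """Align to the X-Y plane and decimate to the standard face count."""
    mesh = section.mesh
    azimuth = section.long_axis_azimuth
    if not config.pre_aligned:
        az = np.radians(azimuth)
        mesh = align_to_xy(mesh, (np.cos(az), np.sin(az), 0.0))
        azimuth = 90.0  # alignment maps the long axis onto +Y
    if mesh.n_faces > config.target_faces:
        mesh = decimate(mesh, config.target_faces)
    return SurfaceSection(
        mesh=mesh,
        specimen_id=section.specimen_id,
        egg_id=section.egg_id,
        zone=section.zone,
        section_id=section.section_id,
        long_axis_azimuth=azimuth,
        section_diameter=section.section_diameter,
    )


def run_score(config: RunConfig, sections=None):
    """Score a batch of sections; returns (records, failures).

    ``sections`` may be in-memory :class:`SurfaceSection` objects (e.g., from
    the synthetic generator); otherwise they are read from ``config.inputs``.
    Also writes ``score.csv`` (sorted by specimen, egg, zone, section) to the
    output directory when one is configured.  Every input section ends up in
    exactly one of the two return lists.
    """
    records: list[ScoreRecord] = []
    failures: list[tuple[str, str]] = []

    def handle(section_id, fn):
        try:
            records.append(fn())
        except (EggscoreError, OSError) as exc:
            logger.warning("section %s failed: %s", section_id, exc)
            failures.append((section_id, str(exc)))

    if sections is not None:
        for sec in sections:
            handle(
                sec.section_id,
                lambda sec=sec: score(standardize(sec, config), config.settings),
            )
    else:
        for path, kw in _sections_from_files(config):
            def load_and_score(path=path, kw=kw):
                mesh = read_mesh(path)
                sec = SurfaceSection(mesh=mesh, **kw)
                return score(standardize(sec, config), config.settings)

            handle(kw["section_id"], load_and_score)

    if not records:
        raise EggscoreError("no section could be scored")
    records.sort(key=lambda r: (r.specimen_id, r.egg_id, r.zone, r.section_id))
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        write_score_csv(
            records, os.path.join(config.output_dir, "score.csv"), config.settings
        )
    return records, failures


# ---------------------------------------------------------------------------
# aggregation


def aggregate(records, policy: OutlierPolicy = OutlierPolicy()) -> AggregateTable:
    """Per-egg means and per-zone means/ranges after per-egg outlier removal.

    Outlier filtering is applied per egg per metric (each metric keeps its
    own retained subset); zone statistics are computed from the retained
    sections only.
    """
    if not records:
        raise ParameterError("no records to aggregate")
    df = pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "egg_id": r.egg_id,
                "zone": r.zone,
                "section_id": r.section_id,
                **{m: getattr(r, m) for m in METRICS},
            }
            for r in records
        ]
    )
    egg_rows = []
    zone_rows = {}
    for egg_id, group in df.groupby("egg_id", sort=True):
        row = {"egg_id": egg_id, "specimen_id": group["specimen_id"].iloc[0]}
        for m in METRICS:
            x = group[m].to_numpy()
            if len(x) >= 4:
                kept_vals, removed = iqr_filter(x, policy)
                keep_mask = np.isin(x, kept_vals)
            else:
                kept_vals, removed = x, np.array([])
                keep_mask = np.ones(len(x), dtype=bool)
            row[f"{m}_mean"] = kept_vals.mean()
            row[f"{m}_retained"] = int(len(kept_vals))
            row[f"{m}_removed"] = int(len(removed))
            sub = group[keep_mask]
            for zone, zgroup in sub.groupby("zone", sort=True):
                zkey = (egg_id, zone)
                zrow = zone_rows.setdefault(
                    zkey, {"egg_id": egg_id, "zone": zone}
                )
                zrow[f"{m}_mean"] = zgroup[m].mean()
                zrow[f"{m}_min"] = zgroup[m].min()
                zrow[f"{m}_max"] = zgroup[m].max()
                zrow[f"{m}_n"] = int(len(zgroup))
        egg_rows.append(row)
    per_egg = pd.DataFrame(egg_rows).set_index("egg_id")
    per_zone = pd.DataFrame(list(zone_rows.values())).set_index(["egg_id", "zone"])
    return AggregateTable(per_egg=per_egg, per_zone=per_zone.sort_index())


# ---------------------------------------------------------------------------
# comparison


def run_compare(records, config: RunConfig):
    """Group- and egg-level comparison of SCORE distributions.

    Returns ``(matrix, group_tests, bootstrap_results, summary_text)`` where
    ``matrix`` is the egg-pairwise :class:`PairwiseMatrix`, ``group_tests``
    maps metric -> (D, p) for the pooled two-group KS test, and
    ``bootstrap_results`` maps metric -> mean-difference CI between the two
    groups.  Long-format and square-matrix CSVs plus a text summary are
    written to the output directory when one is configured.
    """
    records = list(records)
    matrix = pairwise_compare(records, alpha=config.alpha, policy=config.policy)

    groups: dict[str, list[ScoreRecord]] = {}
    for r in records:
        groups.setdefault(getattr(r, config.group_field), []).append(r)
    group_names = sorted(groups)

    group_tests = {}
    boots = {}
    if len(group_names) >= 2:
        if len(group_names) > 2:
            warnings.warn(
                "more than two groups; group-level tests use the first two",
                stacklevel=2,
            )
        ga, gb = group_names[:2]
        for m in METRICS:
            a = _pooled_filtered(groups[ga], m, config.policy)
            b = _pooled_filtered(groups[gb], m, config.policy)
            group_tests[m] = ks_exact(a, b)
            boots[m] = bootstrap_mean_diff(
                a, b, iterations=config.bootstrap_iterations, seed=config.seed
            )
    else:
        logger.info("single group %r: group comparison skipped", group_names)

    lines = [f"eggscore comparison (alpha={config.alpha}, seed={config.seed})"]
    lines.append(f"eggs: {', '.join(matrix.labels)}")
    frac = matrix.significant_fraction()
    lines.append(
        f"significant egg pairs (harmonic-mean p < {config.alpha}): "
        f"{frac:.3f} of {matrix.n_pairs}"
    )
    if len(group_names) >= 2:
        ga, gb = group_names[:2]
        eggs_a = sorted({r.egg_id for r in groups[ga]})
        eggs_b = sorted({r.egg_id for r in groups[gb]})
        within_a = matrix.significant_fraction(eggs_a, eggs_a)
        within_b = matrix.significant_fraction(eggs_b, eggs_b)
        cross = matrix.significant_fraction(eggs_a, eggs_b)
        lines.append(f"within-{ga} significant fraction: {within_a:.3f}")
        lines.append(f"within-{gb} significant fraction: {within_b:.3f}")
        lines.append(f"cross-group significant fraction: {cross:.3f}")
        for m in METRICS:
            d, p = group_tests[m]
            bo = boots[m]
            lines.append(
                f"{m}: group KS D={d:.4f} p={p:.3g} ({group_tests[m].method}); "
                f"mean diff {bo.estimate:.4f} [95% CI {bo.lower:.4f}, {bo.upper:.4f}]"
            )
    summary = "\n".join(lines) + "\n"

    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        long_rows = []
        for m in METRICS:
            pm = matrix.per_metric[m]
            for i, a in enumerate(matrix.labels):
                for b in matrix.labels[i + 1 :]:
                    long_rows.append(
                        {"egg_a": a, "egg_b": b, "metric": m, "p_value": pm.loc[a, b]}
                    )
        for i, a in enumerate(matrix.labels):
            for b in matrix.labels[i + 1 :]:
                long_rows.append(
                    {
                        "egg_a": a,
                        "egg_b": b,
                        "metric": "harmonic_mean",
                        "p_value": matrix.combined.loc[a, b],
                    }
                )
        pd.DataFrame(long_rows).to_csv(
            os.path.join(config.output_dir, "pairwise_long.csv"), index=False
        )
        matrix.combined.to_csv(
            os.path.join(config.output_dir, "pairwise_harmonic_matrix.csv")
        )
        for m in METRICS:
            matrix.per_metric[m].to_csv(
                os.path.join(config.output_dir, f"pairwise_{m}_matrix.csv")
            )
        with open(
            os.path.join(config.output_dir, "summary.txt"), "w", encoding="utf-8"
        ) as fh:
            fh.write(summary)
    return matrix, group_tests, boots, summary


def _pooled_filtered(records, metric, policy):
    """Pool a group's sections for one metric, outlier-filtered per egg."""
    out = []
    by_egg: dict[str, list[float]] = {}
    for r in records:
        by_egg.setdefault(r.egg_id, []).append(getattr(r, metric))
    for egg_id in sorted(by_egg):
        x = np.asarray(by_egg[egg_id])
        if len(x) >= 4:
            x, _ = iqr_filter(x, policy)
        out.append(x)
    return np.concatenate(out)
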