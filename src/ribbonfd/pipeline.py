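"""End-to-end orchestration: config -> per-subject measures -> report tables.

Two input modes:

* ``volumes`` — a list of labeled NIfTI volumes (one per subject, with
  group and sex) plus an atlas mapping file; each subject is split into
  regions, and FD (per selected method) and morphometry are computed per
  region mask.
* ``simulate`` — a :class:`~ribbonfd.phantoms.CohortSpec` drives the
  folded-ribbon cohort simulator.

The report bundle contains the per-subject measure table, the per-sex
group-comparison table (one row per region × measure, mirroring the
standard mean ± sd / U / p layout, with Holm-adjusted p and an explicit
``significant`` flag at α = 0.05 on the raw p), and the FD-volume
correlation table.  All outputs are CSV plus a JSON metadata echo;
runs are deterministic given config and seed.

A subject whose mask extraction or measurement fails is flagged in the
metadata and excluded from the statistics; the run itself continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fractal import compute_fd
from .morphometry import measure_mask
from .phantoms import CohortSpec, GroupEffect, simulate_cohort
from .stats import SEXES, compare_groups, fd_volume_correlations, holm_adjust
from .volumes import default_region_atlas, extract_region_mask, load_atlas_map, load_label_volume

__all__ = ["SubjectInput", "AnalysisConfig", "ReportBundle", "run_analysis", "load_config"]

logger = logging.getLogger("ribbonfd")

COMPARISON_COLUMNS = [
    "sex", "region", "measure", "n1", "mean1", "sd1", "n2", "mean2", "sd2",
    "U", "p", "p_holm", "direction", "significant",
]


@dataclass(frozen=True)
class SubjectInput:
    subject_id: str
    group: str
    sex: str
    path: str


@dataclass(frozen=True)
class AnalysisConfig:
    mode: str = "simulate"  # "simulate" | "volumes"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    subjects: tuple[SubjectInput, ...] = ()
    atlas_path: str | None = None
    methods: tuple[str, ...] = ("BC", "MB")
    regions: tuple[str, ...] = ()  # empty = all atlas regions
    out_dir: str = "ribbonfd_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "volumes"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.methods:
            raise ValueError("select at least one FD method")
        for m in self.methods:
            if m not in ("BC", "MB"):
                raise ValueError(f"unknown FD method {m!r}; choose BC and/or MB")
        if self.mode == "volumes":
            if not self.subjects:
                raise ValueError("volumes mode requires a subject list")
            if not self.atlas_path:
                raise ValueError("volumes mode requires an atlas mapping file")


@dataclass
class ReportBundle:
    subjects: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    metadata: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        (out / "run_metadata.json").write_text(json.dumps(self.metadata, indent=2, sort_keys=True))
        return out


def _cohort_spec_from_mapping(raw: Mapping) -> CohortSpec:
    kwargs: dict = {}
    if "n_per_cell" in raw:
        kwargs["n_per_cell"] = {
            (str(g), str(s)): int(n)
            for key, n in raw["n_per_cell"].items()
            for g, s in [key.split("/") if isinstance(key, str) else key]
        }
    if "effect" in raw:
        kwargs["effect"] = {
            str(g): GroupEffect(**{k: tuple(v) for k, v in params.items()})
            for g, params in raw["effect"].items()
        }
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return CohortSpec(**kwargs)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML or JSON file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    kwargs = dict(raw)
    if "cohort" in kwargs:
        kwargs["cohort"] = _cohort_spec_from_mapping(kwargs["cohort"])
    if "subjects" in kwargs:
        kwargs["subjects"] = tuple(SubjectInput(**s) for s in kwargs["subjects"])
    for key in ("methods", "regions"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return AnalysisConfig(**kwargs)


def _measure_volumes(config: AnalysisConfig) -> tuple[pd.DataFrame, list[dict]]:
    label_map = load_atlas_map(config.atlas_path)
    regions = default_region_atlas(label_map)
    if config.regions:
        wanted = set(config.regions)
        unknown = wanted - {r.name for r in regions}
        if unknown:
            raise ValueError(
                f"unknown region names {sorted(unknown)}; "
                f"valid: {[r.name for r in regions]}"
            )
        regions = [r for r in regions if r.name in wanted]
    rows, failures = [], []
    for subj in config.subjects:
        try:
            vol = load_label_volume(subj.path)
            for region in regions:
                mask = extract_region_mask(vol, region)
                if mask.is_empty:
                    raise ValueError(f"region {region.name!r} is empty")
                row: dict[str, object] = {
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                    "sex": subj.sex,
                    "region": region.name,
                }
                for method in config.methods:
                    row[f"fd_{method.lower()}"] = compute_fd(mask, method, region.kind).D
                morpho = measure_mask(mask)
                row["volume_mm3"] = morpho.volume_mm3
                row["surface_mm2"] = morpho.surface_mm2
                rows.append(row)
        except Exception as exc:  # fail-soft: flag and continue
            logger.warning("subject %s excluded: %s", subj.subject_id, exc)
            failures.append({"subject_id": subj.subject_id, "error": str(exc)})
            rows = [r for r in rows if r["subject_id"] != subj.subject_id]
    return pd.DataFrame(rows), failures


def _comparison_tables(table: pd.DataFrame, measures: Sequence[str]) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        sub = table[table["sex"] == sex]
        if sub.empty:
            continue
        for measure in measures:
            if measure not in sub.columns:
                continue
            fam = []
            for region in sub["region"].unique():
                try:
                    cmp_ = compare_groups(table, sex, region, measure)
                except ValueError as exc:
                    logger.warning("comparison skipped (%s/%s/%s): %s", sex, region, measure, exc)
                    continue
                fam.append(
                    {
                        "sex": sex, "region": region, "measure": measure,
                        "n1": cmp_.n1, "mean1": cmp_.mean1, "sd1": cmp_.sd1,
                        "n2": cmp_.n2, "mean2": cmp_.mean2, "sd2": cmp_.sd2,
                        "U": cmp_.U, "p": cmp_.p, "direction": cmp_.direction,
                    }
                )
            if fam:
                adj = holm_adjust([r["p"] for r in fam])
                for r, ph in zip(fam, adj):
                    r["p_holm"] = float(ph)
                    r["significant"] = bool(r["p"] < 0.05)
                rows.extend(fam)
    frame = pd.DataFrame(rows)
    return frame.reindex(columns=COMPARISON_COLUMNS) if len(frame) else pd.DataFrame(
        columns=COMPARISON_COLUMNS
    )


def _correlation_table(table: pd.DataFrame, methods: Sequence[str]) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        if table[table["sex"] == sex].empty:
            continue
        for method in methods:
            fd_col = f"fd_{method.lower()}"
            if fd_col not in table.columns:
                continue
            regions = [r for r in ("LH", "RH", "WB") if r in set(table["region"])]
            results = []
            for region in regions:
                try:
                    results += fd_volume_correlations(
                        table, sex, fd_measure=fd_col, regions=[region]
                    )
                except ValueError as exc:  # e.g. zero variance in a tiny fixture cohort
                    logger.warning(
                        "correlation skipped (%s/%s/%s): %s", sex, method, region, exc
                    )
            for res in results:
                rows.append(
                    {
                        "sex": sex, "method": method,
                        "x": res.x_name, "y": res.y_name,
                        "n": res.n, "R": res.R, "p": res.p,
                        "significant": bool(res.p < 0.05),
                    }
                )
    return pd.DataFrame(
        rows, columns=["sex", "method", "x", "y", "n", "R", "p", "significant"]
    )


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full pipeline described by ``config``; see module docstring."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    failures: list[dict] = []
    if config.mode == "simulate":
        spec = config.cohort.with_seed(config.seed) if config.seed else config.cohort
        table = simulate_cohort(spec, methods=config.methods)
    else:
        table, failures = _measure_volumes(config)
    if table.empty:
        raise ValueError("no subjects could be measured; nothing to report")

    measures = [f"fd_{m.lower()}" for m in config.methods] + ["volume_mm3", "surface_mm2"]
    comparisons = _comparison_tables(table, measures)
    correlations = _correlation_table(table, config.methods)
    metadata = {
        "config": _config_to_jsonable(config),
        "excluded_subjects": failures,
        "n_subjects": int(table["subject_id"].nunique()),
        "ribbonfd_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    return ReportBundle(
        subjects=table, comparisons=comparisons,
        correlations=correlations, metadata=metadata,
    )


def _config_to_jsonable(config: AnalysisConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {
                ("/".join(k) if isinstance(k, tuple) else str(k)): convert(v)
                for k, v in obj.items()
            }
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return convert(config)
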