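"""End-to-end orchestration: data → attributes → scores → grid → priority map.

:func:`run_pipeline` wires the stages together, writes every artifact
(``attributes.csv``, ``scores.csv``, ``cells.csv``, ``priority.geojson``,
``report.json``) and returns a :class:`RunReport`-shaped dict summarizing
the run.  Reruns with the same inputs and seed produce identical artifacts;
a failure in any stage removes partial outputs and raises
:class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as kio
from .attributes import attribute_table
from .config import PRIORITY_LABELS, StudyConfig, UNOCCUPIED_LABEL
from .grid import (
    aggregate_layer,
    assign_caves,
    build_grid,
    classify_priority,
    composite_map,
    export_priority,
)
from .richness import richness_summary
from .scoring import ATTRIBUTES, score_table
from .simulate import GeneratorParams, SyntheticDataset, generate_dataset

logger = logging.getLogger("karstprior")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def percentage(count: int, total: int) -> dict:
    """Count/total as a raw ratio plus the integer percent used for display."""
    if total <= 0:
        raise ValueError("total must be positive")
    ratio = count / total
    return {"count": count, "total": total, "ratio": ratio,
            "percent": round(100 * ratio)}


def _category_counts(scores: pd.DataFrame, attribute: str) -> dict[str, int]:
    counts = scores[f"{attribute}_category"].value_counts().to_dict()
    return {label: int(counts.get(label, 0))
            for label in ("None", "Low", "Average", "High", "Extreme")}


def run_pipeline(
    config: StudyConfig | None = None,
    caves: pd.DataFrame | None = None,
    occurrences: pd.DataFrame | None = None,
    impacts: pd.DataFrame | None = None,
    simulate: GeneratorParams | bool | None = None,
    dataset: SyntheticDataset | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full prioritization and return the report dict.

    Provide either the three input tables, a :class:`SyntheticDataset`, or
    ``simulate`` (True for default parameters seeded from the config).
    """
    cfg = config or StudyConfig()
    written: list[Path] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def emit(name: str, writer) -> None:
        if out is None:
            return
        path = out / name
        writer(path)
        written.append(path)

    stage = "inputs"
    try:
        if dataset is not None:
            caves, occurrences, impacts = (
                dataset.caves, dataset.occurrences, dataset.impacts,
            )
        elif simulate:
            params = (
                simulate if isinstance(simulate, GeneratorParams)
                else GeneratorParams(seed=cfg.seed)
            )
            dataset = generate_dataset(params)
            caves, occurrences, impacts = (
                dataset.caves, dataset.occurrences, dataset.impacts,
            )
        if caves is None or occurrences is None or impacts is None:
            raise ValueError("provide caves/occurrences/impacts, a dataset, "
                             "or simulate=True")
        caves = kio.validate_caves(caves)
        occurrences = kio.validate_occurrences(occurrences, caves)
        impacts = kio.validate_impacts(impacts)
        logger.info("inputs: %d caves, %d occurrence records, %d impact sites",
                    len(caves), len(occurrences), len(impacts))
        if dataset is not None and out is not None:
            dataset.write(out)
            written += [out / n for n in
                        ("caves.csv", "occurrences.csv", "impacts.csv", "truth.json")]

        stage = "attributes"
        attrs = attribute_table(caves, occurrences, impacts, cfg.buffer_radius_m)
        emit("attributes.csv", lambda p: attrs.to_csv(p, index=False))

        stage = "scoring"
        scores, intervals = score_table(attrs, cfg)
        emit("scores.csv", lambda p: scores.to_csv(p, index=False))

        stage = "grid"
        grid = build_grid(cfg.bbox, cfg.ncols, cfg.nrows)
        mapping = assign_caves(grid, caves)
        layers = {a: aggregate_layer(scores, mapping, a) for a in ATTRIBUTES}
        pic = composite_map(layers)

        stage = "classification"
        classes, breaks = classify_priority(pic, cfg.n_classes)
        if out is not None:
            export_priority(grid, layers, pic, classes,
                            out / "priority.geojson", out / "cells.csv")
            written += [out / "priority.geojson", out / "cells.csv"]

        stage = "report"
        class_counts = {
            label: sum(1 for c in classes.values() if c == label)
            for label in (PRIORITY_LABELS if cfg.n_classes == 4
                          else sorted(set(classes.values())))
        }
        occupied = len(pic)
        report = {
            "config": cfg.to_dict(),
            "seed": cfg.seed,
            "dataset": {
                "n_caves": int(len(caves)),
                "n_species": int(occurrences["species_id"].nunique()),
                "n_troglobiont_species": int(
                    occurrences.loc[occurrences["troglobiont"], "species_id"].nunique()
                ),
                "n_impact_sites": int(len(impacts)),
            },
            "nts_intervals": {"vmin": intervals.vmin, "vmax": intervals.vmax,
                              "uppers": list(intervals.uppers)},
            "category_counts": {a: _category_counts(scores, a) for a in ATTRIBUTES},
            "occupied_cells": occupied,
            "pic_range": [int(min(pic.values())), int(max(pic.values()))],
            "priority_breaks": list(breaks.uppers),
            "priority_class_counts": class_counts,
            "priority_class_shares": {
                label: percentage(count, occupied)
                for label, count in class_counts.items()
            },
            "completeness": richness_summary(
                occurrences, n_caves=len(caves), troglobionts_only=True
            ).to_dict(),
        }
        emit("report.json",
             lambda p: Path(p).write_text(json.dumps(report, indent=2)))
        logger.info("classified %d occupied cells of %d", occupied, grid.n_cells)
        return report
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


def summarize_report(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = []
    ds = report["dataset"]
    lines.append(
        f"Dataset: {ds['n_caves']} caves, {ds['n_species']} species "
        f"({ds['n_troglobiont_species']} troglobionts), "
        f"{ds['n_impact_sites']} impact sites"
    )
    iv = report["nts_intervals"]
    lines.append(
        f"nTS equal intervals over [{iv['vmin']}, {iv['vmax']}]: "
        f"upper bounds {iv['uppers']}"
    )
    for attr, counts in report["category_counts"].items():
        shown = ", ".join(f"{k}={v}" for k, v in counts.items() if v)
        lines.append(f"{attr} categories: {shown}")
    occupied = report["occupied_cells"]
    if occupied == 0:
        lines.append("Priority map: no occupied cells")
    else:
        lines.append(
            f"Priority map: {occupied} occupied cells, "
            f"PiC range {report['pic_range'][0]}-{report['pic_range'][1]}"
        )
        for label, share in report["priority_class_shares"].items():
            lines.append(
                f"  {label}: {share['count']} cells ({share['percent']}%)"
            )
    c = report["completeness"]
    lines.append(
        f"Troglobiont completeness: S_obs={c['S_obs']}, Q1={c['Q1']}, "
        f"n={c['n']}, S_jack1={c['S_jack1']:.1f}, "
        f"completeness={c['completeness']:.3f}"
    )
    return "\n".join(lines)
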