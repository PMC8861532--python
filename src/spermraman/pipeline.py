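"""End-to-end orchestration: simulate/load -> preprocess -> features -> stats.

A :class:`RunConfig` either carries a :class:`GeneratorConfig` (synthetic
cohort) or paths to a long-table spectra CSV plus a label CSV -- exactly
one of the two.  :func:`run_pipeline` executes every stage and returns a
JSON-serializable report with per-group summaries, the Mann-Whitney tests,
ROC/AUC/cutoff per feature, histogram breakpoints, the PCA grouping with
its exclusion list, and the full effective configuration so any number in
the report can be recomputed from the report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .features import extract_features
from .preprocess import PreprocessParams, preprocess_cohort
from .spectra_io import LabelTable, read_spectrum, write_feature_table
from .stats_classify import (
    exclude_outliers,
    frequency_histogram,
    classify,
    mann_whitney,
    normality_check,
    roc_analysis,
    run_pca,
    split_groups,
)
from .synthetic_data import GeneratorConfig, calibrate_defaults, generate_cohort

logger = logging.getLogger("spermraman")

FEATURES = ("I785", "area_714_1162")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one of ``generator`` / (``spectra_path`` + ``labels_path``)
    must be set.  ``seed`` overrides the generator seed so one flag
    controls all randomness of a run.
    """

    generator: GeneratorConfig | None = None
    spectra_path: str | None = None
    labels_path: str | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    pca_window: tuple[float, float] = (650.0, 1800.0)
    outlier_alpha: float = 0.025
    features: tuple[str, ...] = FEATURES
    bin_widths: Mapping[str, float] | None = None
    run_pca_stage: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        has_gen = self.generator is not None
        has_paths = self.spectra_path is not None
        if has_gen == has_paths:
            raise ValueError(
                "exactly one of generator config and input paths must be set"
            )
        unknown = set(self.features) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")


def _load_cells(cfg: RunConfig):
    if cfg.generator is not None:
        gen = cfg.generator
        if cfg.seed is not None:
            gen = dataclasses.replace(gen, seed=cfg.seed)
        logger.info("simulating cohort: %d X + %d Y cells, seed %d",
                    gen.n_x, gen.n_y, gen.seed)
        scan_sets, labels = generate_cohort(gen)
        return scan_sets, labels, gen
    scan_sets = read_spectrum(cfg.spectra_path, dialect="long_table")
    labels = (LabelTable.from_csv(cfg.labels_path)
              if cfg.labels_path else LabelTable({}))
    return scan_sets, labels, None


def run_pipeline(cfg: RunConfig, feature_table_path: str | Path | None = None) -> dict:
    """Execute every stage and return the run report."""
    scan_sets, labels, gen = _load_cells(cfg)

    try:
        cells = preprocess_cohort(scan_sets, labels, cfg.preprocess)
    except Exception as exc:  # pragma: no cover - context decoration
        raise RuntimeError(f"preprocess stage failed: {exc}") from exc

    table = extract_features(cells)
    if feature_table_path is not None:
        write_feature_table(table, feature_table_path)

    labeled = table[table["label"].isin(["X", "Y"])]
    n_x = int((labeled["label"] == "X").sum())
    n_y = int((labeled["label"] == "Y").sum())

    report: dict[str, Any] = {
        "package_version": __version__,
        "seed": cfg.seed if cfg.seed is not None else (gen.seed if gen else None),
        "n_cells": int(len(table)),
        "n_x": n_x,
        "n_y": n_y,
        "config": _config_echo(cfg, gen),
        "features": {},
        "pca": None,
    }

    for feat in cfg.features:
        x = labeled.loc[labeled["label"] == "X", feat].to_numpy(dtype=float)
        y = labeled.loc[labeled["label"] == "Y", feat].to_numpy(dtype=float)
        entry: dict[str, Any] = {}
        if n_x and n_y:
            norm = normality_check({"X": x, "Y": y}) if min(n_x, n_y) >= 3 else None
            comp = mann_whitney(x, y, feature=feat)
            roc = roc_analysis(table, feat)
            width = (cfg.bin_widths or {}).get(feat)
            hist = frequency_histogram(table, feat, width)
            _, confusion = classify(table, roc.cutoff, feat)
            entry = {
                "mean": {"X": comp.mean_x, "Y": comp.mean_y},
                "median": {"X": comp.median_x, "Y": comp.median_y},
                "normality": norm,
                "U": comp.u,
                "p_value": comp.p_value,
                "test_method": comp.method,
                "auc": roc.auc,
                "cutoff": roc.cutoff,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "histogram_breakpoint": hist.breakpoint,
                "cdf_gap": hist.cdf_gap,
                "confusion_at_cutoff": confusion,
            }
        report["features"][feat] = entry

    if cfg.run_pca_stage and len(cells) >= 3:
        try:
            pca = run_pca(cells, cfg.pca_window)
            pca = exclude_outliers(pca, cfg.outlier_alpha, cfg.pca_window)
            i785 = dict(zip(table["cell_id"], table["I785"]))
            pca = split_groups(pca, i785)
            groups = list(pca.group_assignment.values())
            truth = {cid: lab for cid, lab in zip(table["cell_id"], table["label"])}
            agree = [
                (g == "A") == (truth[cid] == "X")
                for cid, g in pca.group_assignment.items()
                if truth.get(cid) in ("X", "Y")
            ]
            report["pca"] = {
                "retained_components": pca.retained,
                "explained_variance": [float(v) for v in
                                       pca.explained_variance[: pca.retained]],
                "excluded_ids": list(pca.excluded_ids),
                "n_group_a": groups.count("A"),
                "n_group_b": groups.count("B"),
                "label_agreement": float(np.mean(agree)) if agree else None,
            }
        except ValueError as exc:
            report["pca"] = {"error": str(exc)}

    return report


def _config_echo(cfg: RunConfig, gen: GeneratorConfig | None) -> dict:
    echo = dataclasses.asdict(cfg)
    if gen is not None:
        echo["generator"] = dataclasses.asdict(gen)
        echo["generator"]["peaks"] = [dataclasses.asdict(p) for p in gen.peaks]
    echo["preprocess"] = dataclasses.asdict(cfg.preprocess)
    if echo.get("bin_widths") is not None:
        echo["bin_widths"] = dict(echo["bin_widths"])
    return echo


def default_run_config(seed: int = 0, **overrides) -> RunConfig:
    """The package's reference run: calibrated generator, default chain."""
    gen = dataclasses.replace(calibrate_defaults(), seed=seed)
    return RunConfig(generator=gen, seed=seed, **overrides)


def render_report(report: dict, path: str | Path) -> None:
    """Write the report as JSON plus a sibling plain-text summary."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n",
                    encoding="utf-8")
    lines = [
        f"spermraman {report['package_version']} run report",
        f"cells: {report['n_cells']} (X: {report['n_x']}, Y: {report['n_y']})",
    ]
    for feat, e in report["features"].items():
        if not e:
            continue
        lines += [
            f"[{feat}] median X/Y: {e['median']['X']:.1f} / {e['median']['Y']:.1f}",
            f"[{feat}] Mann-Whitney U = {e['U']:.1f}, p = {e['p_value']:.4g} ({e['test_method']})",
            f"[{feat}] AUC = {e['auc']:.3f}, Youden cutoff = {e['cutoff']:.1f} "
            f"(sens {e['sensitivity']:.2f}, spec {e['specificity']:.2f})",
            f"[{feat}] histogram breakpoint = {e['histogram_breakpoint']:.1f}",
        ]
    if report.get("pca"):
        p = report["pca"]
        if "error" not in p:
            lines.append(
                f"PCA: {p['retained_components']} components, groups "
                f"A/B = {p['n_group_a']}/{p['n_group_b']}, "
                f"excluded {len(p['excluded_ids'])} cells"
            )
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
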