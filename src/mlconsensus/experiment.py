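"""The experiment grid: strategy x IC x scope, with comparisons and reports.

The full grid crosses two alignment strategies (built-in sorted aligner,
imported alignments), IC on/off, and the twelve scope settings (no PS,
scopes 1..10, full) — 48 configurations.  ``run_grid`` evaluates every
cell by leave-one-out cross-validation, writes flat TSV/JSON results, and
adds the pairwise Wilcoxon comparisons along each axis plus a plateau
report per (strategy, IC) track.  A manifest records the package version,
seed, configuration and a dataset fingerprint so identical inputs yield
identical result directories.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

from . import __version__
from .align import Alignment
from .evaluation import (
    LooExperiment,
    build_roc,
    detect_plateau,
    roc_curves_cross,
    run_sweep,
    wilcoxon_compare,
)
from .scoring import SCOPES, ScoringConfig, normalize_scope
from .seqio import SpeciesDataset


def _scope_str(scope) -> str:
    return "none" if scope is None else str(scope)


@dataclass
class GridConfig:
    """Which cells of the experiment grid to run."""

    strategies: tuple = ("sorted", "imported")
    ic: str = "both"  # 'on', 'off' or 'both'
    scopes: tuple = SCOPES
    n_slots: int = 20
    fpr_max: float = 0.20
    tie_rule: str = "last_best"
    min_overlap: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ic not in ("on", "off", "both"):
            raise ValueError("ic must be 'on', 'off' or 'both'")
        self.scopes = tuple(normalize_scope(s) for s in self.scopes)

    @property
    def ic_options(self) -> tuple:
        return {"on": (True,), "off": (False,), "both": (False, True)}[self.ic]

    def expand(self) -> list:
        """All configurations of the grid, in deterministic order."""
        return [
            ScoringConfig(use_ic=ic, ps_scope=scope, alignment_strategy=strategy)
            for strategy in self.strategies
            for ic in self.ic_options
            for scope in self.scopes
        ]


@dataclass
class GridResult:
    out_dir: Path
    experiments: dict  # config -> [LooExperiment]
    aucs: dict  # config -> float
    failed: dict = field(default_factory=dict)  # config label -> error message

    @property
    def ok(self) -> bool:
        return not self.failed


def _write_experiments_tsv(path: Path, experiments: list) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["tf_id", "site_id", "positive_score", "fp", "n_negatives", "fpr"])
        for e in experiments:
            writer.writerow(
                [e.tf_id, e.site_id, f"{e.positive_score:.6g}", e.fp, e.n_negatives, f"{e.fpr:.6g}"]
            )


def _write_roc_tsv(path: Path, roc) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["slot_fpr", "tpr"])
        for f, t in zip(roc.slot_fprs, roc.tpr):
            writer.writerow([f"{f:.6g}", f"{t:.6g}"])


def _dataset_fingerprint(dataset: SpeciesDataset) -> str:
    h = hashlib.sha256()
    for site_set in dataset:
        for rec in site_set:
            h.update(f"{rec.tf_id}\t{rec.site_id}\t{rec.sequence}\n".encode())
    return h.hexdigest()[:16]


def _comparison_record(label_a, label_b, exps_a, exps_b, fpr_max, n_slots) -> dict:
    res = wilcoxon_compare(exps_a, exps_b)
    roc_a = build_roc(exps_a, fpr_max=fpr_max, n_slots=n_slots)
    roc_b = build_roc(exps_b, fpr_max=fpr_max, n_slots=n_slots)
    superior = {"a": label_a, "b": label_b, None: None}[res.superior]
    crossing = roc_curves_cross(roc_a, roc_b)
    return {
        "a": label_a,
        "b": label_b,
        "n_pairs": res.n_pairs,
        "w_plus": res.w_plus,
        "w_minus": res.w_minus,
        "z": round(res.z, 4),
        "p_value": res.p_value,
        "p_bound": res.p_bound,
        "superior": superior,
        "auc_a": roc_a.auc,
        "auc_b": roc_b.auc,
        "roc_curves_cross": crossing,
        # areas alone cannot rank configurations whose ROC curves cross
        "auc_comparable": not crossing,
    }


def run_grid(
    dataset: SpeciesDataset,
    grid: GridConfig,
    out_dir: str | Path,
    *,
    imported_alignments: Mapping[str, Alignment] | None = None,
) -> GridResult:
    """Run every grid cell, write per-cell and comparison reports.

    Cells that cannot run (for example the imported strategy without a
    registered alignment) are recorded in the manifest as failed; the
    remaining cells are still written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    configs = grid.expand()
    failed: dict = {}
    experiments: dict = {}
    for strategy in grid.strategies:
        cells = [c for c in configs if c.alignment_strategy == strategy]
        try:
            experiments.update(
                run_sweep(
                    dataset,
                    cells,
                    tie_rule=grid.tie_rule,
                    imported_alignments=imported_alignments,
                    min_overlap=grid.min_overlap,
                )
            )
        except Exception as exc:  # mark the whole strategy's cells failed
            for c in cells:
                failed[c.label] = str(exc)

    aucs: dict = {}
    for config, exps in experiments.items():
        cell_dir = out_dir / config.label
        cell_dir.mkdir(exist_ok=True)
        roc = build_roc(exps, fpr_max=grid.fpr_max, n_slots=grid.n_slots)
        aucs[config] = roc.auc
        _write_experiments_tsv(cell_dir / "experiments.tsv", exps)
        _write_roc_tsv(cell_dir / "roc.tsv", roc)
        (cell_dir / "summary.json").write_text(
            json.dumps(
                {
                    "config": config.label,
                    "auc": roc.auc,
                    "n_slots": grid.n_slots,
                    "fpr_max": grid.fpr_max,
                    "n_experiments": len(exps),
                },
                indent=1,
            )
        )

    comparisons = []
    # IC on/off at fixed strategy + scope
    if grid.ic == "both":
        for strategy in grid.strategies:
            for scope in grid.scopes:
                a = ScoringConfig(False, scope, strategy)
                b = ScoringConfig(True, scope, strategy)
                if a in experiments and b in experiments:
                    comparisons.append(
                        _comparison_record(
                            a.label, b.label, experiments[a], experiments[b],
                            grid.fpr_max, grid.n_slots,
                        )
                    )
    # strategy A/B at fixed IC + scope
    if len(grid.strategies) == 2:
        s1, s2 = grid.strategies
        for ic in grid.ic_options:
            for scope in grid.scopes:
                a = ScoringConfig(ic, scope, s1)
                b = ScoringConfig(ic, scope, s2)
                if a in experiments and b in experiments:
                    comparisons.append(
                        _comparison_record(
                            a.label, b.label, experiments[a], experiments[b],
                            grid.fpr_max, grid.n_slots,
                        )
                    )
    (out_dir / "comparisons.json").write_text(json.dumps(comparisons, indent=1))

    plateaus = {}
    if len(grid.scopes) >= 3:
        for strategy in grid.strategies:
            for ic in grid.ic_options:
                track = {
                    scope: experiments[ScoringConfig(ic, scope, strategy)]
                    for scope in grid.scopes
                    if ScoringConfig(ic, scope, strategy) in experiments
                }
                if len(track) >= 3:
                    report = detect_plateau(
                        track, fpr_max=grid.fpr_max, n_slots=grid.n_slots
                    )
                    plateaus[f"{strategy}_{'ic' if ic else 'noic'}"] = {
                        "scopes": [_scope_str(s) for s in report.scopes],
                        "verdicts": report.verdicts,
                        "plateau": [_scope_str(s) for s in report.plateau],
                        "aucs": {_scope_str(s): a for s, a in report.aucs.items()},
                        "max_auc_scope": _scope_str(report.max_auc_scope),
                        "peak_in_plateau": report.peak_in_plateau,
                    }
        (out_dir / "plateaus.json").write_text(json.dumps(plateaus, indent=1))

    manifest = {
        "package_version": __version__,
        "seed": grid.seed,
        "grid": {**asdict(grid), "scopes": [_scope_str(s) for s in grid.scopes]},
        "dataset": {
            "species": dataset.species,
            "n_tfs": len(dataset),
            "n_sites": dataset.n_sites,
            "fingerprint": _dataset_fingerprint(dataset),
        },
        "cells": {c.label: {"auc": aucs[c]} for c in configs if c in aucs},
        "failed_cells": failed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return GridResult(out_dir=out_dir, experiments=experiments, aucs=aucs, failed=failed)
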