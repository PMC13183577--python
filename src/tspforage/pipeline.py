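"""End-to-end orchestration: inputs -> measures -> statistics -> reports.

Bundles the full analysis behind two entry points: :func:`run_behavior`
(trial logs to behavioural measures, strategy aggregation, factorial
ANOVAs, transition maps and a compact significance summary) and
:func:`run_microglia` (cell masks or descriptor tables to morphotype
counts, percent hypertrophic, and per-region 2x2 ANOVAs).  Inputs are
either files or a simulated cohort; reruns with the same configuration and
seed reproduce every output byte for byte.

Machine-readable outputs always keep raw p-values; the human-readable
summary renders non-significant terms as "ns".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .geometry import (
    bundled_configurations,
    distance_matrix,
    load_configurations,
)
from .measures import (
    attach_tracks,
    compute_measures,
    measures_table,
    parse_event_log,
    read_track_table,
    transition_maps,
)
from .morphology import (
    cells_from_descriptor_table,
    cells_table,
    summarize_regions,
)
from .routes import OptimalRouteSet, RouteMode, optimal_route
from .simulate import (
    CohortDesign,
    default_design,
    simulate_cohort,
    simulate_microglia,
)
from .stats import (
    AnovaResult,
    DesignError,
    aggregate_by_strategy,
    between_anova_2x2,
    mixed_model_anova,
    rm_anova_2x2x3,
)

__all__ = ["RunConfig", "BehaviorReport", "MicrogliaReport",
           "run_behavior", "run_microglia"]

BEHAVIOR_MEASURES = [
    "revisits_per_target",
    "pao_pct",
    "skips",
    "span",
    "rate",
    "prop_opt",
    "prop_dist_opt",
    "velocity",
]

ANOVA_TERMS = [
    "strain", "sex", "strain*sex",
    "strategy", "strain*strategy", "sex*strategy", "strain*sex*strategy",
]


@dataclass
class RunConfig:
    """Inputs, method options and output location for one pipeline run."""

    # file inputs (None = simulate or use bundled geometry)
    configs_path: str | None = None
    events_path: str | None = None
    tracks_path: str | None = None
    descriptors_path: str | None = None
    # simulation
    simulate: bool = False
    design: CohortDesign | None = None
    n_per_cell: int = 9
    microglia_cells_per_rat: int = 30
    microglia_noise: float = 0.0
    # method options
    route_mode: RouteMode = RouteMode.OPEN
    anchor: int | None = None
    tol: float | None = None
    circ_max: float = 1.03
    min_processes: int = 3
    alpha: float = 0.05
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    def provenance(self) -> dict:
        return {
            "package_version": _pkg_version,
            "seed": self.seed,
            "route_mode": self.route_mode.value,
            "anchor": self.anchor,
            "circ_max": self.circ_max,
            "min_processes": self.min_processes,
            "alpha": self.alpha,
        }


def _p_label(p: float, alpha: float) -> str:
    if not np.isfinite(p):
        return "na"
    return f"p = {p:.4g}" if p < alpha else "ns"


def _anova_for_measure(table: pd.DataFrame, measure: str) -> AnovaResult:
    """Repeated-measures ANOVA, falling back to the mixed model on
    incomplete data."""
    try:
        return rm_anova_2x2x3(table, measure)
    except DesignError:
        return mixed_model_anova(table, measure)


@dataclass
class BehaviorReport:
    measures: pd.DataFrame
    strategy_table: pd.DataFrame
    anovas: dict[str, AnovaResult]
    transition_maps: pd.DataFrame
    summary: pd.DataFrame          # Table-1-shaped, human-readable
    provenance: dict
    ground_truth: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.measures.to_csv(out / "trial_measures.csv", index=False)
        self.strategy_table.to_csv(out / "strategy_table.csv", index=False)
        self.transition_maps.to_csv(out / "transition_maps.csv", index=False)
        self.summary.to_csv(out / "behavior_summary.csv", index=False)
        if self.ground_truth is not None:
            self.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        doc = {
            "provenance": self.provenance,
            "anovas": {
                meas: {
                    "method": res.method,
                    "terms": [
                        {
                            "term": t.term, "df_num": t.df_num,
                            "df_den": t.df_den, "F": t.F, "p": t.p,
                            "p_gg": t.p_gg,
                        }
                        for t in res.terms
                    ],
                    "cell_means": res.cell_means,
                }
                for meas, res in self.anovas.items()
            },
        }
        with open(out / "behavior_anova.json", "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


def run_behavior(cfg: RunConfig) -> BehaviorReport:
    """Run the behavioural pipeline from files or a simulated cohort."""
    if cfg.configs_path:
        configs = load_configurations(cfg.configs_path)
    else:
        configs = bundled_configurations()
    by_id = {c.config_id: c for c in configs}

    ground_truth = None
    if cfg.simulate:
        design = cfg.design or default_design(configs, n_per_cell=cfg.n_per_cell)
        cohort = simulate_cohort(design, cfg.seed)
        logs = cohort.logs
        ground_truth = cohort.ground_truth
    else:
        if not cfg.events_path:
            raise ValueError("either events_path or simulate=True is required")
        logs = parse_event_log(cfg.events_path)
        if cfg.tracks_path:
            logs = attach_tracks(logs, read_track_table(cfg.tracks_path))

    missing = {lg.config_id for lg in logs} - set(by_id)
    if missing:
        raise ValueError(f"event log references unknown configs {sorted(missing)}")

    opts: dict[int, OptimalRouteSet] = {
        cid: optimal_route(
            distance_matrix(by_id[cid]), cfg.route_mode, cfg.anchor, cfg.tol
        )
        for cid in sorted({lg.config_id for lg in logs})
    }
    ms = measures_table(
        [compute_measures(lg, by_id[lg.config_id], opts[lg.config_id])
         for lg in logs]
    )
    strategy_table = aggregate_by_strategy(ms, by_id)

    anovas: dict[str, AnovaResult] = {}
    for meas in BEHAVIOR_MEASURES:
        if meas not in strategy_table.columns:
            continue
        col = strategy_table[meas]
        if col.dropna().empty or col.dropna().nunique() == 1:
            continue  # e.g. velocity without tracks
        anovas[meas] = _anova_for_measure(strategy_table, meas)

    tmaps = transition_maps(logs, by_id)
    tm_rows = [
        {
            "strain": tm.strain, "sex": tm.sex, "config_id": tm.config_id,
            "from_target": tm.target_ids[i], "to_target": tm.target_ids[j],
            "p": tm.p[i, j],
        }
        for tm in tmaps
        for i in range(len(tm.target_ids))
        for j in range(len(tm.target_ids))
        if tm.p[i, j] > 0
    ]
    tm_df = pd.DataFrame(
        tm_rows,
        columns=["strain", "sex", "config_id", "from_target", "to_target", "p"],
    )

    summary_rows = []
    for meas, res in anovas.items():
        row = {"measure": meas, "method": res.method}
        for term in ANOVA_TERMS:
            try:
                row[term] = _p_label(res[term].p, cfg.alpha)
            except KeyError:
                row[term] = "na"
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    report = BehaviorReport(
        measures=ms,
        strategy_table=strategy_table,
        anovas=anovas,
        transition_maps=tm_df,
        summary=summary,
        provenance=cfg.provenance(),
        ground_truth=ground_truth,
    )
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report


@dataclass
class MicrogliaReport:
    cells: pd.DataFrame
    regions: pd.DataFrame
    anovas: dict[str, AnovaResult | None]   # None = not testable
    summary: pd.DataFrame                   # Table-2-shaped
    provenance: dict
    ground_truth: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False)
        self.regions.to_csv(out / "region_summaries.csv", index=False)
        self.summary.to_csv(out / "microglia_summary.csv", index=False)
        if self.ground_truth is not None:
            self.ground_truth.to_csv(out / "microglia_truth.csv", index=False)
        doc = {
            "provenance": self.provenance,
            "anovas": {
                region: (
                    None if res is None else {
                        "method": res.method,
                        "terms": [
                            {
                                "term": t.term, "df_num": t.df_num,
                                "df_den": t.df_den, "F": t.F, "p": t.p,
                            }
                            for t in res.terms
                        ],
                        "cell_means": res.cell_means,
                    }
                )
                for region, res in self.anovas.items()
            },
        }
        with open(out / "microglia_anova.json", "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


def run_microglia(cfg: RunConfig) -> MicrogliaReport:
    """Run the histology pipeline from descriptor tables or simulation."""
    ground_truth = None
    if cfg.simulate:
        design = cfg.design or default_design(
            bundled_configurations(), n_per_cell=cfg.n_per_cell
        )
        rats = {
            cell: [f"{cell[0]}_{cell[1]}_{i + 1:02d}" for i in range(n)]
            for cell, n in design.n_per_cell.items()
        }
        masks, meta = simulate_microglia(
            design.microglia_mixtures, rats,
            n_cells=cfg.microglia_cells_per_rat,
            noise=cfg.microglia_noise, seed=cfg.seed,
        )
        meta = meta.assign(
            label=np.arange(1, len(meta) + 1),
            pixel_size_um=1.0,
        )
        records = []
        from .morphology import (
            CellRecord, classify_cell, count_processes, shape_descriptors,
        )
        for mask, row in zip(masks, meta.itertuples()):
            area, perim, circ = shape_descriptors(mask, 1.0)
            n_proc = count_processes(mask)
            records.append(
                CellRecord(
                    cell_id=row.cell_id, rat_id=row.rat_id, strain=row.strain,
                    sex=row.sex, region=row.region, area=area, perimeter=perim,
                    circularity=circ, n_processes=n_proc,
                    morph_class=classify_cell(
                        circ, n_proc, cfg.circ_max, cfg.min_processes
                    ),
                )
            )
        ground_truth = meta[["cell_id", "rat_id", "strain", "sex", "region",
                             "true_class"]]
    elif cfg.descriptors_path:
        records = cells_from_descriptor_table(
            pd.read_csv(cfg.descriptors_path),
            circ_max=cfg.circ_max, min_processes=cfg.min_processes,
        )
    else:
        raise ValueError("either descriptors_path or simulate=True is required")

    cells = cells_table(records)
    regions = summarize_regions(records)

    anovas: dict[str, AnovaResult | None] = {}
    summary_rows = []
    for region, sub in regions.groupby("region", sort=True):
        cell_n = sub.groupby(["strain", "sex"])["rat_id"].nunique()
        testable = len(cell_n) == 4 and (cell_n >= 2).all()
        if testable:
            res = between_anova_2x2(sub, "pct_hypertrophic")
        else:
            res = None
        anovas[str(region)] = res
        row = {"region": region,
               "mean_pct_hypertrophic": float(sub["pct_hypertrophic"].mean())}
        for term in ("strain", "sex", "strain*sex"):
            row[term] = (
                "not testable" if res is None else _p_label(res[term].p, cfg.alpha)
            )
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    report = MicrogliaReport(
        cells=cells,
        regions=regions,
        anovas=anovas,
        summary=summary,
        provenance=cfg.provenance(),
        ground_truth=ground_truth,
    )
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report
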