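"""End-to-end orchestration: simulate/load -> quantify -> classify -> network -> compare.

One :class:`RunConfig` drives the whole analysis; every stage writes its
table under the output directory and the run ends with a machine-readable
``report.json`` summarizing group sizes, QC exclusions and the shared /
exclusive edge counts per compartment.  The report carries the config and
seed so a run is reproducible; rerunning with the same config and seed
produces an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import group_compare, ihc_ratio, netdiff, rppa_quant, synthetic_data

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration, caught before any computation."""


@dataclass
class RunConfig:
    out_dir: str = "stromanet_run"
    # either input paths ...
    spots_path: str | None = None
    ihc_path: str | None = None
    # ... or a synthetic cohort spec
    simulate: synthetic_data.CohortSpec | None = None
    # thresholds
    rho_min: float = netdiff.DEFAULT_RHO_MIN
    p_max: float = netdiff.DEFAULT_P_MAX
    alpha: float = group_compare.DEFAULT_ALPHA
    qc_alpha: float = rppa_quant.DEFAULT_QC_ALPHA
    slope_tolerance: float = rppa_quant.DEFAULT_SLOPE_TOLERANCE
    abs_rho: bool = False
    seed: int = 0
    network_format: str = "gexf"
    contrasts: tuple[str, ...] = (
        "compartment-within-group",
        "group-within-compartment",
    )

    def validate(self) -> None:
        if not -1.0 <= self.rho_min <= 1.0:
            raise ConfigError(f"rho_min must be in [-1, 1], got {self.rho_min}")
        for name in ("p_max", "alpha", "qc_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.slope_tolerance < 0:
            raise ConfigError("slope_tolerance must be >= 0")
        if self.network_format not in ("gexf", "graphml"):
            raise ConfigError(f"unknown network format {self.network_format!r}")
        if self.simulate is None and (self.spots_path is None or self.ihc_path is None):
            raise ConfigError("provide spots_path and ihc_path, or a simulate spec")


def config_from_yaml(path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "contrasts"})
    if "contrasts" in raw:
        cfg.contrasts = tuple(raw["contrasts"])
    if sim is not None:
        cfg.simulate = synthetic_data.spec_from_dict(sim)
    return cfg


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    # the report describes the analysis, not the filesystem: two runs of the
    # same config+seed hash identically regardless of where they were written
    d.pop("out_dir", None)
    if config.simulate is not None:
        d["simulate"] = dataclasses.asdict(config.simulate)
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("stromanet")
    root.addHandler(log_handler)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    # --- inputs ------------------------------------------------------------
    if config.simulate is not None:
        spec = dataclasses.replace(config.simulate, seed=config.seed)
        cohort = synthetic_data.generate_cohort(spec)
        cohort.write(out)
        spots = cohort.spots
        ihc_cases = [
            ihc_ratio.IHCCase(str(r.case_id), int(r.epithelium_score), int(r.stroma_score))
            for r in cohort.ihc.itertuples()
        ]
        logger.info("simulated cohort with seed %d", config.seed)
    else:
        spots = rppa_quant.read_spot_table(config.spots_path)
        ihc_cases = ihc_ratio.read_score_table(config.ihc_path)

    # --- quantify ----------------------------------------------------------
    quant = rppa_quant.quantify(
        spots,
        qc_alpha=config.qc_alpha,
        slope_tolerance=config.slope_tolerance,
    )
    rppa_quant.write_reduced_table(out / "reduced.csv", quant)
    qc_json = [dataclasses.asdict(r) for r in quant.qc_reports]
    (out / "qc_report.json").write_text(json.dumps(qc_json, indent=1, sort_keys=True))

    # --- classify ----------------------------------------------------------
    grouping = ihc_ratio.classify_cohort(ihc_cases)
    ihc_ratio.write_grouping(out / "groups.csv", grouping)
    labels = grouping.labels

    # --- networks ----------------------------------------------------------
    excluded = set(quant.excluded_cases)
    matrices = netdiff.endpoint_matrices(quant.wide, labels, exclude_cases=excluded)
    edge_sets = {
        key: netdiff.significant_edges(
            mat, rho_min=config.rho_min, p_max=config.p_max, abs_rho=config.abs_rho
        )
        for key, mat in matrices.items()
    }
    compartments = sorted({comp for _, comp in edge_sets})
    network_counts: dict[str, dict] = {}
    for comp in compartments:
        es_high = edge_sets[("high", comp)]
        es_low = edge_sets[("low", comp)]
        shared, excl_high, excl_low = netdiff.shared_and_exclusive(es_high, es_low)
        for es, name in ((es_high, "high"), (es_low, "low")):
            netdiff.edge_table(es, shared).to_csv(
                out / f"edges_{name}_{comp}.csv", index=False
            )
        subgroup_counts = {}
        for excl in (excl_high, excl_low):
            net = netdiff.build_network(excl)
            netdiff.detect_subgroups(net, seed=config.seed)
            netdiff.export_network(
                net,
                out / f"network_{excl.group}_{comp}.{config.network_format}",
                format=config.network_format,
            )
            subgroup_counts[excl.group] = net.n_subgroups
        network_counts[comp] = {
            "pairs_evaluated_high": es_high.n_pairs_evaluated,
            "pairs_evaluated_low": es_low.n_pairs_evaluated,
            "significant_high": len(es_high),
            "significant_low": len(es_low),
            "shared": len(shared),
            "exclusive_high": len(excl_high),
            "exclusive_low": len(excl_low),
            "union": len(es_high.pairs | es_low.pairs),
            "n_subgroups": subgroup_counts,
        }

    # --- comparisons -------------------------------------------------------
    comparison_frames = []
    for contrast in config.contrasts:
        t = group_compare.compare_all(
            quant.wide, labels, contrast, alpha=config.alpha, exclude_cases=excluded
        )
        t.insert(0, "contrast", contrast)
        comparison_frames.append(t)
    comparisons = (
        pd.concat(comparison_frames, ignore_index=True)
        if comparison_frames
        else pd.DataFrame()
    )
    comparisons.to_csv(out / "comparisons.csv", index=False)
    group_compare.boxplot_table(quant.wide, labels, exclude_cases=excluded).to_csv(
        out / "boxplots.csv", index=False
    )

    # --- report ------------------------------------------------------------
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "group_sizes": {"high": grouping.n_high, "low": grouping.n_low},
        "qc_excluded_cases": sorted(excluded),
        "cases_in_network_analysis": {
            group: len(matrices[(group, compartments[0])].cases)
            for group in ("high", "low")
        },
        "networks": network_counts,
        "n_significant_comparisons": int(comparisons["significant"].sum())
        if len(comparisons)
        else 0,
        "detection_floor": quant.detection_floor,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
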