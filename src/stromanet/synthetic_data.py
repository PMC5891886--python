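"""Seeded synthetic RPPA + IHC cohorts with planted correlation structure.

The generator emulates the study design the pipeline expects: 19 colorectal
cases x 2 microdissected compartments x 30 signaling endpoints, each lysate
printed as a two-fold four-point dilution series, with per-case loading
(ssDNA) variation, a negative-control noise floor, one case generated at the
floor so that it fails QC, and an IHC score-pair distribution that classifies
into 10 high- and 9 low-ratio cases.

Endpoint abundances are drawn from a Gaussian copula whose correlation matrix
embeds *planted blocks*: groups of endpoints correlated at a target Spearman
rho, either in both ratio groups (shared) or in exactly one (exclusive), per
compartment.  Latent Gaussians are mapped to log-normal intensities
(positive, right-skewed, like scanner readouts); the target Spearman rho is
converted to the latent Pearson correlation via r = 2*sin(pi*rho/6), exact
for Gaussian copulas.  ssDNA spots are the per-case loading factor times
multiplicative noise, so the ssDNA-normalized endpoint signal follows the
1/dilution law the reducer assumes.

Every planted pair is recorded in a ground-truth ledger so that recovery can
be scored without re-deriving the design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .ihc_ratio import HIGH, LOW, REFERENCE_COHORT_PAIRS, expression_ratio_class
from .rppa_quant import (
    COMPARTMENTS,
    NEGATIVE_CONTROL,
    SPOT_COLUMNS,
    SSDNA,
)

SCOPES = ("shared", "high_only", "low_only")


class CohortSpecError(ValueError):
    """Invalid cohort specification (overlapping blocks, bad rho, ...)."""


@dataclass(frozen=True)
class CorrelationBlock:
    """A set of endpoints planted at a common pairwise target Spearman rho."""

    endpoints: tuple[str, ...]
    rho: float
    scope: str  # shared | high_only | low_only
    compartment: str

    def pairs(self) -> list[tuple[str, str]]:
        eps = sorted(self.endpoints)
        return [(a, b) for i, a in enumerate(eps) for b in eps[i + 1 :]]


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    n_cases_high: int = 10
    n_cases_low: int = 9
    n_endpoints: int = 30
    dilution_steps: int = 4
    correlation_blocks: tuple[CorrelationBlock, ...] = ()
    noise_sd_log: float = 0.15
    latent_sd_log: float = 1.0
    ssdna_loading_range: tuple[float, float] = (0.7, 1.3)
    negative_control_mean_sd: tuple[float, float] = (50.0, 10.0)
    base_intensity_range: tuple[float, float] = (1000.0, 5000.0)
    ssdna_base_intensity: float = 500.0
    ihc_pair_distribution: tuple[tuple[int, int], ...] = REFERENCE_COHORT_PAIRS
    qc_fail_cases: tuple[str, ...] = ()
    seed: int = 0

    @property
    def endpoints(self) -> list[str]:
        return [f"P{i:02d}" for i in range(1, self.n_endpoints + 1)]

    @property
    def case_ids(self) -> list[str]:
        n = self.n_cases_high + self.n_cases_low
        return [f"C{i:02d}" for i in range(1, n + 1)]


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground-truth ledger."""

    spots: pd.DataFrame
    ihc: pd.DataFrame
    truth: dict
    spec: CohortSpec

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spots.to_csv(out / "spots.csv", index=False)
        self.ihc.to_csv(out / "ihc.csv", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))


def validate_spec(spec: CohortSpec) -> None:
    if spec.n_cases_high <= 0 or spec.n_cases_low <= 0 or spec.n_endpoints <= 0:
        raise CohortSpecError("case and endpoint counts must be positive")
    if spec.noise_sd_log <= 0 or spec.latent_sd_log <= 0:
        raise CohortSpecError("log-scale noise SDs must be positive")
    known = set(spec.endpoints)
    seen: dict[tuple[str, str], set[str]] = {}
    for blk in spec.correlation_blocks:
        if not 0 < blk.rho < 1:
            raise CohortSpecError(f"block rho must be in (0,1), got {blk.rho}")
        if blk.scope not in SCOPES:
            raise CohortSpecError(f"unknown block scope {blk.scope!r}")
        if blk.compartment not in COMPARTMENTS:
            raise CohortSpecError(f"unknown block compartment {blk.compartment!r}")
        unknown = set(blk.endpoints) - known
        if unknown:
            raise CohortSpecError(f"block references unknown endpoints {sorted(unknown)}")
        key = (blk.scope, blk.compartment)
        overlap = seen.setdefault(key, set()) & set(blk.endpoints)
        if overlap:
            raise CohortSpecError(
                f"blocks overlap within scope {key}: {sorted(overlap)}"
            )
        seen[key] |= set(blk.endpoints)
    n_high = sum(
        1 for e, s in spec.ihc_pair_distribution if expression_ratio_class(e, s) == HIGH
    )
    n = len(spec.ihc_pair_distribution)
    if n != spec.n_cases_high + spec.n_cases_low or n_high != spec.n_cases_high:
        raise CohortSpecError(
            "ihc_pair_distribution is inconsistent with the group sizes: "
            f"{n_high} high pairs for n_cases_high={spec.n_cases_high}, "
            f"{n} pairs for {spec.n_cases_high + spec.n_cases_low} cases"
        )
    unknown_qc = set(spec.qc_fail_cases) - set(spec.case_ids)
    if unknown_qc:
        raise CohortSpecError(f"qc_fail_cases not in cohort: {sorted(unknown_qc)}")
    # positive-definiteness of every implied correlation matrix
    for group in (HIGH, LOW):
        for comp in COMPARTMENTS:
            corr = _correlation_matrix(spec, group, comp)
            try:
                np.linalg.cholesky(corr)
            except np.linalg.LinAlgError as exc:
                raise CohortSpecError(
                    f"implied correlation matrix for {group}/{comp} is not "
                    "positive definite (blocks overlap or rho too high)"
                ) from exc


def _latent_pearson(rho_spearman: float) -> float:
    return float(2.0 * np.sin(np.pi * rho_spearman / 6.0))


def _correlation_matrix(spec: CohortSpec, group: str, compartment: str) -> np.ndarray:
    idx = {e: i for i, e in enumerate(spec.endpoints)}
    corr = np.eye(spec.n_endpoints)
    wanted = {"shared", f"{group}_only"}
    for blk in spec.correlation_blocks:
        if blk.compartment != compartment or blk.scope not in wanted:
            continue
        r = _latent_pearson(blk.rho)
        for a, b in blk.pairs():
            i, j = idx[a], idx[b]
            corr[i, j] = corr[j, i] = r
    return corr


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The default study-like cohort: 10 + 9 cases, 30 endpoints, one
    QC-failing case (a high-ratio case, so 9 + 9 enter network analysis),
    and shared/exclusive 4-endpoint blocks at target Spearman 0.9 in each
    compartment."""
    blocks = []
    layout = [
        ("epithelium", "shared", (1, 2, 3, 4)),
        ("epithelium", "high_only", (5, 6, 7, 8)),
        ("epithelium", "low_only", (9, 10, 11, 12)),
        ("stroma", "shared", (13, 14, 15, 16)),
        ("stroma", "high_only", (17, 18, 19, 20)),
        ("stroma", "low_only", (21, 22, 23, 24)),
    ]
    for comp, scope, ids in layout:
        blocks.append(
            CorrelationBlock(
                endpoints=tuple(f"P{i:02d}" for i in ids),
                rho=0.9,
                scope=scope,
                compartment=comp,
            )
        )
    return CohortSpec(
        correlation_blocks=tuple(blocks),
        qc_fail_cases=("C10",),
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full synthetic dataset for a spec, deterministically.

    Returns spot and IHC tables in the same dialects the real pipeline
    consumes, plus a ground-truth ledger of planted pairs, group assignment
    and forced QC failures.
    """
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    endpoints = spec.endpoints
    case_ids = spec.case_ids
    m = spec.n_endpoints
    steps = list(range(spec.dilution_steps))
    nc_mean, nc_sd = spec.negative_control_mean_sd

    # group assignment follows the IHC pair classification, in order
    pair_groups = [expression_ratio_class(e, s) for e, s in spec.ihc_pair_distribution]
    group_of = dict(zip(case_ids, pair_groups))

    # per-endpoint base intensity (log-uniform), shared across the cohort
    lo, hi = spec.base_intensity_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))
    # per case x compartment loading factor
    loading = {
        (c, comp): rng.uniform(*spec.ssdna_loading_range)
        for c in case_ids
        for comp in COMPARTMENTS
    }

    # latent abundances per group x compartment from the Gaussian copula
    log_abundance: dict[tuple[str, str], np.ndarray] = {}
    for group in (HIGH, LOW):
        members = [c for c in case_ids if group_of[c] == group]
        for comp in COMPARTMENTS:
            corr = _correlation_matrix(spec, group, comp)
            L = np.linalg.cholesky(corr)
            z = rng.standard_normal((len(members), m)) @ L.T
            ab = np.log(base)[None, :] + spec.latent_sd_log * z
            for k, c in enumerate(members):
                log_abundance[(c, comp)] = ab[k]

    qc_fail = set(spec.qc_fail_cases)
    rows: list[tuple] = []
    for c in case_ids:
        for comp in COMPARTMENTS:
            lf = loading[(c, comp)]
            la = log_abundance[(c, comp)]
            for k in steps:
                if c in qc_fail:
                    # spots at the negative-control noise floor
                    vals = np.clip(rng.normal(nc_mean, nc_sd, size=m), 0.1, None)
                else:
                    noise = rng.normal(0.0, spec.noise_sd_log, size=m)
                    vals = lf * np.exp(la) / 2.0**k * np.exp(noise)
                for e, v in zip(endpoints, vals):
                    rows.append((c, comp, e, k, 0, float(v)))
                ss = lf * spec.ssdna_base_intensity * np.exp(
                    rng.normal(0.0, spec.noise_sd_log)
                )
                rows.append((c, comp, SSDNA, k, 0, float(ss)))
                ncv = float(np.clip(rng.normal(nc_mean, nc_sd), 0.1, None))
                rows.append((c, comp, NEGATIVE_CONTROL, k, 0, ncv))

    spots = pd.DataFrame(rows, columns=list(SPOT_COLUMNS))
    spots = spots.sort_values(list(SPOT_COLUMNS[:5]), kind="mergesort").reset_index(
        drop=True
    )

    ihc = pd.DataFrame(
        {
            "case_id": case_ids,
            "epithelium_score": [e for e, _ in spec.ihc_pair_distribution],
            "stroma_score": [s for _, s in spec.ihc_pair_distribution],
        }
    )

    truth = {
        "seed": spec.seed,
        "group_assignment": group_of,
        "qc_fail_cases": sorted(qc_fail),
        "planted_pairs": [
            {
                "endpoint_a": a,
                "endpoint_b": b,
                "compartment": blk.compartment,
                "scope": blk.scope,
                "rho": blk.rho,
            }
            for blk in spec.correlation_blocks
            for a, b in blk.pairs()
        ],
        "planted_blocks": [
            {
                "endpoints": sorted(blk.endpoints),
                "compartment": blk.compartment,
                "scope": blk.scope,
                "rho": blk.rho,
            }
            for blk in spec.correlation_blocks
        ],
    }
    return SyntheticCohort(spots=spots, ihc=ihc, truth=truth, spec=spec)


def spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    blocks = tuple(
        CorrelationBlock(
            endpoints=tuple(b["endpoints"]),
            rho=float(b["rho"]),
            scope=b["scope"],
            compartment=b["compartment"],
        )
        for b in d.pop("correlation_blocks", [])
    )
    if "ihc_pair_distribution" in d:
        d["ihc_pair_distribution"] = tuple(
            (int(e), int(s)) for e, s in d["ihc_pair_distribution"]
        )
    for key in ("ssdna_loading_range", "negative_control_mean_sd", "base_intensity_range"):
        if key in d:
            d[key] = tuple(float(v) for v in d[key])
    if "qc_fail_cases" in d:
        d["qc_fail_cases"] = tuple(d["qc_fail_cases"])
    return CohortSpec(correlation_blocks=blocks, **d)
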