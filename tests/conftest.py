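import numpy as np
import pytest
from hypothesis import settings

from stromanet import ihc_ratio, netdiff, rppa_quant, synthetic_data

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One generated study-like cohort (seed 1) with its quantification."""
    spec = synthetic_data.default_cohort_spec(seed=1)
    cohort = synthetic_data.generate_cohort(spec)
    quant = rppa_quant.quantify(cohort.spots)
    grouping = ihc_ratio.classify_cohort(
        [
            ihc_ratio.IHCCase(str(r.case_id), int(r.epithelium_score), int(r.stroma_score))
            for r in cohort.ihc.itertuples()
        ]
    )
    return cohort, quant, grouping


def _score_recovery(n_seeds: int = 100) -> dict:
    """Run the full pipeline on n_seeds cohorts and score planted-structure
    recovery: how planted exclusive/shared pairs land in the partitioned edge
    sets, and how often unplanted pairs turn up significant."""
    ex_hits = []  # per planted exclusive pair: 1 if in the correct exclusive set
    ex_detected = 0  # planted exclusive pairs significant in >= 1 group
    ex_correct = 0  # ... of which landed in the correct exclusive set
    sh_hits = []
    null_fracs = []
    partition_ok = True
    for seed in range(n_seeds):
        spec = synthetic_data.default_cohort_spec(seed=seed)
        cohort = synthetic_data.generate_cohort(spec)
        quant = rppa_quant.quantify(cohort.spots)
        labels = cohort.truth["group_assignment"]
        mats = netdiff.endpoint_matrices(
            quant.wide, labels, exclude_cases=set(quant.excluded_cases)
        )
        edge_sets = {k: netdiff.significant_edges(m) for k, m in mats.items()}
        planted = {
            (p["endpoint_a"], p["endpoint_b"], p["compartment"]): p["scope"]
            for p in cohort.truth["planted_pairs"]
        }
        for comp in ("epithelium", "stroma"):
            es_h, es_l = edge_sets[("high", comp)], edge_sets[("low", comp)]
            shared, ex_h, ex_l = netdiff.shared_and_exclusive(es_h, es_l)
            union = es_h.pairs | es_l.pairs
            if (
                len(shared) + len(ex_h) + len(ex_l) != len(union)
                or shared & ex_h.pairs
                or shared & ex_l.pairs
                or ex_h.pairs & ex_l.pairs
            ):
                partition_ok = False
            planted_comp = {
                (a, b): scope for (a, b, c), scope in planted.items() if c == comp
            }
            n_null_slots = 435 - len(planted_comp)
            n_null_hits = sum(1 for p in union if p not in planted_comp)
            null_fracs.append(n_null_hits / n_null_slots)
            for pair, scope in planted_comp.items():
                if scope == "shared":
                    sh_hits.append(pair in shared)
                else:
                    correct = ex_h.pairs if scope == "high_only" else ex_l.pairs
                    ex_hits.append(pair in correct)
                    if pair in union:
                        ex_detected += 1
                        ex_correct += pair in correct
    return {
        "n_seeds": n_seeds,
        "exclusive_pair_recovery": float(np.mean(ex_hits)),
        "exclusive_assignment_correct": ex_correct / ex_detected,
        "shared_pair_recovery": float(np.mean(sh_hits)),
        "false_planting_fraction": float(np.mean(null_fracs)),
        "partition_identity_ok": partition_ok,
    }


@pytest.fixture(scope="session")
def recovery_stats():
    return _score_recovery(n_seeds=100)
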