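"""End-to-end replication pipeline and run manifests.

``replicate_run`` chains the generator, the (optional) allocation
simulator and the inference layer into one reproducible run: synthetic
cohort -> receipt outcomes -> descriptive table -> crude and adjusted
logistic models -> unadjusted odds ratio, writing CSV/JSON artifacts
plus a manifest (seed, config hash, package version) sufficient to
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import Optional

from . import __version__
from .allocation import (
    AllocationConfig,
    apply_allocation,
    default_allocation_config,
    receipt_table,
    simulate_allocation,
)
from .cohort import (
    GeneratorConfig,
    generate_cohort,
    summarize_cohort,
    write_cohort_csv,
)
from .inference import crude_and_adjusted, group_mean_tests, odds_ratio

__all__ = ["config_hash", "replicate_run", "analyze_cohort"]


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, datetime.date):
        return obj.isoformat()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def config_hash(config) -> str:
    payload = json.dumps(_jsonify(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def analyze_cohort(cohort) -> dict:
    """Descriptive + inferential results for one cohort with outcomes."""
    cands = [r for r in cohort if r.candidate]
    summary = summarize_cohort(cohort)
    cbs = [r.cbs for r in cands]
    medicare = [int(r.profile.insurance.value == "medicare") for r in cands]
    received = [int(r.received_pbt) for r in cands]
    models = crude_and_adjusted(cbs, medicare, received)
    table = receipt_table(None, cohort, "medicare")
    unadj = odds_ratio(table)

    # stratum mean-score comparisons mirroring the descriptive table
    pvals = {}
    strata = {
        "proton_therapy": [[c for c, r in zip(cbs, received) if r],
                           [c for c, r in zip(cbs, received) if not r]],
        "insurance": [[c for c, m in zip(cbs, medicare) if m],
                      [c for c, m in zip(cbs, medicare) if not m]],
    }
    for name, groups in strata.items():
        if all(len(g) >= 2 for g in groups):
            stat, p, test = group_mean_tests(groups)
            pvals[name] = {"statistic": stat, "p": p, "test": test}

    return {
        "n_evaluated": len(cohort),
        "n_candidates": len(cands),
        "n_received": sum(received),
        "candidate_fraction_pct": round(100 * len(cands) / len(cohort), 1),
        "receipt_fraction_evaluated_pct": round(
            100 * sum(received) / len(cohort), 1),
        "receipt_fraction_candidates_pct": round(
            100 * sum(received) / len(cands), 1),
        "mean_cbs": round(sum(cbs) / len(cbs), 1),
        "unadjusted_medicare_or": {
            "or": unadj.or_, "ci_low": unadj.ci_low, "ci_high": unadj.ci_high,
            "table": dataclasses.asdict(table),
        },
        "models": models.rows,
        "group_mean_tests": pvals,
        "summary": summary.to_dict("records"),
    }


def replicate_run(out_dir, seed: int = 0,
                  config: Optional[GeneratorConfig] = None,
                  use_allocation: bool = False,
                  alloc_config: Optional[AllocationConfig] = None) -> dict:
    """Full pipeline run; returns the results dict and writes artifacts.

    With ``use_allocation`` the receipt outcomes come from the
    capacity-constrained queue simulation instead of the generator's
    logistic outcome model.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config if config is not None else GeneratorConfig()
    cohort = generate_cohort(config, seed=seed)
    if use_allocation:
        alloc_config = (alloc_config if alloc_config is not None
                        else default_allocation_config())
        outcome = simulate_allocation(cohort, alloc_config, seed=seed)
        apply_allocation(cohort, outcome)
        per_period = [_jsonify(p) for p in outcome.periods]
    else:
        per_period = None

    results = analyze_cohort(cohort)
    if per_period is not None:
        results["per_period"] = per_period

    write_cohort_csv(cohort, out / "cohort.csv")
    summary_df = summarize_cohort(cohort)
    summary_df.to_csv(out / "summary.csv", index=False)
    (out / "results.json").write_text(json.dumps(results, indent=2,
                                                 sort_keys=True))
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "allocation": use_allocation,
        "package_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return results
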