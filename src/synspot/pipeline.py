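"""End-to-end drivers composing annotation, statistics, sequence design and
hairpin scanning into reproducible report bundles.

Every bundle embeds the package version, a hash of the configuration and
every seed used, so identical (config, seed) inputs yield byte-identical
JSON reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from . import __version__
from .hairpin_scan import ScanParams, compare_variants
from .mutation_annotation import (
    EXCLUDED,
    UNIDENTIFIED,
    EvolvedLine,
    build_outcome_table,
    group_routes,
)
from .repeatability_stats import (
    DEFAULT_ITERATIONS,
    p_focal_at_least,
    p_max_at_least,
    report_p,
)
from .sequence_variants import (
    CDSRecord,
    apply_substitutions,
    design_synonymous_swap,
    partition_divergence,
)


@dataclass
class RunConfig:
    """Parameters of a pipeline run; every stochastic stage records its seed."""

    seed: int = 0
    iterations: int = DEFAULT_ITERATIONS
    alpha: float = 0.05
    focal_route: str | None = None
    n_routes: int | None = None  # route-pool size; default = observed in condition
    flank_codons: int = 5
    scan: ScanParams = field(default_factory=ScanParams)

    def config_hash(self) -> str:
        blob = json.dumps(
            {**{k: v for k, v in asdict(self).items()}}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def run_repeatability_report(
    lines: list[EvolvedLine],
    reference_cds: dict[str, CDSRecord],
    config: RunConfig | None = None,
) -> dict:
    """Route classes, outcome tables, and bootstrap nulls for a line set.

    For each (strain, environment) condition the observed spectrum is tested
    against the equal-weight null. When ``config.focal_route`` names a route
    a priori, the focal-at-least statistic is used on that route's count;
    otherwise the most frequent route is summarised and the max-at-least
    statistic is used (testing a post-hoc maximum as if it were named in
    advance would overstate significance). The route pool defaults to the
    routes observed in the condition; ``config.n_routes`` widens it to a
    pool known from other conditions or experiments. Conditions with one
    observed route and no wider pool are reported without a test (the null
    is degenerate).
    """
    config = config or RunConfig()
    if not lines:
        return {**_provenance(config), "conditions": {}, "routes": [], "excluded": 0}

    classes, excluded = group_routes(lines, reference_cds)
    table = build_outcome_table(lines, reference_cds)

    conditions: dict[str, dict] = {}
    analysable = table.drop(index=[EXCLUDED], errors="ignore")
    for col in table.columns:
        strain, env = col
        counts = analysable[col]
        counts = counts[counts > 0]
        n_routes = config.n_routes or len(counts)
        n_draws = int(counts.sum())
        a_priori = config.focal_route is not None and config.focal_route in counts.index
        focal_label = config.focal_route if a_priori else counts.idxmax()
        entry: dict = {
            "n_lines": n_draws,
            "routes": {str(k): int(v) for k, v in counts.items()},
            "focal_route": str(focal_label),
            "focal_count": int(counts[focal_label]),
        }
        if n_routes >= 2:
            test = p_focal_at_least if a_priori else p_max_at_least
            res = test(
                k=int(counts[focal_label]),
                n_draws=n_draws,
                n_routes=n_routes,
                iterations=config.iterations,
                seed=config.seed,
            )
            entry["bootstrap"] = {
                "statistic": res.statistic,
                "k": res.k,
                "n_draws": res.n_draws,
                "n_routes": res.n_routes,
                "iterations": res.iterations,
                "hits": res.hits,
                "p_estimate": res.p_estimate,
                "p_bound": res.p_bound,
                "seed": res.seed,
                "formatted": report_p(res),
                "significant": (
                    res.hits == 0 or res.p_estimate < config.alpha
                ),
            }
        conditions[f"{strain}/{env}"] = entry

    return {
        **_provenance(config),
        "routes": [c.label for c in classes],
        "excluded": len(excluded),
        "conditions": conditions,
    }


def run_hotspot_swap(
    cds_a: CDSRecord,
    cds_b: CDSRecord,
    focal: int,
    config: RunConfig | None = None,
) -> dict:
    """Design and verify a local synonymous swap, with hairpin delta report.

    Designs the silent edit set matching ``cds_a`` to ``cds_b`` within
    ``flank_codons`` codons of the focal site, applies it (hard failure if
    any residual window edit would be non-synonymous), diffs the called
    hairpin stems of the two sequences around the focal site, and reports
    the full-length divergence partition.
    """
    config = config or RunConfig()
    swap = design_synonymous_swap(cds_a, cds_b, focal, config.flank_codons)
    engineered = apply_substitutions(cds_a, swap)  # certifies synonymy
    delta = compare_variants(cds_a.seq, engineered.seq, focal, config.scan)
    divergence = partition_divergence(cds_a, cds_b)
    return {
        **_provenance(config),
        "focal": focal,
        "flank_codons": config.flank_codons,
        "edits": [e.label for e in swap.edits],
        "skipped_positions": list(swap.skipped),
        "engineered_id": engineered.id,
        "engineered_seq": engineered.seq,
        "hairpin_delta": {
            "broken": len(delta.broken),
            "gained": len(delta.gained),
            "shared": len(delta.shared),
            "focal_paired_wt": delta.focal_paired_wt,
            "focal_paired_variant": delta.focal_paired_variant,
            "top_score_wt": delta.top_score_wt,
            "top_score_variant": delta.top_score_variant,
        },
        "divergence": divergence.as_dict(),
        "scan_params": asdict(config.scan),
    }
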