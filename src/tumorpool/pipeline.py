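"""End-to-end experiments and detection-power sweeps.

:func:`run_experiment` executes the full comparison for one simulated
tumor: generate truth, sequence each region, build the pooled and
in-silico mixed samples, call and filter variants, classify them across
regions, and compare expression profiles.  All randomness flows from the
single config seed, so a rerun is byte-identical.

:func:`sweep_detection` quantifies the central trade-off: how detection
power for a private (single-region) variant depends on its VAF and the
sequencing depth, in its home region, in a randomly chosen single biopsy,
and in an equal-weight pool where its VAF is diluted n-fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .calling import CallSet, apply_filters, detect
from .classification import (
    ClassificationSummary,
    classify,
    concordance_fractions,
    pca_variant_profiles,
    pooled_detection_stats,
    vaf_correlation,
    vaf_distribution_by_class,
)
from .config import SimulationConfig, stream_rng
from .expression import ExpressionComparison, compare_expression
from .pooling import mix_in_silico, pool_physical
from .synthetic_data import RegionReadSet, TruthSet, make_truth, simulate_region_counts
from .vcfio import (
    counts_matrix,
    write_callset_vcf,
    write_counts_tsv,
    write_gene_means_tsv,
    write_truth_vcf,
)

__all__ = ["ExperimentResult", "run_experiment", "sweep_detection", "min_detectable_alt"]

log = logging.getLogger("tumorpool")


@dataclass
class ExperimentResult:
    """Everything produced by one end-to-end run."""

    config: SimulationConfig
    truth: TruthSet
    regions: list[RegionReadSet]
    pooled: RegionReadSet
    mixed: RegionReadSet
    callsets: dict[str, CallSet]
    summary: ClassificationSummary
    expression: ExpressionComparison
    pca: pd.DataFrame
    report: dict = field(default_factory=dict)


def _summary_report(result: ExperimentResult) -> dict:
    agg = result.summary.aggregate
    return {
        "tool": {"name": "tumorpool", "version": __version__},
        "config": result.config.to_dict(),
        "n_variants": len(result.truth.variants),
        "classification": {
            "class_counts": agg["class_counts"],
            "concordance_fractions": agg["concordance_fractions"],
            "n_detected_any_region": agg["n_detected_any_region"],
            "pooled_detection": agg["pooled_detection"],
            "vaf_correlation": agg["vaf_correlation"],
            "vaf_by_class": agg["vaf_by_class"],
        },
        "expression": result.expression.to_aggregate(),
        "pca": {s: [float(x) for x in row] for s, row in result.pca.iterrows()},
    }


def run_experiment(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    panel: bool = False,
    mix_fraction: float = 0.25,
    restrict_moderate_to_shared: bool = False,
    figures: bool = False,
) -> ExperimentResult:
    """Run simulate -> pool/mix -> call -> classify -> expression-compare.

    When ``outdir`` is given, writes the truth VCF, per-sample call VCFs,
    the classification TSV, expression tables and a summary JSON there.
    On a stage failure the partially written outputs are removed and the
    error names the failing stage.
    """
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "simulate"
        truth = make_truth(config)
        regions = [simulate_region_counts(truth, r) for r in range(config.n_regions)]

        stage = "pool"
        pooled = pool_physical(
            regions,
            pooled_depth=config.depth_mean,
            depth_dispersion=config.depth_dispersion,
            rng=config.rng("pooled"),
        )
        mixed = mix_in_silico(regions, fraction=mix_fraction, rng=config.rng("mixed"))

        stage = "call"
        flags = truth.flags_frame()
        callsets = {}
        for rs in [*regions, pooled, mixed]:
            cs = detect(rs, error_rate=config.error_rate)
            callsets[rs.sample_id] = apply_filters(cs, flags, panel=panel)

        stage = "classify"
        summary = classify([callsets[r.sample_id] for r in regions])
        concordance_fractions(summary)
        pooled_detection_stats(
            summary,
            callsets[pooled.sample_id],
            callsets[mixed.sample_id],
            restrict_moderate_to_shared=restrict_moderate_to_shared,
        )
        vaf_correlation(summary)
        vaf_distribution_by_class(summary)
        pca = pca_variant_profiles(list(callsets.values()))

        stage = "expression"
        counts = counts_matrix([*regions, pooled])
        expr = compare_expression(counts, pooled_id=pooled.sample_id)

        result = ExperimentResult(
            config=config,
            truth=truth,
            regions=regions,
            pooled=pooled,
            mixed=mixed,
            callsets=callsets,
            summary=summary,
            expression=expr,
            pca=pca,
        )
        result.report = _summary_report(result)

        if outdir is not None:
            stage = "write"
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)

            def _w(path: Path, writer) -> None:
                writer(path)
                written.append(path)

            _w(out / "truth.vcf", lambda p: write_truth_vcf(truth, p))
            _w(out / "gene_means.tsv", lambda p: write_gene_means_tsv(truth, p))
            _w(out / "config.json", lambda p: config.to_json(p))
            for sid, cs in callsets.items():
                _w(out / f"calls_{sid}.vcf", lambda p, cs=cs: write_callset_vcf(cs, truth, p))
            _w(
                out / "classification.tsv",
                lambda p: summary.per_variant.to_csv(p, sep="\t"),
            )
            _w(out / "counts.tsv", lambda p: write_counts_tsv(counts, p))
            _w(
                out / "expression_foldchanges.tsv",
                lambda p: expr.foldchanges.to_csv(p, sep="\t", index=False),
            )
            _w(
                out / "expression_correlations.tsv",
                lambda p: expr.correlations.to_csv(p, sep="\t"),
            )
            _w(out / "pca.tsv", lambda p: pca.to_csv(p, sep="\t"))
            _w(
                out / "summary.json",
                lambda p: p.write_text(
                    json.dumps(result.report, indent=2, sort_keys=True) + "\n"
                ),
            )
            if figures:
                from .figures import write_figures

                for p in write_figures(result, out):
                    written.append(p)
        return result
    except Exception as err:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err


def min_detectable_alt(
    depth: np.ndarray | int,
    min_alt: int = 4,
    alpha: float = 1e-6,
    error_rate: float = 1e-3,
) -> np.ndarray:
    """Smallest alt count the stand-in caller accepts at each depth."""
    depth = np.atleast_1d(np.asarray(depth, dtype=int))
    out = np.empty(depth.shape, dtype=int)
    for i, d in enumerate(depth):
        k = int(min_alt)
        while k <= d and not stats.binom.sf(k - 1, d, error_rate) < alpha:
            k += 1
        out[i] = k  # d+1 means undetectable at this depth
    return out


def sweep_detection(
    vaf_grid,
    depth_grid,
    n_replicates: int = 2000,
    seed: int = 0,
    n_regions: int = 4,
    error_rate: float = 1e-3,
    min_alt: int = 4,
    alpha: float = 1e-6,
) -> pd.DataFrame:
    """Monte-Carlo detection power of a private variant on a (VAF, depth) grid.

    For each grid point, power is estimated for (a) the variant's home
    region, (b) one randomly chosen biopsy (which contains the variant
    with probability 1/n_regions), and (c) an equal-weight pool where the
    variant's VAF is diluted by n_regions.  Common random numbers are
    reused across the VAF grid, so the estimated power curves are exactly
    monotone in VAF.
    """
    vaf_grid = np.asarray(sorted(vaf_grid), dtype=float)
    depth_grid = np.asarray(sorted(int(d) for d in depth_grid), dtype=int)
    rng = stream_rng(seed, "sweep")
    rows = []
    for d in depth_grid:
        kmin = int(min_detectable_alt(d, min_alt, alpha, error_rate)[0])
        u_home = rng.uniform(size=n_replicates)
        u_pool = rng.uniform(size=n_replicates)
        u_absent = rng.uniform(size=n_replicates)
        in_biopsy = rng.uniform(size=n_replicates) < 1.0 / n_regions
        for v in vaf_grid:
            def _power(u, vv):
                p = vv * (1.0 - error_rate) + (1.0 - vv) * error_rate / 3.0
                alt = stats.binom.ppf(u, d, p)
                return alt >= kmin

            det_home = _power(u_home, v)
            det_absent = _power(u_absent, 0.0)
            det_single = np.where(in_biopsy, det_home, det_absent)
            det_pool = _power(u_pool, v / n_regions)
            rows.append(
                {
                    "vaf": float(v),
                    "depth": int(d),
                    "power_home_region": float(det_home.mean()),
                    "power_single_biopsy": float(det_single.mean()),
                    "power_pooled": float(det_pool.mean()),
                }
            )
    return pd.DataFrame(rows)
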