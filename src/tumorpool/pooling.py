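"""Pooled and in-silico mixed samples from regional read sets.

Two pooling routes are modeled:

* :func:`pool_physical` — tissue from the regions is mixed (with given
  weights) and a fresh library is sequenced.  The pooled allele fraction
  at a locus is the weighted mean of the regional observed fractions, and
  a new binomial read-count draw at the pooled depth represents the
  re-sequencing.  This dilutes region-restricted variants: a variant at
  40% VAF in one of four equally weighted regions pools to 10%.

* :func:`mix_in_silico` — a fixed fraction of reads is drawn (without
  replacement) from each regional library and the draws are summed; no
  re-sequencing occurs, so the mixed sample inherits the regional reads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import RegionReadSet, nb_draw

__all__ = ["pool_physical", "mix_in_silico"]


def _check_consistent(regions: list[RegionReadSet]) -> None:
    if not regions:
        raise ValueError("need at least one regional read set")
    ref = regions[0]
    for r in regions[1:]:
        ids_a = ref.variants["variant_id"].to_numpy()
        ids_b = r.variants["variant_id"].to_numpy()
        if len(ids_a) != len(ids_b) or (ids_a != ids_b).any():
            bad = next(
                (i for i, (a, b) in enumerate(zip(ids_a, ids_b)) if a != b),
                min(len(ids_a), len(ids_b)),
            )
            raise ValueError(
                f"variant loci mismatch between {ref.sample_id!r} and "
                f"{r.sample_id!r} at position {bad}"
            )
        if not ref.expr_counts.index.equals(r.expr_counts.index):
            raise ValueError(
                f"gene list mismatch between {ref.sample_id!r} and {r.sample_id!r}"
            )


def pool_physical(
    regions: list[RegionReadSet],
    weights: np.ndarray | list[float] | None = None,
    pooled_depth: float | None = None,
    depth_dispersion: float | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "pooled",
) -> RegionReadSet:
    """Simulate sequencing of a physically pooled library.

    Parameters
    ----------
    weights
        Per-region tissue fractions; nonnegative, summing to 1.  Default
        equal weights.
    pooled_depth
        Target mean depth of the pooled library; default the mean of the
        regional mean depths.
    depth_dispersion
        If given, per-locus depth is negative-binomial with this shape
        around ``pooled_depth`` (the regional depth model); otherwise the
        depth is fixed at ``pooled_depth``.
    """
    _check_consistent(regions)
    if rng is None:
        rng = np.random.default_rng()
    n = len(regions)
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")

    depths = np.stack([r.variants["depth"].to_numpy(float) for r in regions])
    alts = np.stack([r.variants["alt_count"].to_numpy(float) for r in regions])
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = np.where(depths > 0, alts / np.maximum(depths, 1.0), 0.0)
    pooled_frac = w @ fracs

    if pooled_depth is None:
        pooled_depth = float(depths.mean(axis=0).mean())
    n_loci = pooled_frac.shape[0]
    if depth_dispersion is not None:
        depth = nb_draw(rng, np.full(n_loci, float(pooled_depth)), depth_dispersion)
    else:
        depth = np.full(n_loci, int(round(pooled_depth)), dtype=int)
    alt = rng.binomial(depth, np.clip(pooled_frac, 0.0, 1.0))

    # expression: weighted mixture of regional rates, re-sampled to the
    # mean regional library size (one new library from mixed RNA)
    lib = np.array([float(r.expr_counts.sum()) for r in regions])
    rates = np.stack(
        [r.expr_counts.to_numpy(float) / max(l, 1.0) for r, l in zip(regions, lib)]
    )
    mix_rate = w @ rates
    total = int(round(lib.mean()))
    if mix_rate.sum() <= 0:
        expr = np.zeros(mix_rate.shape[0], dtype=int)
    else:
        expr = rng.multinomial(total, mix_rate / mix_rate.sum())

    return RegionReadSet(
        sample_id=sample_id,
        kind="pooled",
        variants=pd.DataFrame(
            {
                "variant_id": regions[0].variants["variant_id"].to_numpy(),
                "depth": np.asarray(depth, dtype=int),
                "alt_count": np.asarray(alt, dtype=int),
            }
        ),
        expr_counts=pd.Series(
            expr, index=regions[0].expr_counts.index.copy(), name=sample_id
        ),
    )


def mix_in_silico(
    regions: list[RegionReadSet],
    fraction: float = 0.25,
    rng: np.random.Generator | None = None,
    sample_id: str = "mixed",
) -> RegionReadSet:
    """Combine a random read subsample of each region into one sample.

    At each locus, ``round(fraction * depth)`` reads are drawn without
    replacement (hypergeometric) from each region's alt/ref reads; the
    per-region draws are summed.  Expression reads are thinned binomially
    at the same fraction per gene.  ``fraction=1`` with a single region is
    the identity.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    _check_consistent(regions)
    if rng is None:
        rng = np.random.default_rng()

    tot_depth = None
    tot_alt = None
    for r in regions:
        depth = r.variants["depth"].to_numpy(int)
        alt = r.variants["alt_count"].to_numpy(int)
        n_take = np.rint(fraction * depth).astype(int)
        taken_alt = np.zeros_like(alt)
        m = n_take > 0
        if fraction >= 1.0:
            taken_alt = alt.copy()
            n_take = depth.copy()
        elif m.any():
            taken_alt[m] = rng.hypergeometric(alt[m], depth[m] - alt[m], n_take[m])
        tot_depth = n_take if tot_depth is None else tot_depth + n_take
        tot_alt = taken_alt if tot_alt is None else tot_alt + taken_alt

    expr = None
    for r in regions:
        counts = r.expr_counts.to_numpy(int)
        taken = counts if fraction >= 1.0 else rng.binomial(counts, fraction)
        expr = taken if expr is None else expr + taken

    return RegionReadSet(
        sample_id=sample_id,
        kind="mixed",
        variants=pd.DataFrame(
            {
                "variant_id": regions[0].variants["variant_id"].to_numpy(),
                "depth": tot_depth,
                "alt_count": tot_alt,
            }
        ),
        expr_counts=pd.Series(
            expr, index=regions[0].expr_counts.index.copy(), name=sample_id
        ),
    )
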