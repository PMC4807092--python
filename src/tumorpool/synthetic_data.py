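"""Ground-truth clonal architectures and simulated sequencing evidence.

The generator emulates a multi-region tumor biopsy design: ``n_regions``
spatially distinct samples from one tumor, somatic variants partitioned
into truncal (present everywhere, VAF centered near 40%), shared (a strict
subset of >= 2 regions) and private (one region) classes at subclonal VAF,
plus germline heterozygous/homozygous SNPs, and a per-region gene
expression profile in which a minority of genes carry region-specific fold
changes.

Sequencing is replaced by a transparent count model: per-locus depth is
negative-binomial around the target coverage, and the alternate-read count
is binomial with success probability

    p = v * (1 - e) + (1 - v) * e / 3

where ``v`` is the true regional VAF and ``e`` the per-base error rate
(the substitution-symmetric error model: absent variants still produce
rare error reads).  Expression counts are gamma-Poisson (negative
binomial) around the gene mean times the region effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "TruthVariant",
    "TruthSet",
    "RegionReadSet",
    "make_truth",
    "simulate_region_counts",
    "nb_draw",
]

ORIGINS = (
    "somatic_truncal",
    "somatic_shared",
    "somatic_private",
    "germline_het",
    "germline_hom",
)

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))
_CHROM_LEN = 250_000_000
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthVariant:
    """A single ground-truth variant with its regional presence and VAFs."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    origin: str
    presence: frozenset[int]
    region_vaf: tuple[float, ...]  # length n_regions; 0 where absent
    in_dbsnp: bool
    pop_af_gt_1pct: bool
    in_cosmic_or_tcga: bool
    in_panel337: bool

    @property
    def is_somatic(self) -> bool:
        return self.origin.startswith("somatic")


@dataclass
class TruthSet:
    """Complete simulated ground truth for one tumor."""

    config: SimulationConfig
    variants: list[TruthVariant]
    gene_ids: list[str]
    gene_means: np.ndarray  # (n_genes,)
    region_effects: np.ndarray  # (n_genes, n_regions) fold multipliers

    @property
    def n_regions(self) -> int:
        return self.config.n_regions

    def vaf_matrix(self) -> np.ndarray:
        """True VAFs as a (n_variants, n_regions) array."""
        return np.array([v.region_vaf for v in self.variants])

    def flags_frame(self) -> pd.DataFrame:
        """Annotation flags indexed by variant_id (input to the filters)."""
        return pd.DataFrame(
            {
                "in_dbsnp": [v.in_dbsnp for v in self.variants],
                "pop_af_gt_1pct": [v.pop_af_gt_1pct for v in self.variants],
                "in_cosmic_or_tcga": [v.in_cosmic_or_tcga for v in self.variants],
                "in_panel337": [v.in_panel337 for v in self.variants],
            },
            index=pd.Index([v.variant_id for v in self.variants], name="variant_id"),
        )

    def variant_frame(self) -> pd.DataFrame:
        """One row per variant: locus, origin, presence, per-region VAFs."""
        rows = []
        for v in self.variants:
            row = {
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "origin": v.origin,
                "presence": ",".join(map(str, sorted(v.presence))),
            }
            for r in range(self.n_regions):
                row[f"vaf_r{r}"] = v.region_vaf[r]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class RegionReadSet:
    """Observed sequencing evidence for one sample.

    ``variants`` has one row per truth locus with columns
    ``variant_id, depth, alt_count``; ``expr_counts`` is the gene-level
    read-count vector indexed by gene id.
    """

    sample_id: str
    kind: str  # region | pooled | mixed
    variants: pd.DataFrame
    expr_counts: pd.Series

    def __post_init__(self) -> None:
        v = self.variants
        if ((v["alt_count"] < 0) | (v["alt_count"] > v["depth"])).any():
            raise ValueError("alt_count must satisfy 0 <= alt_count <= depth")

    @property
    def vaf(self) -> pd.Series:
        depth = self.variants["depth"].to_numpy(float)
        alt = self.variants["alt_count"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        return pd.Series(v, index=self.variants["variant_id"].to_numpy(), name="vaf")


def nb_draw(rng: np.random.Generator, mean, shape: float, size=None) -> np.ndarray:
    """Negative-binomial draw parameterized by mean and shape (size) k.

    Variance is mean + mean^2 / k; k -> inf recovers Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size if size is not None else mean.shape)


def _draw_loci(rng: np.random.Generator, n: int):
    chrom = rng.choice(len(_CHROMS), size=n)
    pos = rng.integers(1, _CHROM_LEN, size=n)
    # re-draw the (vanishingly rare) duplicated coordinates
    seen = set()
    for i in range(n):
        while (chrom[i], pos[i]) in seen:
            pos[i] = rng.integers(1, _CHROM_LEN)
        seen.add((chrom[i], int(pos[i])))
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_shift) % 4
    return (
        [_CHROMS[c] for c in chrom],
        pos,
        _BASES[ref_idx],
        _BASES[alt_idx],
    )


def make_truth(config: SimulationConfig) -> TruthSet:
    """Generate the ground-truth clonal architecture for one tumor.

    Variant order is deterministic: truncal, shared, private, germline het,
    germline hom.  Identical config (including seed) gives bit-identical
    output.
    """
    config.validate()
    rng = config.rng("truth")
    R = config.n_regions

    counts = {
        "somatic_truncal": config.n_truncal,
        "somatic_shared": config.n_shared,
        "somatic_private": config.n_private,
        "germline_het": config.n_germline_het,
        "germline_hom": config.n_germline_hom,
    }
    n_total = sum(counts.values())
    chroms, poss, refs, alts = _draw_loci(rng, n_total)

    lo, hi = config.vaf_subclonal_range
    variants: list[TruthVariant] = []
    i = 0
    for origin, n in counts.items():
        for _ in range(n):
            if origin == "somatic_truncal":
                presence = frozenset(range(R))
                v = float(np.clip(
                    rng.normal(config.vaf_truncal_mean, config.vaf_truncal_sd),
                    0.05, 0.95,
                ))
                vafs = tuple(v for _ in range(R))
            elif origin == "somatic_shared":
                k = int(rng.integers(2, R))  # strict subset, 2..R-1
                presence = frozenset(rng.choice(R, size=k, replace=False).tolist())
                vafs = tuple(
                    float(rng.uniform(lo, hi)) if r in presence else 0.0
                    for r in range(R)
                )
            elif origin == "somatic_private":
                presence = frozenset({int(rng.integers(R))})
                vafs = tuple(
                    float(rng.uniform(lo, hi)) if r in presence else 0.0
                    for r in range(R)
                )
            elif origin == "germline_het":
                presence = frozenset(range(R))
                vafs = tuple(0.5 for _ in range(R))
            else:  # germline_hom
                presence = frozenset(range(R))
                vafs = tuple(1.0 for _ in range(R))

            somatic = origin.startswith("somatic")
            if somatic:
                flags = dict(
                    in_dbsnp=False,
                    pop_af_gt_1pct=False,
                    in_cosmic_or_tcga=bool(rng.random() < config.frac_somatic_cosmic),
                    in_panel337=bool(rng.random() < config.frac_panel),
                )
            else:
                flags = dict(
                    in_dbsnp=True,
                    pop_af_gt_1pct=True,
                    in_cosmic_or_tcga=bool(rng.random() < config.frac_germline_cosmic),
                    in_panel337=bool(rng.random() < config.frac_panel),
                )
            variants.append(
                TruthVariant(
                    variant_id=f"v{i:05d}",
                    chrom=chroms[i],
                    pos=int(poss[i]),
                    ref=str(refs[i]),
                    alt=str(alts[i]),
                    origin=origin,
                    presence=presence,
                    region_vaf=vafs,
                    **flags,
                )
            )
            i += 1

    # expression truth
    G = config.n_genes
    gene_ids = [f"g{j:05d}" for j in range(G)]
    gene_means = rng.lognormal(np.log(config.expr_median), config.expr_log_sigma, size=G)
    region_effects = np.ones((G, R))
    n_de = int(round(config.frac_de_genes * G))
    if n_de > 0:
        de_genes = rng.choice(G, size=n_de, replace=False)
        de_regions = rng.integers(0, R, size=n_de)
        folds = rng.uniform(config.de_fold_range[0], config.de_fold_range[1], size=n_de)
        up = rng.random(n_de) < 0.5
        mult = np.where(up, folds, 1.0 / folds)
        region_effects[de_genes, de_regions] = mult

    return TruthSet(
        config=config,
        variants=variants,
        gene_ids=gene_ids,
        gene_means=gene_means,
        region_effects=region_effects,
    )


def simulate_region_counts(
    truth: TruthSet,
    region: int,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> RegionReadSet:
    """Sequence one regional biopsy of ``truth``: variant loci + expression.

    With no explicit ``rng`` a dedicated stream is derived from the config
    seed and the region index, so regional samples are mutually
    independent and individually reproducible.
    """
    cfg = truth.config
    if not 0 <= region < cfg.n_regions:
        raise ValueError(f"region must be in [0, {cfg.n_regions}), got {region}")
    if rng is None:
        rng = cfg.rng("region", region)
    if sample_id is None:
        sample_id = f"region{region + 1}"

    v = truth.vaf_matrix()[:, region]
    e = cfg.error_rate
    p = v * (1.0 - e) + (1.0 - v) * e / 3.0
    depth = nb_draw(rng, np.full(v.shape, cfg.depth_mean), cfg.depth_dispersion)
    alt = rng.binomial(depth, p)

    mean_expr = truth.gene_means * truth.region_effects[:, region]
    expr = nb_draw(rng, mean_expr, cfg.expr_dispersion)

    return RegionReadSet(
        sample_id=sample_id,
        kind="region",
        variants=pd.DataFrame(
            {
                "variant_id": [tv.variant_id for tv in truth.variants],
                "depth": depth.astype(int),
                "alt_count": alt.astype(int),
            }
        ),
        expr_counts=pd.Series(expr.astype(int), index=pd.Index(truth.gene_ids, name="gene_id"), name=sample_id),
    )
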