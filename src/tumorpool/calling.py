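"""A transparent stand-in variant caller and the post-call filters.

Detection is an exact binomial test against the sequencing error rate: a
locus is called iff the alt-read count reaches ``min_alt`` AND the
one-sided tail probability P(X >= alt | depth, error_rate) falls below
``alpha``.  With the defaults (min_alt=4, alpha=1e-6, error 1e-3) this
gives near-certain detection of VAF >= 5% variants at ~137x while keeping
error-driven calls rare, comparable in spirit to an exome somatic caller
run at default settings.

Three post-call filters mirror a conventional somatic pipeline:

* homozygous filter — calls with VAF > 90% are presumed homozygous
  germline SNPs and removed;
* germline filter — a call is removed iff it is in dbSNP AND has > 1%
  population frequency AND is NOT in COSMIC/TCGA (cancer-database
  membership rescues the call);
* panel filter (optional) — restrict to a 337-gene cancer panel.

Filters are independent predicates: a call failing several accumulates
their codes in ``filter_status`` (';'-separated, VCF style), so the PASS
set does not depend on the order in which filters are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import RegionReadSet

__all__ = [
    "VariantCall",
    "CallSet",
    "detect",
    "filter_homozygous",
    "filter_germline",
    "filter_panel",
    "apply_filters",
]

HOM_FILTER = "HOM_FILTER"
GERMLINE_FILTER = "GERMLINE_FILTER"
PANEL_FILTER = "PANEL_FILTER"
NOT_DETECTED = "NOT_DETECTED"
PASS = "PASS"


@dataclass(frozen=True)
class VariantCall:
    """One call record for one sample."""

    variant_id: str
    sample_id: str
    depth: int
    alt_count: int
    vaf: float
    detected: bool
    filter_status: str


@dataclass
class CallSet:
    """All calls of one sample plus the caller parameters used.

    ``df`` holds one row per variant locus with columns
    ``variant_id, depth, alt_count, vaf, detected, filter_status``.
    """

    sample_id: str
    df: pd.DataFrame
    params: dict = field(default_factory=dict)

    def records(self):
        for row in self.df.itertuples(index=False):
            yield VariantCall(
                variant_id=row.variant_id,
                sample_id=self.sample_id,
                depth=int(row.depth),
                alt_count=int(row.alt_count),
                vaf=float(row.vaf),
                detected=bool(row.detected),
                filter_status=row.filter_status,
            )

    @property
    def passing(self) -> pd.Series:
        """Boolean mask of detected calls that pass every applied filter."""
        return self.df["detected"] & (self.df["filter_status"] == PASS)

    def copy(self) -> "CallSet":
        return CallSet(self.sample_id, self.df.copy(), dict(self.params))


def detect(
    readset: RegionReadSet,
    min_alt: int = 4,
    alpha: float = 1e-6,
    error_rate: float = 1e-3,
) -> CallSet:
    """Call variants from read counts with the binomial-tail detector."""
    if min_alt < 1:
        raise ValueError("min_alt must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")

    v = readset.variants
    if len(v) == 0:
        warnings.warn(f"empty read set for sample {readset.sample_id!r}")
        df = pd.DataFrame(
            columns=["variant_id", "depth", "alt_count", "vaf", "detected", "filter_status"]
        )
        return CallSet(readset.sample_id, df,
                       dict(min_alt=min_alt, alpha=alpha, error_rate=error_rate))

    depth = v["depth"].to_numpy(int)
    alt = v["alt_count"].to_numpy(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    # P(X >= alt) under Binomial(depth, error_rate)
    pval = stats.binom.sf(alt - 1, depth, error_rate)
    detected = (alt >= min_alt) & (pval < alpha)

    df = pd.DataFrame(
        {
            "variant_id": v["variant_id"].to_numpy(),
            "depth": depth,
            "alt_count": alt,
            "vaf": vaf,
            "detected": detected,
            "filter_status": np.where(detected, PASS, NOT_DETECTED),
        }
    )
    return CallSet(readset.sample_id, df,
                   dict(min_alt=min_alt, alpha=alpha, error_rate=error_rate))


def _mark(calls: CallSet, fail_mask: np.ndarray, code: str) -> CallSet:
    out = calls.copy()
    df = out.df
    mask = df["detected"].to_numpy() & np.asarray(fail_mask, dtype=bool)
    status = df["filter_status"].to_numpy(object).copy()
    for i in np.flatnonzero(mask):
        status[i] = code if status[i] == PASS else f"{status[i]};{code}"
    df["filter_status"] = status
    return out


def filter_homozygous(calls: CallSet, threshold: float = 0.90) -> CallSet:
    """Flag presumed homozygous germline SNPs: VAF strictly above 90%."""
    return _mark(calls, calls.df["vaf"].to_numpy() > threshold, HOM_FILTER)


def _aligned_flags(calls: CallSet, truth_flags: pd.DataFrame) -> pd.DataFrame:
    ids = calls.df["variant_id"]
    missing = ids[~ids.isin(truth_flags.index)]
    if len(missing):
        raise KeyError(
            f"no annotation flags for variant {missing.iloc[0]!r} "
            f"(sample {calls.sample_id!r})"
        )
    return truth_flags.loc[ids]


def filter_germline(calls: CallSet, truth_flags: pd.DataFrame) -> CallSet:
    """Remove presumed germline variants by the three-criteria rule.

    A call is removed iff it is reported in dbSNP, AND has population
    allele frequency > 1%, AND is not reported in COSMIC/TCGA.
    """
    f = _aligned_flags(calls, truth_flags)
    fail = (
        f["in_dbsnp"].to_numpy()
        & f["pop_af_gt_1pct"].to_numpy()
        & ~f["in_cosmic_or_tcga"].to_numpy()
    )
    return _mark(calls, fail, GERMLINE_FILTER)


def filter_panel(
    calls: CallSet, truth_flags: pd.DataFrame, enabled: bool = True
) -> CallSet:
    """Optionally restrict calls to the 337-gene cancer panel."""
    if not enabled:
        return calls.copy()
    f = _aligned_flags(calls, truth_flags)
    return _mark(calls, ~f["in_panel337"].to_numpy(), PANEL_FILTER)


def apply_filters(
    calls: CallSet,
    truth_flags: pd.DataFrame,
    panel: bool = False,
    hom_threshold: float = 0.90,
) -> CallSet:
    """Standard post-call filter chain: homozygous, germline, panel."""
    out = filter_homozygous(calls, hom_threshold)
    out = filter_germline(out, truth_flags)
    out = filter_panel(out, truth_flags, enabled=panel)
    return out
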