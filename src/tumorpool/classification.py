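"""Cross-region variant classification and concordance statistics.

Variants detected across the regional call sets of one tumor are
partitioned into

* ``common``  — detected (and passing filters) in all n regions,
* ``shared``  — detected in >= 2 but not all regions,
* ``private`` — detected in exactly one region,
* ``absent``  — detected in none (excluded from concordance denominators).

From this partition the module computes the headline comparisons of a
pooled (or in-silico mixed) library against the regional ones: per-class
pooled detection rates, the fraction of moderate-VAF (> 20% in at least
one region) variants the pool misses, the Pearson correlation between the
mean regional VAF and the pooled VAF, per-class VAF distributions, and a
PCA of the samples' VAF profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CallSet

__all__ = [
    "ClassificationSummary",
    "classify",
    "concordance_fractions",
    "pooled_detection_stats",
    "vaf_correlation",
    "vaf_distribution_by_class",
    "pca_variant_profiles",
]

CLASSES = ("common", "shared", "private")


@dataclass
class ClassificationSummary:
    """Per-variant class labels and the aggregate statistics built on them.

    ``per_variant`` is indexed by variant_id with columns ``label``,
    ``n_regions_detected``, ``max_regional_vaf``, ``mean_regional_vaf``
    and, after :func:`pooled_detection_stats`, ``pooled_vaf``,
    ``pooled_detected`` (and the mixed equivalents).  ``detection`` is the
    boolean variants x regions detection matrix.
    """

    per_variant: pd.DataFrame
    detection: pd.DataFrame
    n_regions: int
    region_ids: list[str]
    aggregate: dict = field(default_factory=dict)


def _check_loci(callsets: list[CallSet]) -> pd.Index:
    ids = pd.Index(callsets[0].df["variant_id"])
    for cs in callsets[1:]:
        other = pd.Index(cs.df["variant_id"])
        if len(other) != len(ids) or not (other == ids).all():
            raise ValueError(
                f"call sets {callsets[0].sample_id!r} and {cs.sample_id!r} "
                "cover inconsistent loci"
            )
    return ids


def classify(regional_callsets: list[CallSet]) -> ClassificationSummary:
    """Partition variants by how many regional samples they pass in."""
    if len(regional_callsets) < 2:
        raise ValueError("need >= 2 regional call sets")
    ids = _check_loci(regional_callsets)
    n = len(regional_callsets)

    det = np.stack([cs.passing.to_numpy() for cs in regional_callsets], axis=1)
    vafs = np.stack([cs.df["vaf"].to_numpy() for cs in regional_callsets], axis=1)
    n_det = det.sum(axis=1)

    label = np.full(len(ids), "absent", dtype=object)
    label[n_det == n] = "common"
    label[(n_det >= 2) & (n_det <= n - 1)] = "shared"
    label[n_det == 1] = "private"

    per_variant = pd.DataFrame(
        {
            "label": label,
            "n_regions_detected": n_det,
            "max_regional_vaf": vafs.max(axis=1),
            "mean_regional_vaf": vafs.mean(axis=1),
        },
        index=ids.rename("variant_id"),
    )
    detection = pd.DataFrame(
        det,
        index=ids.rename("variant_id"),
        columns=[cs.sample_id for cs in regional_callsets],
    )
    summary = ClassificationSummary(
        per_variant=per_variant,
        detection=detection,
        n_regions=n,
        region_ids=[cs.sample_id for cs in regional_callsets],
    )
    summary.aggregate["class_counts"] = {
        c: int((label == c).sum()) for c in (*CLASSES, "absent")
    }
    return summary


def concordance_fractions(summary: ClassificationSummary) -> dict[str, float]:
    """Per-class fraction of variants detected in at least one region."""
    lab = summary.per_variant["label"]
    denom = int((lab != "absent").sum())
    fractions = {
        c: (float((lab == c).sum()) / denom if denom else float("nan"))
        for c in CLASSES
    }
    summary.aggregate["concordance_fractions"] = fractions
    summary.aggregate["n_detected_any_region"] = denom
    return fractions


def pooled_detection_stats(
    summary: ClassificationSummary,
    pooled_callset: CallSet,
    mixed_callset: CallSet | None = None,
    moderate_vaf_threshold: float = 0.20,
    restrict_moderate_to_shared: bool = False,
) -> dict:
    """Detection of regionally identified variants in the pooled/mixed sample.

    Returns per-class pooled (and mixed) detection rates, the fraction of
    moderate-VAF variants (max regional VAF above ``moderate_vaf_threshold``,
    optionally restricted to the shared class) missed by the pool, and the
    single-biopsy expectation (mean over regions of the fraction of
    regionally detected variants present in that one region).
    """
    pv = summary.per_variant
    ids = pv.index

    pooled_idx = pooled_callset.df.set_index("variant_id")
    if not pooled_idx.index.isin(ids).all() or len(pooled_idx) != len(ids):
        raise ValueError("pooled call set covers inconsistent loci")
    pv["pooled_vaf"] = pooled_idx.loc[ids, "vaf"].to_numpy()
    pv["pooled_detected"] = (
        pooled_idx.loc[ids, "detected"]
        & (pooled_idx.loc[ids, "filter_status"] == "PASS")
    ).to_numpy()
    if mixed_callset is not None:
        mixed_idx = mixed_callset.df.set_index("variant_id")
        pv["mixed_vaf"] = mixed_idx.loc[ids, "vaf"].to_numpy()
        pv["mixed_detected"] = (
            mixed_idx.loc[ids, "detected"]
            & (mixed_idx.loc[ids, "filter_status"] == "PASS")
        ).to_numpy()

    stats_out: dict = {"pooled_detection_rate": {}, "mixed_detection_rate": {}}
    for c in CLASSES:
        m = pv["label"] == c
        nc = int(m.sum())
        stats_out["pooled_detection_rate"][c] = (
            float(pv.loc[m, "pooled_detected"].mean()) if nc else float("nan")
        )
        if mixed_callset is not None:
            stats_out["mixed_detection_rate"][c] = (
                float(pv.loc[m, "mixed_detected"].mean()) if nc else float("nan")
            )

    regional = pv["label"] != "absent"
    moderate = regional & (pv["max_regional_vaf"] > moderate_vaf_threshold)
    if restrict_moderate_to_shared:
        moderate &= pv["label"] == "shared"
    n_mod = int(moderate.sum())
    stats_out["missed_moderate_vaf_fraction"] = (
        float((~pv.loc[moderate, "pooled_detected"]).mean()) if n_mod else float("nan")
    )
    stats_out["n_moderate_vaf"] = n_mod

    det = summary.detection.to_numpy()[regional.to_numpy()]
    stats_out["single_biopsy_expectation"] = (
        float(det.mean(axis=0).mean()) if det.size else float("nan")
    )

    summary.aggregate["pooled_detection"] = stats_out
    return stats_out


def vaf_correlation(summary: ClassificationSummary) -> dict[str, float]:
    """Pearson r of mean regional VAF vs pooled (and mixed) VAF.

    Computed over variants detected in at least one region; variants the
    pool did not call contribute their observed pooled VAF (possibly 0).
    Degenerate (zero-variance) input yields NaN with a warning.
    """
    pv = summary.per_variant
    if "pooled_vaf" not in pv.columns:
        raise ValueError("run pooled_detection_stats first to attach pooled VAFs")
    regional = pv[pv["label"] != "absent"]
    out: dict[str, float] = {}
    for key in ("pooled", "mixed"):
        col = f"{key}_vaf"
        if col not in pv.columns:
            continue
        x = regional["mean_regional_vaf"].to_numpy()
        y = regional[col].to_numpy()
        if len(x) < 3:
            raise ValueError("need >= 3 variants detected in the pooled/mixed sample")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"zero variance in {key} VAF comparison; r undefined")
            out[key] = float("nan")
        else:
            out[key] = float(stats.pearsonr(x, y).statistic)
    summary.aggregate["vaf_correlation"] = out
    return out


def vaf_distribution_by_class(summary: ClassificationSummary) -> pd.DataFrame:
    """Median and quartiles of the max regional VAF, per class."""
    rows = []
    pv = summary.per_variant
    for c in CLASSES:
        v = pv.loc[pv["label"] == c, "max_regional_vaf"].to_numpy()
        if v.size:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
        else:
            q1 = med = q3 = float("nan")
        rows.append({"label": c, "n": int(v.size), "q1": q1, "median": med, "q3": q3})
    out = pd.DataFrame(rows).set_index("label")
    summary.aggregate["vaf_by_class"] = {
        c: {k: (None if pd.isna(val) else float(val)) for k, val in row.items()}
        for c, row in out.drop(columns="n").iterrows()
    }
    return out


def pca_variant_profiles(callsets: list[CallSet], n_components: int = 2) -> pd.DataFrame:
    """Project samples onto the principal components of their VAF profiles.

    The samples x variants VAF matrix (restricted to variants passing in
    at least one sample) is column-centered and decomposed by SVD; scores
    of the first components are returned with a deterministic sign
    convention (the largest-magnitude loading of each component is made
    positive).
    """
    if len(callsets) < 2:
        raise ValueError("need >= 2 samples for a variant-profile PCA")
    ids = _check_loci(callsets)
    vaf = np.stack([cs.df["vaf"].to_numpy() for cs in callsets])
    passing = np.stack([cs.passing.to_numpy() for cs in callsets])
    keep = passing.any(axis=0)
    X = vaf[:, keep]
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(S))
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * S[:k]
    return pd.DataFrame(
        scores,
        index=pd.Index([cs.sample_id for cs in callsets], name="sample_id"),
        columns=[f"PC{j + 1}" for j in range(k)],
    )
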