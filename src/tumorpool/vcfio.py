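"""File formats: truth and call-set VCFs (via pysam), TSV tables.

Truth sets are written as sites-only VCF with INFO fields carrying the
origin class, the region-presence set, per-region true VAFs, and the
annotation flags.  Call sets are written as single-sample VCF with the
FILTER column holding the filter status and FORMAT fields DP/AD/VAF.
VAF is a derived quantity (alt/depth) and is recomputed on read, so a
write/read round trip reproduces the call set exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .calling import NOT_DETECTED, PASS, CallSet
from .config import SimulationConfig
from .synthetic_data import RegionReadSet, TruthSet, TruthVariant

__all__ = [
    "write_truth_vcf",
    "read_truth_vcf",
    "write_callset_vcf",
    "read_callset_vcf",
    "write_gene_means_tsv",
    "write_readset",
    "read_readset",
    "counts_matrix",
    "write_counts_tsv",
    "read_counts_tsv",
]

_CONTIGS = [f"chr{i}" for i in range(1, 23)]
_CONTIG_LEN = 250_000_000
_FILTER_CODES = ("HOM_FILTER", "GERMLINE_FILTER", "PANEL_FILTER", "NOT_DETECTED")
_FLAG_INFO = {
    "in_dbsnp": "DBSNP",
    "pop_af_gt_1pct": "POPAF1PCT",
    "in_cosmic_or_tcga": "COSMIC_TCGA",
    "in_panel337": "PANEL337",
}


def _base_header() -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in _CONTIGS:
        h.contigs.add(c, length=_CONTIG_LEN)
    return h


def write_truth_vcf(truth: TruthSet, path: str | Path) -> None:
    """Serialize the ground truth as a sites-only VCF."""
    h = _base_header()
    h.info.add("ORIGIN", 1, "String", "Variant origin class")
    h.info.add("PRESENCE", ".", "Integer", "Region indices where the variant exists")
    h.info.add("RVAF", ".", "Float", "True VAF per region (all regions, in order)")
    for tag in _FLAG_INFO.values():
        h.info.add(tag, 0, "Flag", f"Annotation flag {tag}")
    order = {c: i for i, c in enumerate(_CONTIGS)}
    with pysam.VariantFile(str(path), "w", header=h) as out:
        for v in sorted(truth.variants, key=lambda t: (order[t.chrom], t.pos)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos,
                alleles=(v.ref, v.alt),
                id=v.variant_id,
            )
            rec.info["ORIGIN"] = v.origin
            rec.info["PRESENCE"] = sorted(v.presence)
            rec.info["RVAF"] = list(v.region_vaf)
            for attr, tag in _FLAG_INFO.items():
                if getattr(v, attr):
                    rec.info[tag] = True
            out.write(rec)


def read_truth_vcf(path: str | Path, config: SimulationConfig | None = None) -> TruthSet:
    """Load a truth VCF back into a TruthSet (variant part only).

    The expression truth (gene means, region effects) is not stored in
    the VCF; the returned TruthSet carries empty expression arrays.
    """
    variants: list[TruthVariant] = []
    with pysam.VariantFile(str(path)) as f:
        for rec in f:
            rvaf = tuple(round(float(x), 6) for x in rec.info["RVAF"])
            variants.append(
                TruthVariant(
                    variant_id=rec.id,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    origin=rec.info["ORIGIN"],
                    presence=frozenset(int(i) for i in rec.info["PRESENCE"]),
                    region_vaf=rvaf,
                    **{attr: bool(rec.info.get(tag, False)) for attr, tag in _FLAG_INFO.items()},
                )
            )
    n_regions = len(variants[0].region_vaf) if variants else 2
    if config is None:
        config = SimulationConfig(
            n_regions=n_regions, n_truncal=0, n_shared=0, n_private=0,
            n_germline_het=0, n_germline_hom=0, n_genes=0,
        )
    # restore generation order (ids are zero-padded)
    variants.sort(key=lambda v: v.variant_id)
    return TruthSet(
        config=config,
        variants=variants,
        gene_ids=[],
        gene_means=np.array([]),
        region_effects=np.ones((0, n_regions)),
    )


def write_callset_vcf(callset: CallSet, truth: TruthSet, path: str | Path) -> None:
    """Write one sample's calls as VCF with DP/AD/VAF FORMAT fields."""
    h = _base_header()
    for code in _FILTER_CODES:
        h.filters.add(code, None, None, f"Call failed {code}")
    h.formats.add("DP", 1, "Integer", "Read depth")
    h.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    h.formats.add("VAF", 1, "Float", "Variant allele fraction")
    h.add_sample(callset.sample_id)
    loci = {v.variant_id: v for v in truth.variants}
    order = {c: i for i, c in enumerate(_CONTIGS)}
    rows = callset.df.to_dict("records")
    rows.sort(key=lambda r: (order[loci[r["variant_id"]].chrom], loci[r["variant_id"]].pos))
    with pysam.VariantFile(str(path), "w", header=h) as out:
        for row in rows:
            tv = loci[row["variant_id"]]
            rec = out.new_record(
                contig=tv.chrom,
                start=tv.pos - 1,
                stop=tv.pos,
                alleles=(tv.ref, tv.alt),
                id=tv.variant_id,
            )
            for code in str(row["filter_status"]).split(";"):
                rec.filter.add(code)
            depth = int(row["depth"])
            alt = int(row["alt_count"])
            sample = rec.samples[callset.sample_id]
            sample["DP"] = depth
            sample["AD"] = (depth - alt, alt)
            sample["VAF"] = float(row["vaf"])
            out.write(rec)


def read_callset_vcf(path: str | Path) -> CallSet:
    """Load a call-set VCF; VAF is recomputed from DP/AD."""
    rows = []
    with pysam.VariantFile(str(path)) as f:
        sample_id = list(f.header.samples)[0]
        for rec in f:
            s = rec.samples[sample_id]
            depth = int(s["DP"])
            alt = int(s["AD"][1])
            status = ";".join(rec.filter.keys())
            rows.append(
                {
                    "variant_id": rec.id,
                    "depth": depth,
                    "alt_count": alt,
                    "vaf": alt / depth if depth > 0 else 0.0,
                    "detected": NOT_DETECTED not in status,
                    "filter_status": status,
                }
            )
    df = pd.DataFrame(rows).sort_values("variant_id", kind="stable").reset_index(drop=True)
    return CallSet(sample_id, df)


def write_gene_means_tsv(truth: TruthSet, path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": truth.gene_ids, "mean": truth.gene_means})
    for r in range(truth.n_regions):
        df[f"effect_r{r}"] = truth.region_effects[:, r]
    df.to_csv(path, sep="\t", index=False)


def write_readset(rs: RegionReadSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write a read set as two TSVs: <prefix>.sites.tsv, <prefix>.counts.tsv."""
    prefix = Path(prefix)
    sites = prefix.with_suffix(".sites.tsv")
    counts = prefix.with_suffix(".counts.tsv")
    df = rs.variants.copy()
    df.insert(0, "sample_id", rs.sample_id)
    df.insert(1, "kind", rs.kind)
    df.to_csv(sites, sep="\t", index=False)
    rs.expr_counts.rename_axis("gene_id").to_frame(rs.sample_id).to_csv(counts, sep="\t")
    return sites, counts


def read_readset(prefix: str | Path) -> RegionReadSet:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".sites.tsv"), sep="\t")
    counts = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col="gene_id")
    sample_id = str(df["sample_id"].iloc[0])
    kind = str(df["kind"].iloc[0])
    return RegionReadSet(
        sample_id=sample_id,
        kind=kind,
        variants=df[["variant_id", "depth", "alt_count"]].copy(),
        expr_counts=counts[counts.columns[0]].rename(sample_id),
    )


def counts_matrix(readsets: list[RegionReadSet]) -> pd.DataFrame:
    """Genes x samples count matrix from a list of read sets."""
    return pd.concat([rs.expr_counts.rename(rs.sample_id) for rs in readsets], axis=1)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
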