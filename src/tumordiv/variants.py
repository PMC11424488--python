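"""Post-calling somatic mutation machinery.

The calling engines themselves (mutect2, platypus, deepSNV) are upstream of
this module; it consumes VCF-like records and implements the per-sample
keep/drop rules, the six-criterion multisample filter cascade, the VAF-based
clonality rule, mutation multiplicity with the loss-of-heterozygosity call,
and strand-split artifact read (SSAR) flagging on alignment records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleCall",
    "VariantRecord",
    "ReadAlignment",
    "apply_site_filters",
    "apply_multisample_filters",
    "classify_clonality",
    "mutation_multiplicity",
    "flag_ssar",
    "records_from_table",
    "read_vcf",
]


@dataclass
class SampleCall:
    """Per-sample evidence at one site."""

    depth: int
    alt_reads: int
    genotype: str = "0/1"
    genotype_quality: float = 99.0

    @property
    def vaf(self) -> float:
        return 0.0 if self.depth == 0 else self.alt_reads / self.depth

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads cannot exceed depth")


@dataclass
class VariantRecord:
    """One variant site with per-sample calls and site-level filter flags."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: dict  # sample id -> SampleCall
    flags: set = field(default_factory=set)  # e.g. {"MQ", "strandBias", "artifact_in_normal"}
    normal_sample: str = "normal"

    @property
    def tumor_samples(self) -> list:
        return [s for s in self.calls if s != self.normal_sample]

    @property
    def normal(self) -> SampleCall:
        return self.calls[self.normal_sample]


@dataclass
class ReadAlignment:
    """Primary alignment plus secondary alignments for one read."""

    read_id: str
    chrom: str
    pos: int
    strand: str  # "+" or "-"
    secondary: list = field(default_factory=list)  # (chrom, pos, strand)


# ---------------------------------------------------------------------------
# single-sample (mutect2-stage) filters


def apply_site_filters(record: VariantRecord, tumor_sample: str,
                       min_depth: int = 10, min_alt: int = 3,
                       vaf_ratio: float = 10.0) -> tuple:
    """Per-tumor-sample keep/drop decision at the first-pass calling stage.

    Keeps a call iff tumor and normal coverage both exceed ``min_depth``
    reads, the tumor shows at least ``min_alt`` variant reads, the normal is
    genotyped '0/0' while the tumor is not, and the tumor VAF is more than
    ``vaf_ratio`` times the normal VAF (records flagged 'artifact_in_normal'
    are retained subject to this ratio clause rather than dropped outright).
    Returns (keep, reason).
    """
    t = record.calls[tumor_sample]
    n = record.normal
    if t.depth <= min_depth or n.depth <= min_depth:
        return False, "coverage"
    if t.alt_reads < min_alt:
        return False, "alt_reads"
    if n.genotype != "0/0":
        return False, "normal_genotype"
    if t.genotype == "0/0":
        return False, "tumor_genotype"
    if n.vaf > 0 and not (t.vaf > vaf_ratio * n.vaf):
        return False, "vaf_ratio"
    return True, "pass"


# ---------------------------------------------------------------------------
# multisample (platypus-stage) cascade

_RULES = ["flags", "genotype_quality", "site_depth", "genotypes", "tumor_alt", "vaf_ratio"]


def _fails_rule(record: VariantRecord, rule: str, min_gq: float, min_depth: int,
                min_alt: int, vaf_ratio: float) -> bool:
    tumors = record.tumor_samples
    if rule == "flags":
        return bool({"MQ", "strandBias"} & record.flags)
    if rule == "genotype_quality":
        return not any(c.genotype_quality >= min_gq for c in record.calls.values())
    if rule == "site_depth":
        return not all(c.depth >= min_depth for c in record.calls.values())
    if rule == "genotypes":
        normal_ok = record.normal.genotype == "0/0"
        tumor_ok = any(record.calls[s].genotype != "0/0" for s in tumors)
        return not (normal_ok and tumor_ok)
    if rule == "tumor_alt":
        return not any(record.calls[s].alt_reads >= min_alt for s in tumors)
    if rule == "vaf_ratio":
        vmax = max(record.calls[s].vaf for s in tumors)
        nv = record.normal.vaf
        return not (vmax > vaf_ratio * nv)
    raise ValueError(rule)


def apply_multisample_filters(
    records: Sequence[VariantRecord],
    min_gq: float = 60.0,
    min_depth: int = 10,
    min_alt: int = 3,
    vaf_ratio: float = 10.0,
) -> tuple:
    """Six-rule multisample filter cascade, applied in order.

    Rules: (1) MQ/strandBias flags; (2) genotype quality >= 60 in at least
    one sample; (3) >= 10 reads at the site in all samples; (4) germline
    '0/0' and at least one tumor not '0/0'; (5) >= 3 variant reads in at
    least one tumor; (6) highest tumor VAF more than 10x the normal VAF.
    Returns (survivors, drop_counts) where drop_counts logs the first failed
    rule per dropped record.
    """
    survivors = []
    drops = {r: 0 for r in _RULES}
    for rec in records:
        failed = None
        for rule in _RULES:
            if _fails_rule(rec, rule, min_gq, min_depth, min_alt, vaf_ratio):
                failed = rule
                break
        if failed is None:
            survivors.append(rec)
        else:
            drops[failed] += 1
    return survivors, drops


# ---------------------------------------------------------------------------
# clonality, multiplicity, SSAR


def classify_clonality(record: VariantRecord, tumor_samples: Optional[Sequence[str]] = None,
                       threshold: float = 0.05, rule: str = "all") -> str:
    """Clonal/subclonal call from VAFs across a participant's tumor samples.

    Default rule: clonal iff the VAF exceeds ``threshold`` in every tumor
    sample (a truncal mutation is expected in all regions); otherwise
    subclonal. ``rule='any'`` implements the alternative reading (subclonal
    iff no sample exceeds the threshold). Refuses participants with fewer
    than three tumor samples, where regional absence is uninformative.
    """
    samples = list(tumor_samples) if tumor_samples is not None else record.tumor_samples
    if len(samples) < 3:
        raise ValueError("clonality assessment requires >= 3 tumor samples")
    vafs = [record.calls[s].vaf for s in samples]
    if rule == "all":
        return "clonal" if all(v > threshold for v in vafs) else "subclonal"
    if rule == "any":
        return "subclonal" if all(v <= threshold for v in vafs) else "clonal"
    raise ValueError(rule)


def mutation_multiplicity(vaf: float, purity: float, cn_total: int) -> tuple:
    """Estimated mutated copies per tumor cell, assuming a clonal mutation.

    m = VAF * (rho * CN + 2 * (1 - rho)) / rho. The mutation is called
    homozygous (wild-type allele lost) when m exceeds CN - 0.5.
    """
    if purity == 0:
        raise ValueError("purity must be positive")
    m = vaf * (purity * cn_total + 2.0 * (1.0 - purity)) / purity
    return m, bool(m > cn_total - 0.5)


def flag_ssar(read: ReadAlignment, window: int = 500) -> bool:
    """True when the read shows a strand-split artifact signature.

    Flagged iff any secondary alignment sits on the opposite strand, on the
    same chromosome, within ``window`` bp of the primary alignment start.
    """
    for chrom, pos, strand in read.secondary:
        if chrom == read.chrom and strand != read.strand and abs(pos - read.pos) <= window:
            return True
    return False


# ---------------------------------------------------------------------------
# input adapters


def records_from_table(df: pd.DataFrame, normal_sample: str = "normal") -> list:
    """Build VariantRecords from a long table (site_id, sample, depth, alt_reads).

    Genotypes default to '0/1' where alt reads are present and '0/0'
    otherwise; optional columns ``genotype``, ``genotype_quality`` and
    ``flags`` (comma-separated) override the defaults.
    """
    records = []
    for site_id, grp in df.groupby("site_id", sort=True):
        calls = {}
        flags: set = set()
        for _, row in grp.iterrows():
            gt = row.get("genotype")
            if gt is None or (isinstance(gt, float) and np.isnan(gt)):
                gt = "0/1" if row["alt_reads"] > 0 else "0/0"
            gq = row.get("genotype_quality", 99.0)
            calls[row["sample"]] = SampleCall(
                depth=int(row["depth"]), alt_reads=int(row["alt_reads"]),
                genotype=str(gt), genotype_quality=float(gq),
            )
            if "flags" in row and isinstance(row["flags"], str) and row["flags"]:
                flags |= set(row["flags"].split(","))
        first = grp.iloc[0]
        records.append(
            VariantRecord(chrom=str(first["chrom"]), pos=int(first["pos"]),
                          ref=str(first["ref"]), alt=str(first["alt_base"]),
                          calls=calls, flags=flags, normal_sample=normal_sample)
        )
    return records


def read_vcf(path, normal_sample: str = "normal") -> list:
    """Read a minimal VCF (FORMAT GT:DP:AD:GQ) into VariantRecords.

    Site FILTER entries other than PASS/'.' become record flags. AD is the
    ref,alt allelic-depth pair; the alt count feeds ``alt_reads``.
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            calls = {}
            for sname, call in rec.samples.items():
                gt = call.get("GT")
                gt_str = "/".join("." if a is None else str(a) for a in gt) if gt else "./."
                ad = call.get("AD") or (0, 0)
                calls[sname] = SampleCall(
                    depth=int(call.get("DP") or 0),
                    alt_reads=int(ad[1] if len(ad) > 1 and ad[1] is not None else 0),
                    genotype=gt_str,
                    genotype_quality=float(call.get("GQ") or 0.0),
                )
            flags = {f for f in rec.filter.keys() if f not in ("PASS", ".")}
            records.append(
                VariantRecord(chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                              alt=rec.alts[0] if rec.alts else ".",
                              calls=calls, flags=flags, normal_sample=normal_sample)
            )
    return records
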