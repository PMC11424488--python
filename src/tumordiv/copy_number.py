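"""Copy-number inference from binned low-pass WGS log2 ratios.

Implements penalized piecewise-constant segmentation (single- and
multi-sample), an ASCAT-style purity/ploidy grid search restricted to total
copy number (no B-allele frequencies), integer copy-number calling, the
proportion of genome altered (PGA), focal-amplification detection, chromosome
arm gain/loss status, and the cfDNA fragment-size filter.

The mixture model throughout: a tumor fraction ``rho`` of cells at integer
copy number ``n`` mixed with diploid normal cells gives a log2 ratio

    r = log2((rho*n + 2*(1-rho)) / (rho*psi + 2*(1-rho)))

where ``psi`` is the tumor ploidy; inverting for ``n`` at a candidate
``(rho, psi)`` and scoring the distance to the nearest nonnegative integer is
the grid-search objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinProfile",
    "SegmentProfile",
    "AbsoluteFit",
    "SampleCN",
    "segment_bins",
    "fit_purity_ploidy",
    "fit_participant",
    "call_integer_cn",
    "compute_pga",
    "detect_focal_amplifications",
    "arm_status",
    "filter_fragment_sizes",
    "expected_log2",
    "implied_copy_number",
]

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass
class BinProfile:
    """Ordered genomic bins with a log2-ratio signal for one sample.

    Bins are 1-based inclusive intervals on a fixed genome-wide grid
    (nominally 500 kb). ``is_sex`` flags sex-chromosome bins, which carry a
    halved baseline in a male cohort.
    """

    sample_id: str
    chrom: np.ndarray  # str per bin
    start: np.ndarray  # int, 1-based
    end: np.ndarray  # int, inclusive
    log2: np.ndarray  # float per bin
    is_sex: np.ndarray = None  # bool per bin

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.log2 = np.asarray(self.log2, dtype=float)
        if self.is_sex is None:
            self.is_sex = np.array([c in SEX_CHROMS for c in self.chrom])
        self.is_sex = np.asarray(self.is_sex, dtype=bool)
        n = len(self.log2)
        if not (len(self.chrom) == len(self.start) == len(self.end) == n == len(self.is_sex)):
            raise ValueError("bin arrays must have equal length")
        for c in pd.unique(self.chrom):
            mask = self.chrom == c
            s, e = self.start[mask], self.end[mask]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] <= e[:-1]):
                raise ValueError(f"bins on {c} overlap or are unordered")
        if not np.all(np.isfinite(self.log2)):
            raise ValueError("log2 values must be finite after masking")

    @property
    def n_bins(self) -> int:
        return len(self.log2)

    def same_grid(self, other: "BinProfile") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "bin_index": np.arange(self.n_bins),
                "log2": self.log2,
            }
        )

    @classmethod
    def from_frame(cls, sample_id: str, df: pd.DataFrame) -> "BinProfile":
        return cls(
            sample_id=sample_id,
            chrom=df["chrom"].to_numpy(),
            start=df["start"].to_numpy(),
            end=df["end"].to_numpy(),
            log2=df["log2"].to_numpy(),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, sample_id: str, path) -> "BinProfile":
        return cls.from_frame(sample_id, pd.read_csv(path, sep="\t"))


@dataclass
class SegmentProfile:
    """Piecewise-constant segmentation of a :class:`BinProfile`.

    Segments are stored as half-open bin-index ranges ``[first_bin,
    last_bin]`` (inclusive) that partition the profile's bins in order.
    """

    sample_id: str
    chrom: np.ndarray  # str per segment
    first_bin: np.ndarray  # int bin index, inclusive
    last_bin: np.ndarray  # int bin index, inclusive
    mean_log2: np.ndarray
    n_bins: np.ndarray
    profile: Optional[BinProfile] = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.first_bin = np.asarray(self.first_bin, dtype=np.int64)
        self.last_bin = np.asarray(self.last_bin, dtype=np.int64)
        self.mean_log2 = np.asarray(self.mean_log2, dtype=float)
        self.n_bins = np.asarray(self.n_bins, dtype=np.int64)
        if np.any(self.n_bins < 1):
            raise ValueError("segments must contain at least one bin")

    @property
    def n_segments(self) -> int:
        return len(self.mean_log2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "chrom": self.chrom,
                "first_bin": self.first_bin,
                "last_bin": self.last_bin,
                "n_bins": self.n_bins,
                "mean_log2": self.mean_log2,
            }
        )


@dataclass
class AbsoluteFit:
    """Purity/ploidy solution from the grid search."""

    purity: float
    ploidy: float
    goodness: float
    manual_override: bool = False
    purity_unidentifiable: bool = False


@dataclass
class SampleCN:
    """Absolute copy number for one sample: segments, bins, fit and PGA."""

    segments: SegmentProfile
    fit: AbsoluteFit
    seg_cn: np.ndarray  # integer CN per segment
    bin_cn: np.ndarray  # integer CN per bin
    pga: float = field(default=np.nan)

    @property
    def sample_id(self) -> str:
        return self.segments.sample_id

    def to_seg_frame(self) -> pd.DataFrame:
        df = self.segments.to_frame()
        df["integer_cn"] = self.seg_cn
        return df


# ---------------------------------------------------------------------------
# mixture equation


def expected_log2(n, rho: float, psi: float):
    """Log2 ratio implied by integer CN ``n`` at purity ``rho``, ploidy ``psi``."""
    n = np.asarray(n, dtype=float)
    num = rho * n + 2.0 * (1.0 - rho)
    den = rho * psi + 2.0 * (1.0 - rho)
    return np.log2(np.maximum(num, 1e-10) / den)


def implied_copy_number(r, rho: float, psi: float):
    """Invert the mixture equation: fractional CN implied by log2 ratio ``r``."""
    r = np.asarray(r, dtype=float)
    return (np.exp2(r) * (rho * psi + 2.0 * (1.0 - rho)) - 2.0 * (1.0 - rho)) / rho


# ---------------------------------------------------------------------------
# segmentation


def _pcf_chromosome(y: np.ndarray, gamma: float) -> list[int]:
    """Optimal breakpoints for one chromosome by dynamic programming.

    ``y`` has shape (n_samples, n_bins). Minimizes total SSE around segment
    means, summed over samples, plus ``gamma`` per breakpoint (breakpoints
    shared across samples). Returns segment start indices (always includes 0).
    """
    n = y.shape[1]
    c1 = np.concatenate([np.zeros((y.shape[0], 1)), np.cumsum(y, axis=1)], axis=1)
    c2 = np.concatenate([np.zeros((y.shape[0], 1)), np.cumsum(y * y, axis=1)], axis=1)

    def seg_cost(i: int, j: np.ndarray) -> np.ndarray:
        # SSE of bins i..j-1 (i fixed, j vector), summed over samples
        length = (j - i).astype(float)
        s = c1[:, j] - c1[:, i : i + 1]
        ss = c2[:, j] - c2[:, i : i + 1]
        return np.sum(ss - s * s / length, axis=0)

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -gamma  # first segment carries no breakpoint penalty
    js = np.arange(1, n + 1)
    # best[j] = min_i best[i] + gamma + SSE(i..j)
    cost_rows = np.empty((n, n), dtype=float)
    for i in range(n):
        cost_rows[i, i:] = seg_cost(i, js[i:])
    for j in range(1, n + 1):
        cand = best[:j] + gamma + cost_rows[:j, j - 1]
        i = int(np.argmin(cand))
        best[j] = cand[i]
        prev[j] = i
    # backtrack
    starts = []
    j = n
    while j > 0:
        i = prev[j]
        starts.append(i)
        j = i
    return sorted(starts)


def _noise_scale(y: np.ndarray) -> float:
    """Per-sample noise SD estimate from first differences (MAD-based)."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.4826 / np.sqrt(2.0))


def segment_bins(
    profiles: BinProfile | Sequence[BinProfile], gamma: float = 15.0
) -> SegmentProfile | list[SegmentProfile]:
    """Penalized least-squares piecewise-constant segmentation.

    A single profile is segmented on its own; a list of profiles sharing a
    bin grid is segmented jointly with breakpoints shared across samples
    (multi-sample mode). ``gamma`` is the per-breakpoint penalty (15 for
    tissue, 10 for cfDNA) expressed in units of the per-sample noise
    variance: each profile is standardized by a MAD-based noise SD estimate
    before the fit, so gamma is comparable across samples of different
    quality. Noise-free profiles fall back to a vanishing penalty, which
    places breakpoints exactly at true copy-number steps and nowhere else.
    Chromosome boundaries are always breakpoints.
    """
    single = isinstance(profiles, BinProfile)
    plist = [profiles] if single else list(profiles)
    if not plist:
        raise ValueError("no profiles given")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    for p in plist[1:]:
        if not p.same_grid(plist[0]):
            raise ValueError("profiles are on mismatched bin grids")

    ref = plist[0]
    scales = np.array([_noise_scale(p.log2) for p in plist])
    eff_gamma = gamma
    if np.any(scales <= 0):
        scales = np.ones_like(scales)
        eff_gamma = 1e-9  # noise-free: any true step is worth splitting
    y_all = np.stack([p.log2 / s for p, s in zip(plist, scales)])
    chrom_ids = pd.unique(ref.chrom)
    seg_bounds: list[tuple[int, int]] = []  # global (first, last) inclusive
    for c in chrom_ids:
        idx = np.flatnonzero(ref.chrom == c)
        starts = _pcf_chromosome(y_all[:, idx], eff_gamma)
        bounds = starts + [len(idx)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_bounds.append((idx[a], idx[b - 1]))

    out = []
    for p in plist:
        first = np.array([a for a, _ in seg_bounds])
        last = np.array([b for _, b in seg_bounds])
        means = np.array([p.log2[a : b + 1].mean() for a, b in seg_bounds])
        out.append(
            SegmentProfile(
                sample_id=p.sample_id,
                chrom=ref.chrom[first],
                first_bin=first,
                last_bin=last,
                mean_log2=means,
                n_bins=last - first + 1,
                profile=p,
            )
        )
    return out[0] if single else out


def penalized_sse(segments: SegmentProfile, gamma: float) -> float:
    """Penalized objective of a segmentation in noise-standardized units."""
    p = segments.profile
    scale = _noise_scale(p.log2)
    if scale <= 0:
        scale, gamma = 1.0, 1e-9
    y = p.log2 / scale
    sse = 0.0
    for a, b in zip(segments.first_bin, segments.last_bin):
        seg = y[a : b + 1]
        sse += float(np.sum((seg - seg.mean()) ** 2))
    n_chroms = len(pd.unique(segments.chrom))
    return sse + gamma * (segments.n_segments - n_chroms)


# ---------------------------------------------------------------------------
# purity / ploidy grid search

_TISSUE_GRID = dict(rho=(0.10, 1.00), psi=(1.5, 5.5))
_CFDNA_GRID = dict(rho=(0.01, 1.00), psi=(1.5, 4.7))
RHO_STEP = 0.01
PSI_STEP = 0.01


def fit_purity_ploidy(
    segments: SegmentProfile,
    mode: str = "tissue",
    participant_context: Optional[Sequence[SegmentProfile]] = None,
    override: Optional[tuple[float, float]] = None,
    concordance_weight: float = 0.1,
    psi_range: Optional[tuple[float, float]] = None,
) -> AbsoluteFit:
    """Grid search for purity ``rho`` and ploidy ``psi``.

    Minimizes the segment-length-weighted mean squared distance of the
    implied fractional copy number to the nearest nonnegative integer.
    Tissue mode searches rho in [0.10, 1.00], psi in [1.5, 5.5]; cfDNA mode
    rho in [0.01, 1.00], psi in [1.5, 4.7] (both at 0.01 steps).

    If ``participant_context`` is given (other segmented samples of the same
    participant), the objective gains ``concordance_weight * (psi -
    median rounded context ploidy)**2``, nudging all samples of a participant
    toward a shared ploidy solution. ``override`` bypasses the search.
    """
    if override is not None:
        return AbsoluteFit(purity=float(override[0]), ploidy=float(override[1]),
                           goodness=np.nan, manual_override=True)
    if segments.n_segments == 0:
        raise ValueError("empty segment profile")
    grid = {"tissue": _TISSUE_GRID, "cfdna": _CFDNA_GRID}[mode]
    rho_lo, rho_hi = grid["rho"]
    psi_lo, psi_hi = psi_range if psi_range is not None else grid["psi"]
    rhos = np.round(np.arange(rho_lo, rho_hi + RHO_STEP / 2, RHO_STEP), 10)
    psis = np.round(np.arange(psi_lo, psi_hi + PSI_STEP / 2, PSI_STEP), 10)
    if rhos.size == 0 or psis.size == 0:
        raise ValueError("empty purity/ploidy grid after range restriction")

    goodness = _goodness_surface(segments, rhos, psis)

    if participant_context:
        ctx = [_context_rounded_ploidy(s) for s in participant_context]
        psi_ctx = float(np.median(ctx))
        goodness = goodness + concordance_weight * (psis[None, :] - psi_ctx) ** 2

    gmin = goodness.min()
    near = np.argwhere(goodness <= gmin + 1e-12)
    # tie-break: psi closest to 2, then highest purity
    order = np.lexsort((-rhos[near[:, 0]], np.abs(psis[near[:, 1]] - 2.0)))
    gi, gj = near[order[0]]
    unident = bool(np.ptp(rhos[near[:, 0]]) > 0.5) if len(near) > 1 else False
    return AbsoluteFit(
        purity=float(rhos[gi]),
        ploidy=float(psis[gj]),
        goodness=float(goodness[gi, gj]),
        purity_unidentifiable=bool(unident),
    )


def _context_rounded_ploidy(segments: SegmentProfile) -> float:
    fit = fit_purity_ploidy(segments)
    return float(np.round(fit.ploidy))


def _goodness_surface(segments: SegmentProfile, rhos: np.ndarray, psis: np.ndarray) -> np.ndarray:
    w = segments.n_bins.astype(float)
    w = w / w.sum()
    two_r = np.exp2(segments.mean_log2)[None, None, :]
    rho_g = rhos[:, None, None]
    psi_g = psis[None, :, None]
    n = (two_r * (rho_g * psi_g + 2 * (1 - rho_g)) - 2 * (1 - rho_g)) / rho_g
    dist = (n - np.clip(np.round(n), 0, None)) ** 2
    return np.tensordot(dist, w, axes=([2], [0]))


def fit_participant(
    segments_list: Sequence[SegmentProfile],
    mode: str = "tissue",
    ploidy_parsimony: float = 0.01,
    refine_window: float = 0.3,
) -> list[AbsoluteFit]:
    """Multi-sample purity/ploidy search for one participant.

    All samples of a participant share a tumor ploidy up to small
    normalization shifts, so the ploidy axis is searched jointly: for each
    candidate psi the per-sample best-purity goodness is summed, a weak
    parsimony penalty (``ploidy_parsimony`` per ploidy unit) disfavors
    genome-doubled lattice solutions that fit noise spuriously well, and
    each sample is then refined within ``refine_window`` of the shared
    optimum. This leverages multiple sampling to resolve the purity/ploidy
    ambiguities that defeat single-sample grid searches at low purity.
    """
    if not segments_list:
        raise ValueError("no segment profiles given")
    grid = {"tissue": _TISSUE_GRID, "cfdna": _CFDNA_GRID}[mode]
    rhos = np.round(np.arange(grid["rho"][0], grid["rho"][1] + RHO_STEP / 2, RHO_STEP), 10)
    psis = np.round(np.arange(grid["psi"][0], grid["psi"][1] + PSI_STEP / 2, PSI_STEP), 10)
    surfaces = [_goodness_surface(s, rhos, psis) for s in segments_list]
    total = np.sum([g.min(axis=0) for g in surfaces], axis=0)
    obj = total / len(segments_list) + ploidy_parsimony * psis
    psi_star = float(psis[int(np.argmin(obj))])
    fits = []
    mask = np.abs(psis - psi_star) <= refine_window
    for g in surfaces:
        sub = g[:, mask]
        gmin = sub.min()
        near = np.argwhere(sub <= gmin + 1e-12)
        order = np.lexsort((-rhos[near[:, 0]], np.abs(psis[mask][near[:, 1]] - psi_star)))
        i, j = near[order[0]]
        fits.append(AbsoluteFit(purity=float(rhos[i]), ploidy=float(psis[mask][j]),
                                goodness=float(sub[i, j])))
    return fits


# ---------------------------------------------------------------------------
# integer CN, PGA, focal amplifications, arm status


def call_integer_cn(segments: SegmentProfile, fit: AbsoluteFit) -> SampleCN:
    """Round the implied fractional CN of each segment to an integer (floor 0)."""
    n = implied_copy_number(segments.mean_log2, fit.purity, fit.ploidy)
    seg_cn = np.clip(np.round(n), 0, None).astype(int)
    bin_cn = np.empty(int(segments.last_bin.max()) + 1, dtype=int)
    for a, b, cn in zip(segments.first_bin, segments.last_bin, seg_cn):
        bin_cn[a : b + 1] = cn
    sample = SampleCN(segments=segments, fit=fit, seg_cn=seg_cn, bin_cn=bin_cn)
    sample.pga = compute_pga(sample)
    return sample


def baseline_cn(fit: AbsoluteFit, is_sex) -> np.ndarray:
    """Baseline integer CN per bin: round(psi), halved on sex chromosomes."""
    base = np.full(len(is_sex), int(np.round(fit.ploidy)))
    base[np.asarray(is_sex, dtype=bool)] = int(np.round(fit.ploidy / 2.0))
    return base


def compute_pga(sample: SampleCN) -> float:
    """Fraction of bins whose CN deviates from the rounded baseline ploidy.

    Sex-chromosome bins are compared to half the baseline (male cohort), so a
    normal male X at CN round(psi/2) does not count as altered.
    """
    is_sex = sample.segments.profile.is_sex if sample.segments.profile is not None else np.zeros(
        len(sample.bin_cn), dtype=bool
    )
    base = baseline_cn(sample.fit, is_sex)
    return float(np.mean(sample.bin_cn != base))


def detect_focal_amplifications(
    samples: Sequence[SampleCN],
    oncogene_regions: Optional[pd.DataFrame] = None,
    z_threshold: float = 3.0,
    min_bins: int = 3,
    max_bins: int = 20,
) -> pd.DataFrame:
    """Flag short high-z segments as focal amplifications.

    A segment is called when its z score — computed from the sample's
    bin-level log2 mean and SD — exceeds ``z_threshold`` and it spans more
    than ``min_bins`` and fewer than ``max_bins`` bins (strict bounds:
    a 3-bin or 20-bin segment is not called).

    ``oncogene_regions`` is an optional BED-like frame (chrom, start, end,
    name); overlapping calls are annotated with the gene name.
    """
    rows = []
    for s in samples:
        prof = s.segments.profile
        if prof is None:
            raise ValueError("segment profile lacks its bin profile")
        mu, sd = float(prof.log2.mean()), float(prof.log2.std())
        if sd == 0:
            raise ValueError(f"degenerate profile (zero bin-level sd): {s.sample_id}")
        for a, b, m, nb in zip(
            s.segments.first_bin, s.segments.last_bin, s.segments.mean_log2, s.segments.n_bins
        ):
            z = (m - mu) / sd
            if z > z_threshold and min_bins < nb < max_bins:
                chrom = prof.chrom[a]
                start, end = int(prof.start[a]), int(prof.end[b])
                genes = ""
                if oncogene_regions is not None:
                    hits = oncogene_regions[
                        (oncogene_regions["chrom"] == chrom)
                        & (oncogene_regions["start"] <= end)
                        & (oncogene_regions["end"] >= start)
                    ]
                    genes = ",".join(hits["name"].astype(str))
                rows.append(
                    dict(sample=s.sample_id, chrom=chrom, start=start, end=end,
                         n_bins=int(nb), z=float(z), genes=genes)
                )
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "n_bins", "z", "genes"])


def arm_status(sample: SampleCN, arm_table: pd.DataFrame) -> pd.DataFrame:
    """Per-arm gain/loss/neutral from the median bin CN vs the baseline.

    ``arm_table`` columns: chrom, arm, first_bin, last_bin (global bin
    indices, inclusive).
    """
    is_sex = sample.segments.profile.is_sex
    base = baseline_cn(sample.fit, is_sex)
    rows = []
    for _, r in arm_table.iterrows():
        a, b = int(r["first_bin"]), int(r["last_bin"])
        med = float(np.median(sample.bin_cn[a : b + 1]))
        arm_base = float(np.median(base[a : b + 1]))
        label = "gain" if med > arm_base else ("loss" if med < arm_base else "neutral")
        rows.append(dict(sample=sample.sample_id, chrom=r["chrom"], arm=r["arm"],
                         median_cn=med, baseline=arm_base, status=label))
    return pd.DataFrame(rows)


def filter_fragment_sizes(fragments: pd.DataFrame, lo: int = 90, hi: int = 150) -> pd.DataFrame:
    """Keep cfDNA fragments with insert size in [lo, hi] (inclusive bounds)."""
    keep = (fragments["insert_size"] >= lo) & (fragments["insert_size"] <= hi)
    return fragments[keep].reset_index(drop=True)
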