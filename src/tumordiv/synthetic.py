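"""Synthetic multiregion cohorts with recorded ground truth.

Every input the pipeline consumes can be generated here: binned log2-ratio
profiles under the purity/ploidy mixture model with an explicit clone tree,
classified cell point patterns with spatially structured Gleason and immune
labels, multi-sample variant tables with binomial read counts, and survival
records with metric-linked hazards. All generators are deterministic given
their seed.

The copy-number forward model: a clone's integer CN per bin is obtained by
applying its root-to-leaf event list (contiguous +/-1 runs, floor 0, events
on an absorbed zero bin rejected) to a baseline of round(ploidy) (halved on
sex chromosomes); a sample's log2 ratio is the mixture equation

    r = log2((rho*n + 2*(1-rho)) / (rho*psi + 2*(1-rho)))

plus iid Gaussian noise, then median-centred as in the low-pass WGS
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .copy_number import BinProfile, expected_log2

__all__ = [
    "CloneNode",
    "SimCNConfig",
    "SimTruth",
    "default_arm_table",
    "default_clone_tree",
    "simulate_cn_cohort",
    "simulate_cell_slide",
    "simulate_label_map",
    "simulate_variant_table",
    "simulate_survival_cohort",
]

BIN_WIDTH = 500_000


@dataclass
class CloneNode:
    """A clone in the simulated tree; ``events`` are (first_bin, last_bin,
    delta) applied on the branch leading into this clone."""

    name: str
    events: list = field(default_factory=list)
    children: list = field(default_factory=list)

    def leaves(self) -> list:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()


def default_arm_table(n_bins: int, n_autosomes: int = 4, include_x: bool = True) -> pd.DataFrame:
    """Evenly partition ``n_bins`` into p/q arms of a small synthetic genome."""
    n_chroms = n_autosomes + (1 if include_x else 0)
    per_chrom = n_bins // n_chroms
    rows = []
    pos = 0
    for i in range(n_chroms):
        chrom = "chrX" if (include_x and i == n_chroms - 1) else f"chr{i + 1}"
        size = per_chrom if i < n_chroms - 1 else n_bins - pos
        half = size // 2
        rows.append(dict(chrom=chrom, arm="p", first_bin=pos, last_bin=pos + half - 1))
        rows.append(dict(chrom=chrom, arm="q", first_bin=pos + half, last_bin=pos + size - 1))
        pos += size
    return pd.DataFrame(rows)


def default_clone_tree(n_bins: int) -> CloneNode:
    """Two-clone tree: one clonal (truncal) loss plus a private gain/loss each.

    Event spans are fixed fractions of the genome so tests can pin the
    expected phylogeny event counts.
    """
    w = n_bins // 20
    trunk = CloneNode(
        name="trunk",
        events=[(0, 2 * w - 1, -1)],  # clonal loss on chr1p
        children=[
            CloneNode(name="cloneA", events=[(4 * w, 5 * w - 1, +1)]),
            CloneNode(name="cloneB", events=[(8 * w, 9 * w - 1, -1)]),
        ],
    )
    return trunk


@dataclass
class SimCNConfig:
    """Study conditions for the copy-number cohort generator."""

    n_participants: int = 20
    samples_per_participant: tuple = (3, 6)
    n_bins: int = 400
    arm_table: Optional[pd.DataFrame] = None
    clone_tree: Optional[CloneNode] = None
    purity_range: tuple = (0.3, 0.8)
    ploidy_values: Sequence[float] = (2.0,)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm_table is None:
            self.arm_table = default_arm_table(self.n_bins)
        if self.clone_tree is None:
            self.clone_tree = default_clone_tree(self.n_bins)
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(p < 1 for p in self.ploidy_values):
            raise ValueError("ploidy values must be >= 1")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators (seed-reproducible)."""

    bin_cn: dict = field(default_factory=dict)  # (participant, sample) -> int array
    purity: dict = field(default_factory=dict)
    ploidy: dict = field(default_factory=dict)
    clone: dict = field(default_factory=dict)  # (participant, sample) -> clone name
    branch_events: dict = field(default_factory=dict)  # participant -> {clone: n_events}
    log_hazard: dict = field(default_factory=dict)  # participant -> float


def _bin_grid(n_bins: int, arm_table: pd.DataFrame):
    chrom = np.empty(n_bins, dtype=object)
    start = np.empty(n_bins, dtype=np.int64)
    for c, grp in arm_table.groupby("chrom", sort=False):
        a, b = int(grp["first_bin"].min()), int(grp["last_bin"].max())
        chrom[a : b + 1] = c
        start[a : b + 1] = np.arange(b - a + 1) * BIN_WIDTH + 1
    end = start + BIN_WIDTH - 1
    return chrom, start, end


def _apply_events(cn: np.ndarray, events) -> np.ndarray:
    out = cn.copy()
    for first, last, delta in events:
        region = out[first : last + 1]
        if np.any(region == 0):
            raise ValueError(
                f"event ({first}, {last}, {delta:+d}) touches an absorbed CN-0 bin"
            )
        out[first : last + 1] = np.maximum(0, region + delta)
    return out


def _clone_profiles(tree: CloneNode, baseline: np.ndarray) -> dict:
    """Integer CN per clone by applying event lists along root-to-node paths."""
    profiles = {}

    def walk(node: CloneNode, cn: np.ndarray) -> None:
        cn = _apply_events(cn, node.events)
        profiles[node.name] = cn
        for child in node.children:
            walk(child, cn)

    walk(tree, baseline)
    return profiles


def simulate_cn_cohort(config: SimCNConfig):
    """Generate multiregion bin profiles for a cohort.

    Returns ``(profiles, truth)`` where ``profiles`` maps participant id to a
    list of :class:`BinProfile` and ``truth`` records per-sample integer CN,
    purity, ploidy and clone assignment.
    """
    rng = np.random.default_rng(config.seed)
    chrom, start, end = _bin_grid(config.n_bins, config.arm_table)
    is_sex = np.array([c in ("chrX", "chrY", "X", "Y") for c in chrom])

    truth = SimTruth()
    profiles: dict = {}
    leaves = config.clone_tree.leaves()
    for pi in range(config.n_participants):
        pid = f"P{pi:03d}"
        psi = float(rng.choice(np.asarray(config.ploidy_values, dtype=float)))
        baseline = np.where(is_sex, int(round(psi / 2)), int(round(psi))).astype(int)
        clone_cn = _clone_profiles(config.clone_tree, baseline)
        truth.branch_events[pid] = {
            node.name: len(node.events) for node in config.clone_tree.iter_nodes()
        }
        lo, hi = config.samples_per_participant
        n_samples = int(rng.integers(lo, hi + 1))
        plist = []
        for si in range(n_samples):
            sid = f"{pid}_S{si}"
            clone = leaves[si % len(leaves)]
            rho = float(rng.uniform(*config.purity_range))
            cn = clone_cn[clone.name]
            r = expected_log2(cn, rho, psi)
            if config.noise_sd > 0:
                r = r + rng.normal(0.0, config.noise_sd, size=config.n_bins)
            r = r - np.median(r)
            plist.append(
                BinProfile(sample_id=sid, chrom=chrom, start=start, end=end,
                           log2=r, is_sex=is_sex)
            )
            truth.bin_cn[(pid, sid)] = cn.copy()
            truth.purity[(pid, sid)] = rho
            truth.ploidy[(pid, sid)] = psi
            truth.clone[(pid, sid)] = clone.name
        profiles[pid] = plist
    return profiles, truth


# ---------------------------------------------------------------------------
# cell slides and label maps


def simulate_cell_slide(
    n_cells: int,
    layout: str = "segregated",
    patterns: tuple = (3, 4),
    immune_fraction: float = 0.1,
    stromal_fraction: float = 0.2,
    immune_layout: str = "uniform",
    checker_k: int = 100,
    mixing: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Classified cell point pattern on the unit square.

    ``layout`` places the Gleason label of epithelial cells: ``segregated``
    assigns ``patterns[0]`` to the left half-plane and ``patterns[1]`` to the
    right; ``interleaved`` uses a fine ``checker_k`` x ``checker_k``
    checkerboard (finer than any quadrat scheme in use, so both patterns mix
    within every quadrat); ``blend`` labels each epithelial cell by the
    checkerboard with probability ``mixing`` and by the half-plane otherwise,
    giving a tunable segregated-to-interleaved continuum; ``single`` uses
    ``patterns[0]`` everywhere. Immune cells are uniform, or confined to a
    lower-left corner kept free of other cells (``immune_layout='corner'``).
    Columns: x, y, type, gleason_label (NaN for non-epithelial).
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells to seed quadrats")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n_cells)
    y = rng.uniform(0, 1, n_cells)
    u = rng.uniform(0, 1, n_cells)
    ctype = np.where(
        u < immune_fraction, "immune",
        np.where(u < immune_fraction + stromal_fraction, "stromal", "epithelial"),
    )
    if immune_layout == "corner":
        # immune cells occupy a corner niche; other cells vacate it
        im = ctype == "immune"
        x[im] = rng.uniform(0, 0.15, im.sum())
        y[im] = rng.uniform(0, 0.15, im.sum())
        other = ~im & (x < 0.15) & (y < 0.15)
        x[other] = rng.uniform(0.15, 1.0, other.sum())
        y[other] = rng.uniform(0, 1.0, other.sum())

    label = np.full(n_cells, np.nan)
    epi = ctype == "epithelial"
    checker = ((np.floor(x * checker_k) + np.floor(y * checker_k)) % 2 == 0)
    halfplane = x < 0.5
    if layout == "segregated":
        label[epi] = np.where(halfplane[epi], patterns[0], patterns[1])
    elif layout == "interleaved":
        label[epi] = np.where(checker[epi], patterns[0], patterns[1])
    elif layout == "blend":
        use_checker = rng.uniform(0, 1, n_cells) < mixing
        fine = np.where(use_checker, checker, halfplane)
        label[epi] = np.where(fine[epi], patterns[0], patterns[1])
    elif layout == "single":
        label[epi] = patterns[0]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return pd.DataFrame({"x": x, "y": y, "type": ctype, "gleason_label": label})


def simulate_label_map(
    shape: tuple = (100, 100),
    pattern_fractions: Optional[dict] = None,
    benign_fraction: float = 0.0,
    layout: str = "bands",
    seed: int = 0,
) -> np.ndarray:
    """Integer Gleason label raster (0 no-gland, 1 benign, 3/4/5 patterns).

    ``pattern_fractions`` maps pattern (3/4/5) to its fraction of the tumor
    area; ``layout='bands'`` lays patterns out in vertical bands,
    ``'scattered'`` assigns pixels independently at random.
    """
    if pattern_fractions is None:
        pattern_fractions = {4: 1.0}
    h, w = shape
    raster = np.zeros(shape, dtype=int)
    n_benign = int(round(benign_fraction * w))
    raster[:, :n_benign] = 1
    tumor_w = w - n_benign
    labels = list(pattern_fractions)
    fracs = np.array([pattern_fractions[k] for k in labels], dtype=float)
    fracs = fracs / fracs.sum()
    if layout == "bands":
        widths = np.round(np.cumsum(fracs) * tumor_w).astype(int)
        prev = 0
        for lab, cut in zip(labels, widths):
            raster[:, n_benign + prev : n_benign + cut] = lab
            prev = cut
    elif layout == "scattered":
        rng = np.random.default_rng(seed)
        raster[:, n_benign:] = rng.choice(labels, size=(h, tumor_w), p=fracs)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return raster


# ---------------------------------------------------------------------------
# variant tables


def simulate_variant_table(
    n_sites: int,
    clonal_fraction: float = 0.5,
    purity: float = 0.6,
    depth: int = 200,
    seed: int = 0,
    n_tumor_samples: int = 3,
    cn_total: int = 2,
    multiplicity: int = 1,
    error_rate: float = 0.001,
) -> pd.DataFrame:
    """Multi-sample somatic variant table with truth labels.

    Clonal sites are present in every tumor sample; subclonal sites in a
    random strict subset. The expected VAF where present follows the
    purity/copy-number model ``m*rho / (rho*cn + 2*(1-rho))``; read counts
    are binomial at ``depth``. A matched normal carries only sequencing
    error. Long format: one row per (site, sample).
    """
    rng = np.random.default_rng(seed)
    vaf_present = multiplicity * purity / (purity * cn_total + 2 * (1 - purity))
    rows = []
    tumor_ids = [f"T{i}" for i in range(n_tumor_samples)]
    for s in range(n_sites):
        clonal = bool(rng.uniform() < clonal_fraction)
        if clonal:
            present = np.ones(n_tumor_samples, dtype=bool)
        else:
            k = int(rng.integers(1, n_tumor_samples))  # strict subset
            present = np.zeros(n_tumor_samples, dtype=bool)
            present[rng.choice(n_tumor_samples, size=k, replace=False)] = True
        for tid, pres in zip(tumor_ids, present):
            vaf = vaf_present if pres else error_rate
            alt = int(rng.binomial(depth, vaf))
            rows.append(
                dict(site_id=s, chrom="chr1", pos=1000 + s, ref="A", alt_base="T",
                     sample=tid, depth=depth, alt_reads=alt,
                     true_clonal=clonal, true_present=pres,
                     true_multiplicity=multiplicity)
            )
        alt_n = int(rng.binomial(depth, error_rate))
        rows.append(
            dict(site_id=s, chrom="chr1", pos=1000 + s, ref="A", alt_base="T",
                 sample="normal", depth=depth, alt_reads=alt_n,
                 true_clonal=clonal, true_present=False,
                 true_multiplicity=0)
        )
    df = pd.DataFrame(rows)
    df["vaf"] = df["alt_reads"] / df["depth"]
    return df


# ---------------------------------------------------------------------------
# survival


def simulate_survival_cohort(
    metrics: pd.DataFrame,
    beta: dict,
    censor_rate: float = 0.3,
    baseline_hazard: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with hazard proportional to exp(beta . x).

    ``metrics`` holds one row per participant with the covariate columns
    named in ``beta``. Censoring is independent exponential, calibrated so
    roughly ``censor_rate`` of baseline-hazard subjects are censored;
    ``censor_rate=0`` disables it. Returns the metrics frame with ``time``
    and ``event`` columns appended.
    """
    rng = np.random.default_rng(seed)
    lp = np.zeros(len(metrics))
    for name, b in beta.items():
        lp = lp + b * metrics[name].to_numpy(dtype=float)
    hazard = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(metrics))
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
    else:
        time = t_event
        event = np.ones(len(metrics), dtype=bool)
    out = metrics.copy()
    out["time"] = time
    out["event"] = event.astype(int)
    out["true_log_hazard"] = lp
    return out
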