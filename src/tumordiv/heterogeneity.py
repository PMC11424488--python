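"""Participant-level genomic diversity metrics.

All metrics summarize a participant's multiregion low-pass WGS samples:
mean/max proportion of genome altered (PGA), the Spearman divergence of raw
bin-level log2 ratios, lossness (interstitial sub-ploidy segment burden) and
the Joint Diversity combination of genomic and morphological heterogeneity.
Samples with PGA below 0.01 carry essentially no somatic signal and are
excluded where the metric definition requires it.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .copy_number import BinProfile, SampleCN

__all__ = [
    "summarize_pga",
    "spearman_divergence",
    "lossness",
    "joint_diversity",
    "participant_metrics",
]

MIN_PGA = 0.01


def summarize_pga(samples: Sequence[SampleCN], min_pga: float = MIN_PGA):
    """(mPGA, max_PGA) for one participant.

    mPGA averages PGA over samples with PGA >= ``min_pga`` (near-flat
    profiles are treated as tumor-poor and excluded); max PGA is taken over
    all samples. Returns (None, max) when no sample qualifies.
    """
    pgas = np.array([s.pga for s in samples], dtype=float)
    max_pga = float(pgas.max()) if len(pgas) else None
    qual = pgas[pgas >= min_pga]
    mpga = float(qual.mean()) if len(qual) else None
    return mpga, max_pga


def spearman_divergence(
    profiles: Sequence[BinProfile],
    pga: Optional[Sequence[float]] = None,
    min_pga: float = MIN_PGA,
) -> Optional[float]:
    """1 minus the mean pairwise Spearman correlation of bin log2 ratios.

    Ranges over [0, 2]: 0 for identical profiles, 2 for perfectly
    anti-correlated ones. Samples with PGA < ``min_pga`` are excluded when
    ``pga`` is supplied; fewer than two qualifying samples yield None with a
    warning. Ties receive average ranks.
    """
    if pga is not None:
        profiles = [p for p, g in zip(profiles, pga) if g >= min_pga]
    if len(profiles) < 2:
        warnings.warn("fewer than 2 qualifying samples; Spearman divergence undefined")
        return None
    rhos = []
    for a, b in itertools.combinations(profiles, 2):
        rho, _ = stats.spearmanr(a.log2, b.log2)
        rhos.append(rho)
    return float(1.0 - np.mean(rhos))


def lossness(sample: SampleCN, arm_table: pd.DataFrame,
             denominator: str = "all") -> float:
    """Fraction of segments that are sub-ploidy and interstitial.

    A segment counts toward the numerator when its integer CN is below the
    sample's rounded ploidy and it contains neither the first nor the last
    bin of its chromosome arm (i.e. it touches no telomeric or centromeric
    arm-end bin). ``denominator='all'`` divides by all segments of the
    sample; ``'sub_ploidy'`` divides by the sub-ploidy segments only (the
    alternative reading of the definition).
    """
    base = int(round(sample.fit.ploidy))
    arm_ends = set(arm_table["first_bin"]) | set(arm_table["last_bin"])
    n_interstitial_loss = 0
    n_loss = 0
    for a, b, cn in zip(sample.segments.first_bin, sample.segments.last_bin, sample.seg_cn):
        if cn < base:
            n_loss += 1
            covered = set(range(int(a), int(b) + 1))
            if not (covered & arm_ends):
                n_interstitial_loss += 1
    denom = sample.segments.n_segments if denominator == "all" else n_loss
    return 0.0 if denom == 0 else n_interstitial_loss / denom


def joint_diversity(spearman: Optional[float],
                    gleason_morisita_patient: Optional[float]) -> Optional[float]:
    """Geometric mean of Spearman divergence and patient-level Gleason Morisita."""
    if spearman is None or gleason_morisita_patient is None:
        return None
    return float(np.sqrt(spearman * gleason_morisita_patient))


def participant_metrics(
    participant_id: str,
    samples: Sequence[SampleCN],
    profiles: Sequence[BinProfile],
    arm_table: pd.DataFrame,
    tree_events: Optional[tuple] = None,
    sidedness_lambda: Optional[float] = None,
    gleason_morisita_patient: Optional[float] = None,
    mean_gleason_morisita: Optional[float] = None,
    continuous_gleason: Optional[float] = None,
    clinical: Optional[dict] = None,
) -> dict:
    """Assemble one ParticipantMetrics row (dict) from computed pieces.

    ``tree_events`` is the (total, subclonal, subclonality) triple from the
    participant's event tree, or None when no tree could be built.
    """
    pgas = [s.pga for s in samples]
    mpga, max_pga = summarize_pga(samples)
    spear = spearman_divergence(profiles, pga=pgas)
    mean_lossness = float(np.mean([lossness(s, arm_table) for s in samples]))
    total = subclonal = subclonality = None
    if tree_events is not None:
        total, subclonal, subclonality = tree_events
    row = {
        "participant_id": participant_id,
        "mPGA": mpga,
        "max_PGA": max_pga,
        "spearman": spear,
        "lossness": mean_lossness,
        "total_events": total,
        "subclonal_events": subclonal,
        "subclonality": subclonality,
        "sidedness_lambda": sidedness_lambda,
        "gleason_morisita_patient": gleason_morisita_patient,
        "mean_gleason_morisita": mean_gleason_morisita,
        "continuous_gleason": continuous_gleason,
        "joint_diversity": joint_diversity(spear, gleason_morisita_patient),
        "n_samples_cn": int(sum(g >= MIN_PGA for g in pgas)),
    }
    if clinical:
        row.update(clinical)
    return row
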