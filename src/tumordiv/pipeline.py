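"""End-to-end driver: bin profiles to participant-level metric rows.

Chains segmentation, the multi-sample purity/ploidy search, integer CN
calling, the diversity metrics and the event phylogeny for each participant.
The analysis scripts and the acceptance checks both run through this module
so there is a single code path from raw profiles to metrics.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import copy_number as cn
from . import heterogeneity as het
from . import phylogeny as phy

__all__ = ["call_participant_cn", "participant_summary", "cohort_metrics"]


def call_participant_cn(profiles: Sequence[cn.BinProfile], gamma: float = 15.0,
                        mode: str = "tissue") -> list[cn.SampleCN]:
    """Segment jointly and call absolute CN for one participant's samples."""
    segs = cn.segment_bins(list(profiles), gamma=gamma)
    fits = cn.fit_participant(segs, mode=mode)
    return [cn.call_integer_cn(s, f) for s, f in zip(segs, fits)]


def participant_summary(
    participant_id: str,
    profiles: Sequence[cn.BinProfile],
    arm_table: pd.DataFrame,
    locations: Optional[dict] = None,
    gamma: float = 15.0,
    **extra,
) -> dict:
    """One ParticipantMetrics row from raw bin profiles.

    ``locations`` (sample id -> side label) enables the sidedness lambda;
    ``extra`` passes morphology metrics and clinical covariates through to
    the row.
    """
    samples = call_participant_cn(profiles, gamma=gamma)
    tree = phy.build_event_tree(samples)
    events = phy.count_events(tree) if tree is not None else None
    lam = None
    if tree is not None and locations is not None and len(tree.sample_ids) >= 3:
        sig = phy.sidedness_signal(tree, locations)
        if sig.status == "ok":
            lam = sig.lambda_
    return het.participant_metrics(
        participant_id, samples, list(profiles), arm_table,
        tree_events=events, sidedness_lambda=lam, **extra,
    )


def cohort_metrics(profiles_by_participant: dict, arm_table: pd.DataFrame,
                   gamma: float = 15.0) -> pd.DataFrame:
    """ParticipantMetrics table for a whole cohort of bin profiles."""
    rows = [
        participant_summary(pid, plist, arm_table, gamma=gamma)
        for pid, plist in profiles_by_participant.items()
    ]
    return pd.DataFrame(rows)
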