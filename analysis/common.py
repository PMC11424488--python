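"""Shared study conditions and paths for the analysis scripts.

The synthetic cohort emulates a multiregion biopsy study: 12 participants,
3-6 regions each, 400 500-kb bins over four autosomes plus chrX, diploid
baseline with a truncal loss and two subclone-private events, biopsy purity
0.3-0.8, log2-ratio noise SD 0.1. Slides pair each participant with a
morphology section whose pattern mixing is tied to the participant's
genomic divergence, so the outcome stage has a real signal to find.
"""

from pathlib import Path

from tumordiv import synthetic

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 42

COHORT = synthetic.SimCNConfig(
    n_participants=12,
    samples_per_participant=(3, 6),
    n_bins=400,
    purity_range=(0.3, 0.8),
    ploidy_values=(2.0,),
    noise_sd=0.1,
    seed=SEED,
)

# side assignment by clone: subclones occupy opposite lobes, so sidedness
# should track the phylogeny (high Pagel's lambda)
CLONE_SIDE = {"trunk": "middle", "cloneA": "right", "cloneB": "left"}


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
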