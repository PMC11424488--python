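"""Generate the synthetic multiregion cohort and write its raw inputs.

Writes per-sample bin-profile TSVs, the arm table, and a truth summary so the
later stages can be checked against known ground truth.
"""

import pandas as pd

from common import COHORT, outdir
from tumordiv import synthetic


def main() -> None:
    out = outdir("01_cohort")
    profiles, truth = synthetic.simulate_cn_cohort(COHORT)

    n_samples = 0
    truth_rows = []
    for pid, plist in profiles.items():
        for p in plist:
            p.write_tsv(out / f"{p.sample_id}.bins.tsv")
            truth_rows.append({
                "participant": pid,
                "sample": p.sample_id,
                "true_purity": truth.purity[(pid, p.sample_id)],
                "true_ploidy": truth.ploidy[(pid, p.sample_id)],
                "clone": truth.clone[(pid, p.sample_id)],
            })
            n_samples += 1
    COHORT.arm_table.to_csv(out / "arm_table.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)

    print(f"simulated {len(profiles)} participants, {n_samples} samples, "
          f"{COHORT.n_bins} bins each (noise sd {COHORT.noise_sd})")
    print(f"wrote bin profiles and truth table to {out}")


if __name__ == "__main__":
    main()
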