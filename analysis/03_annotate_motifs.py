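#!/usr/bin/env python
"""Scan consensus peaks for each TF's consensus binding motif and split them
into motif-bearing (TF_TFBS) and motif-lacking (TF_noTFBS) subsets.

The focal TF uses the RUNX consensus RCCRCA (8 words over both strands); the
partner TFs use the package's placeholder consensi. Writes per-TF fractions
to results/motif_fractions.tsv.
"""

import argparse
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from hctcall.study import StudyConfig, build_study, run_pipeline


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    study = build_study(args.seed, StudyConfig())
    result = run_pipeline(study)

    rows = []
    n_tfbs = len(result.focal_tfbs)
    n_total = n_tfbs + len(result.focal_notfbs)
    rows.append({"tf": "Runx3", "n_consensus": n_total, "n_with_motif": n_tfbs,
                 "fraction": n_tfbs / n_total})
    for tf, tfbs in result.partner_tfbs.items():
        total = len(result.consensus[tf])
        rows.append({"tf": tf, "n_consensus": total, "n_with_motif": len(tfbs),
                     "fraction": len(tfbs) / total})
    frame = pd.DataFrame(rows)
    root = os.path.join(os.path.dirname(__file__), "..")
    out = os.path.join(root, "results", "motif_fractions.tsv")
    os.makedirs(os.path.dirname(out), exist_ok=True)
    frame.to_csv(out, sep="\t", index=False, float_format="%.4f")

    print(frame.to_string(index=False))
    planted = study.truth.planted_sites["Runx3"]
    planted_frac = sum(s.has_motif for s in planted) / len(planted)
    print(f"\nObserved focal motif fraction {n_tfbs/n_total:.3f} vs planted "
          f"site-level fraction {planted_frac:.3f} (generator target 0.71 on "
          f"background sites; direct-target sites are forced). Table in {out}")


if __name__ == "__main__":
    main()
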