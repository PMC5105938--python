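#!/usr/bin/env python
"""Optional: evaluate the pipeline on a downloaded Apnea-ECG record.

This script is not part of the test suite; it requires a WFDB record
(header + format-16 signal + minute-wise apnea annotations) downloaded
from the Physionet Apnea-ECG database, e.g.:

    https://physionet.org/content/apnea-ecg/   (records a01..c10, .apn files)

Usage:
    python scripts/run_physionet.py --record /path/to/a01 [--out bundle/]
"""

from __future__ import annotations

import argparse
import json
import os
import sys
import warnings

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from osaprog.io_formats import read_wfdb_apnea_record  # noqa: E402
from osaprog.pipeline import PipelineConfig, run_pipeline  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--record", required=True,
                    help="record path without extension (expects .hea/.dat/.apn)")
    ap.add_argument("--channel", type=int, default=0)
    ap.add_argument("--annotations", default=None)
    ap.add_argument("--out", default=None, help="bundle output directory")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    series = read_wfdb_apnea_record(args.record, args.channel, args.annotations)
    print(f"record {series.record_id}: {series.n_beats} beats, "
          f"{series.duration_min} min")
    cfg = PipelineConfig(seed=args.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(cfg, series, args.out)
    summary = {
        "blocks": res.graph.n_blocks,
        "apneic_blocks": int(res.graph.apneic_mask.sum()),
        "svm_cv_sensitivity": round(res.partition.cv_sensitivity, 4),
        "svm_cv_specificity": round(res.partition.cv_specificity, 4),
        "predictions": len(res.predictions),
    }
    if res.report is not None:
        summary.update(r2=round(res.report.r2, 3),
                       ci_coverage=round(res.report.coverage, 3),
                       n_eval=res.report.n,
                       mean_risk_by_true_t={k: round(v, 3) for k, v in
                                            res.report.mean_risk_by_true_t.items()})
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
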