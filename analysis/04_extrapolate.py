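#!/usr/bin/env python
"""Extrapolate the selected models to the lake population.

Predicts summer TN/TP for every mass-balanced lake from the calibrated
retention model, computes nutrient retention, classifies trophic state,
and compares design-weighted CDFs of predictions against the observed
survey band.  Writes predictions_{N,P}.csv, trophic_classes.csv and the
observed CDFs.
"""

import argparse

import pandas as pd

from lakeloads import assessment, io, pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/pipeline")
    args = ap.parse_args()

    cfg = io.PipelineConfig(out_dir=args.out)
    predictions = pipeline.stage_predict(cfg)
    classes = pipeline.stage_classify(cfg, predictions)
    coverage = pipeline.stage_cdf(cfg, predictions)

    for nutrient in ("N", "P"):
        preds = predictions[nutrient]
        ret = preds["retention_pct"]
        print(f"{nutrient}: {len(preds)} lakes predicted; retention "
              f"median {ret.median():.1f}% / mean {ret.mean():.1f}% "
              f"(sd {ret.std():.1f})")
        col = f"T{nutrient}_class"
        counts = classes[col].value_counts()
        print("  trophic classes: " + ", ".join(
            f"{cls} {counts.get(cls, 0)}" for cls in assessment.TROPHIC_CLASSES))
        if nutrient in coverage:
            print(f"  prediction CDF within observed 95% band at "
                  f"{100 * coverage[nutrient]:.0f}% of support points")


if __name__ == "__main__":
    main()
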