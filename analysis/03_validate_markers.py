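"""Validation arm: SPM-O against the conventional 2D markers.

On the held-out validation cohort, compares SPM-O with TAPSE, TAPSE-F, SFD
and SFD-F: Pearson correlation with RVEF, Steiger tests of the correlation
differences, covariate-adjusted regression with variance partitioning,
stacked model-type comparison, leave-one-out RVEF prediction errors, and a
Kruskal–Wallis comparison of the error distributions.

Run:  python analysis/03_validate_markers.py [--seed 1] [--n-boot 1000]
"""

import argparse
import json
from pathlib import Path

from rvatlas.pipeline import PipelineConfig, run_validation
from rvatlas.synthetic import CohortGenerator, GeneratorConfig

ROOT = Path(__file__).resolve().parents[1]
VALIDATION_SEED_OFFSET = 2_002  # matches 01_simulate_cohorts


def main(seed: int = 1, n_boot: int = 1000) -> None:
    gen = CohortGenerator(GeneratorConfig(seed=seed))
    ds = gen.generate(seed=seed + VALIDATION_SEED_OFFSET)
    cfg = PipelineConfig(n_boot=n_boot, seed=seed, outdir=str(ROOT / "scratch" / "validation"))
    rep = run_validation(ds, cfg)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "validation.json").write_text(
        json.dumps(rep.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    print(f"marker correlations with RVEF (n = {rep.n_subjects}):")
    for m, v in sorted(rep.correlations.items(), key=lambda kv: -kv[1]["r"]):
        extra = ""
        if m in rep.steiger:
            extra = f"  Steiger p vs SPM-O = {rep.steiger[m]['p']:.3f}"
        print(f"  {m:8s} R = {v['r']:.2f} (p = {v['p']:.2g}){extra}")
    print("variance in RVEF explained by the marker term (%):")
    for m, fr in rep.variance_fractions.items():
        print(f"  {m:8s} {100 * fr['marker']:.1f}")
    print("leave-one-out median absolute error (ml):")
    for m, s in rep.loo_errors_ml.items():
        print(f"  {m:8s} {s['median']:.2f} ({s['iqr_low']:.2f}-{s['iqr_high']:.2f})")
    print(f"Kruskal-Wallis chi2 = {rep.kruskal_chi2:.2f}, p = {rep.kruskal_p:.3f}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-boot", type=int, default=1000, dest="n_boot")
    main(**vars(ap.parse_args()))
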