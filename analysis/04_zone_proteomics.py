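"""Differential protein abundance between zone B and zone D astrocytes.

Simulates a log2 LFQ table with left-censored missingness (worse in the
lower-intensity zone-B group), filters on per-zone detection, median-
aligns samples, imputes from a down-shifted Gaussian, and applies the
empirical-Bayes moderated t-test with the alpha = 0.05 / |log2 FC| > 1
significance rule. Writes the protein DE table and recovery metrics.
"""

import argparse
from pathlib import Path

from zonescope import io
from zonescope.pipeline import PipelineConfig, run_prot_stage, stage_seeds


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    stage = run_prot_stage(PipelineConfig(seed=args.seed), stage_seeds(args.seed)[3])
    args.out.mkdir(parents=True, exist_ok=True)
    io.write_tsv(args.out / "protein_zone_de.tsv", stage["de"])
    io.write_json(args.out / "protein_metrics.json", stage["metrics"])

    m = stage["metrics"]
    d0 = stage["de"].attrs.get("d0")
    print(f"{m['n_proteins_kept']} proteins pass the missingness filter")
    print(f"moderated t prior df d0 = {d0:.1f}")
    print(f"{m['n_significant']} proteins significant (adj p < 0.05 and |log2 FC| > 1); "
          f"recall of planted effects {100 * m['recall']:.1f}%, "
          f"observed FDR {100 * m['false_discovery_rate']:.1f}%")


if __name__ == "__main__":
    main()
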