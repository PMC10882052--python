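"""Demultiplex a synthetic tDISCO run and test zone-wise expression.

Simulates a 20-cell, 4-zone run (nested 10-per-SSS / 50-per-index
pooling, UMI duplication, barcode errors), resolves every read through
the barcode hierarchy, collapses UMIs, TPM-normalizes, and runs the
negative-binomial likelihood-ratio test across zones. Writes the DE
table, the zone-group classification, and the demultiplexing metrics.
"""

import argparse
import json
from pathlib import Path

from zonescope import io
from zonescope.pipeline import PipelineConfig, run_tdisco_stage, stage_seeds


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = PipelineConfig(seed=args.seed)
    stage = run_tdisco_stage(config, stage_seeds(args.seed)[0])
    args.out.mkdir(parents=True, exist_ok=True)

    io.write_tsv(args.out / "tdisco_zone_de.tsv", stage["de"])
    groups = stage["zone_groups"].rename_axis("gene_id").reset_index()
    io.write_tsv(args.out / "tdisco_zone_groups.tsv", groups)
    io.write_json(args.out / "tdisco_metrics.json", stage["metrics"])

    m = stage["metrics"]
    print(f"reads assigned: {m['reads_assigned']}/{m['reads_total']} "
          f"({100 * m['assigned_fraction']:.2f}%), "
          f"cell accuracy {100 * m['cell_assignment_accuracy']:.2f}%")
    print(f"molecules counted: {m['n_molecules']}")
    print("planted zone-group recovery:",
          {g: f"{100 * v:.0f}%" for g, v in m["planted_groups_recovered"].items()})
    n_sig = int((stage["de"].padj < config.fdr).sum())
    print(f"{n_sig} genes differential across zones at FDR < {config.fdr}")


if __name__ == "__main__":
    main()
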