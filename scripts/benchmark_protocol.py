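#!/usr/bin/env python
"""Full Davis/KiBA benchmark protocol (optional; needs downloaded data).

Given a benchmark directory in the DeepDTA layout (ligands_can.txt,
proteins.txt, Y, folds/), trains the full-size two-branch model on the
provided training folds and reports CI, MSE and RMSE on the held-out test
fold.  This mirrors the published evaluation protocol; at full scale it is
a long-running job and is deliberately not part of the test suite.

Usage:
    python scripts/benchmark_protocol.py --data path/to/davis \
        --dataset davis --out runs/davis --seed 0 [--fold 0]
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
from pathlib import Path

from csatdta.datasets import load_deepdta_dataset, make_split
from csatdta.model import ModelConfig
from csatdta.training import evaluate, train


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, required=True)
    parser.add_argument("--dataset", choices=["davis", "kiba"], required=True)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--fold", type=int, default=0,
                        help="which training fold to hold out for validation")
    parser.add_argument("--epochs", type=int, default=100)
    args = parser.parse_args()

    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    records, folds = load_deepdta_dataset(args.data, args.dataset)
    if folds.get("train_folds"):
        split = make_split(records, "provided_folds", seed=args.seed,
                           folds=folds, fold_id=args.fold)
    else:
        split = make_split(records, "random_pairs", seed=args.seed,
                           fractions=(5 / 6 * 5 / 6, 5 / 6 / 6, 1 / 6))

    config = ModelConfig(epochs=args.epochs, seed=args.seed)
    run = train(records, config, split, out_dir=args.out)
    report = evaluate(run.model, [records[i] for i in split.test])
    (args.out / "benchmark_report.json").write_text(report.to_json())
    print(json.dumps({
        "dataset": args.dataset,
        "n_records": len(records),
        "epochs_run": len(run.history["train_mse"]),
        "test": json.loads(report.to_json()),
    }, indent=2))


if __name__ == "__main__":
    main()
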