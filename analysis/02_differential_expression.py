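#!/usr/bin/env python
"""Call consensus differentially expressed genes.

Welch t-tests per gene for normal-vs-primary and normal-vs-metastasis,
BH FDR within each comparison, then the strict consensus: q < 0.05 in
both comparisons with a consistent direction and matching external
evidence.  Writes results/de_table.tsv and reports recovery against the
planted truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from tfnetminer import diffexpr, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/de_table.tsv"))
    args = parser.parse_args()

    expr = io.read_expression(args.datadir / "expression.tsv")
    evidence = diffexpr.EvidenceList.from_frame(
        pd.read_csv(args.datadir / "evidence.tsv", sep="\t")
    )
    frames = {}
    for case in ("primary", "metastasis"):
        res = diffexpr.per_gene_ttest(expr, "normal", case)
        res["q"] = diffexpr.bh_adjust(res["p"].to_numpy())
        frames[case] = res
    up, down = diffexpr.consensus_de(frames["primary"], frames["metastasis"], evidence)

    table = pd.DataFrame({
        "gene_id": expr.index,
        "p_primary": frames["primary"]["p"].to_numpy(),
        "q_primary": frames["primary"]["q"].to_numpy(),
        "p_met": frames["metastasis"]["p"].to_numpy(),
        "q_met": frames["metastasis"]["q"].to_numpy(),
        "direction": frames["primary"]["direction"].to_numpy(),
        "consensus": [g in set(up) | set(down) for g in expr.index],
    })
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)

    truth = json.loads((args.datadir / "truth.json").read_text())
    planted = set(truth["planted_de"]["gene_id"])
    called = set(up) | set(down)
    print(f"consensus: {len(up)} up, {len(down)} down -> {args.out}")
    print(f"planted-truth recovery: {len(called & planted)}/{len(planted)} "
          f"({len(called - planted)} false positives)")


if __name__ == "__main__":
    main()
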