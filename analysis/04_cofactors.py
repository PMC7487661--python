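#!/usr/bin/env python
"""Nominate co-regulatory TFs by the two-step hypergeometric method.

Step 1 ranks every profile in the ChIP-Seq pool by target-set overlap
with the focal TF's targets (upper-tail hypergeometric, p < 0.01, top
50).  Step 2 tests, per TF, whether its profiles are over-represented
among the selected ones; a TF is called with p < 0.01 and >= 3
significant profiles.  Writes results/cofactors.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from tfnetminer import cofactor, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--targets", type=Path, default=Path("results/targets.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/cofactors.tsv"))
    args = parser.parse_args()

    pool = io.read_profile_pool(args.datadir / "pool.gmt")
    annotation = io.read_annotation(args.datadir / "annotation.tsv")
    universe = {g.gene_id for g in annotation}
    focal = set(pd.read_csv(args.targets, sep="\t")["gene_id"])

    results = cofactor.find_cofactors(pool, focal & universe, universe)
    frame = pd.DataFrame(
        [(r.tf_name, r.n_profiles_pool, r.n_profiles_sig, r.p, r.called) for r in results],
        columns=["tf", "n_profiles_pool", "n_profiles_sig", "p", "called"],
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, sep="\t", index=False)

    called = frame.loc[frame.called, "tf"].tolist()
    print(f"{len(results)} TFs represented in the significant profile set -> {args.out}")
    print(f"called co-factors: {', '.join(called) if called else '(none)'}")


if __name__ == "__main__":
    main()
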