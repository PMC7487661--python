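#!/usr/bin/env python
"""Clinical qPCR analysis of the candidate lncRNA.

Quantifies expression as dCt (target minus reference Ct; smaller =
higher expression), compares paired tumor vs normal tissue, evaluates
diagnostic value by rank-based ROC AUC, and associates tumor dCt with
each clinicopathological covariate (pooled t-test for two levels,
one-way ANOVA otherwise).  Writes results/association_table.tsv and
results/clinical_stats.json.
"""

import argparse
import json
from pathlib import Path

from tfnetminer import clinstats, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = io.read_clinical(args.datadir / "clinical.tsv")
    table["dct_tumor"] = clinstats.delta_ct(table.ct_target_tumor,
                                            table.ct_reference_tumor)
    table["dct_normal"] = clinstats.delta_ct(table.ct_target_normal,
                                             table.ct_reference_normal)
    t, df, p_paired, _ = clinstats.paired_ttest(table.dct_tumor, table.dct_normal)
    auc = clinstats.roc_auc(table.dct_tumor, table.dct_normal)
    mean_ddct = (table.dct_tumor - table.dct_normal).mean()
    fc = clinstats.fold_change(mean_ddct)

    covariates = [c for c in table.columns
                  if c != "sample_id" and not c.startswith(("ct_", "dct_"))]
    assoc = clinstats.association_table(table, covariates)
    args.outdir.mkdir(parents=True, exist_ok=True)
    assoc.to_csv(args.outdir / "association_table.tsv", sep="\t", index=False)
    payload = {"paired_t": t, "paired_df": df, "paired_p": p_paired,
               "mean_ddct": mean_ddct, "fold_change": fc, "roc_auc": auc}
    (args.outdir / "clinical_stats.json").write_text(json.dumps(payload, indent=1))

    print(f"tumor vs paired normal: mean ddCt = {mean_ddct:.2f} "
          f"(fold change {fc:.2f}), paired t({df}) = {t:.2f}, p = {p_paired:.2g}")
    print(f"diagnostic AUC (tumor vs normal dCt): {auc:.3f}")
    sig = assoc.dropna(subset=["p"])
    sig = sig[sig.significant.astype(bool)]
    if len(sig):
        print("covariates associated with expression (p < 0.05):")
        for r in sig.itertuples():
            print(f"  {r.covariate}: p = {r.p:.3g}")
    else:
        print("no covariate associated with expression at p < 0.05")


if __name__ == "__main__":
    main()
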