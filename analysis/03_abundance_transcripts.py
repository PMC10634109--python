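"""Abundance and transcript statistics over the treated time course.

Computes PQI and log2 FCP per protein, Student's t tests of each time point
against 0 h, a permutation-FDR comparison of replicate K_d values between
sustained immunity and growth, hierarchical clustering of Z-scored FCP
profiles, and protein:transcript integration (per-time correlation and
transformed ratio series).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from turnover15n.abundance import (
    average_injections,
    compute_pqi,
    fold_change,
    hcluster_profiles,
    linear_rsq,
    protein_transcript_ratio,
    sam_permutation_fdr,
    ttest_vs_reference,
    zscore_rows,
)
from turnover15n.pipeline import read_table

OUT = Path("results/analysis")


def main() -> None:
    auc = read_table(OUT / "treated" / "auc.tsv", "auc")
    transcripts = read_table(OUT / "treated" / "transcripts.tsv", "transcripts")

    pqi = average_injections(compute_pqi(auc))
    fc = fold_change(pqi)
    fc.to_csv(OUT / "fcp.tsv", sep="\t", index=False)

    # t tests vs 0 h on replicate log2 FCP
    rows = []
    for (protein, t), grp in fc.groupby(["protein_id", "time_h"]):
        if t == 0 or len(grp) < 2:
            continue
        res = ttest_vs_reference(grp["log2_fcp"], np.zeros(len(grp)))
        rows.append({"protein_id": protein, "time_h": t,
                     "statistic": res.statistic, "p": res.p_value,
                     "significant": res.significant})
    stats = pd.DataFrame(rows)
    stats.to_csv(OUT / "stats_ttest.tsv", sep="\t", index=False)
    n_sig = int(stats["significant"].sum())
    print(f"t tests vs 0 h: {n_sig}/{len(stats)} protein-time contrasts significant")

    # permutation-FDR on replicate K_d: sustained immunity vs growth
    c1 = pd.read_csv(OUT / "turnover_C1.tsv", sep="\t")
    c3 = pd.read_csv(OUT / "turnover_C3.tsv", sep="\t")
    rep_cols = [c for c in c1.columns if c.startswith("kloss_rep")]
    shared = sorted(set(c1[c1.qc_pass].protein_id) & set(c3[c3.qc_pass].protein_id))
    if len(shared) >= 5:
        a = c3.set_index("protein_id").loc[shared, rep_cols].to_numpy() \
            - c3.set_index("protein_id").loc[shared, "kdil"].to_numpy()[:, None]
        b = c1.set_index("protein_id").loc[shared, rep_cols].to_numpy() \
            - c1.set_index("protein_id").loc[shared, "kdil"].to_numpy()[:, None]
        res = sam_permutation_fdr(a, b, s0=0.1, n_perm=1000, fdr=0.05, seed=1)
        print(f"permutation FDR on K_d (C3 vs C1): {int(res.significant.sum())}/{len(shared)} "
              f"proteins change significantly (cutoff |d| >= {res.cutoff:.2f})")

    # clustering of Z-scored log2 FCP profiles
    wide = fc.pivot_table(index="protein_id", columns="time_h", values="log2_fcp",
                          aggfunc="median").dropna()
    z, _ = zscore_rows(wide.to_numpy())
    labels, _ = hcluster_profiles(z, k=2)
    clusters = pd.DataFrame({"protein_id": wide.index, "cluster": labels})
    clusters.to_csv(OUT / "clusters.tsv", sep="\t", index=False)
    sizes = clusters["cluster"].value_counts().to_dict()
    print(f"FCP profile clusters (k=2): sizes {sizes}")

    # protein:transcript integration
    expr = transcripts.groupby(["gene_id", "time_h"], as_index=False)["rel_expression"].mean()
    prot = (auc.groupby(["protein_id", "time_h"], as_index=False)["auc"].median()
            .rename(columns={"protein_id": "gene_id"}))
    times = sorted(set(expr["time_h"]) & set(prot["time_h"]))
    ratio_rows = []
    for gene in sorted(set(expr["gene_id"]) & set(prot["gene_id"])):
        e = expr[expr.gene_id == gene].set_index("time_h")["rel_expression"].reindex(times)
        p = prot[prot.gene_id == gene].set_index("time_h")["auc"].reindex(times)
        if e.isna().any() or p.isna().any():
            continue
        for t, r in zip(times, protein_transcript_ratio(p.to_numpy(), e.to_numpy())):
            ratio_rows.append({"gene_id": gene, "time_h": t, "ratio": r})
    pd.DataFrame(ratio_rows).to_csv(OUT / "ratios.tsv", sep="\t", index=False)

    for t in times:
        e = expr[expr.time_h == t].set_index("gene_id")["rel_expression"]
        p = prot[prot.time_h == t].set_index("gene_id")["auc"]
        genes = e.index.intersection(p.index)
        slope, _, r2 = linear_rsq(np.log10(e[genes]), np.log10(p[genes]))
        print(f"transcript-protein correlation at {t:>4} h: R^2 = {r2:.2f} "
              f"(slope {'+' if slope >= 0 else '-'})")


if __name__ == "__main__":
    main()
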