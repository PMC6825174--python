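"""Relative qPCR quantification (2^-ddCt) and expression–metabolite correlation.

The comparative-Ct method assumes 100% amplification efficiency (doubling per
cycle).  Technical replicates are averaged first; dCt = Ct_gene − Ct_reference
is taken per (tissue, biological replicate); ddCt subtracts each gene's mean
dCt in the calibrator tissue; the reported quantity is 2^-ddCt summarized as
mean ± SD over biological replicates.  The calibrator tissue's mean is 1 by
construction for every gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CT_COLUMNS = ["gene", "tissue", "bio_rep", "tech_rep", "ct"]


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def ddct(ct: pd.DataFrame, reference_gene: str, calibrator: str) -> pd.DataFrame:
    """Per (gene, tissue) relative expression: mean and SD of 2^-ddCt.

    ``ct`` has columns (gene, tissue, bio_rep, tech_rep, ct).  The reference
    gene must be present in every (tissue, bio_rep); the calibrator tissue
    must be present for every gene.
    """
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    if calibrator not in set(ct["tissue"]):
        raise ValueError(f"calibrator tissue {calibrator!r} not in table")
    # technical replicates first
    tech = (
        ct.groupby(["gene", "tissue", "bio_rep"], as_index=False)["ct"].mean()
    )
    ref = tech[tech["gene"] == reference_gene].set_index(["tissue", "bio_rep"])["ct"]
    tgt = tech[tech["gene"] != reference_gene].copy()
    key = list(zip(tgt["tissue"], tgt["bio_rep"]))
    missing = [k for k in key if k not in ref.index]
    if missing:
        raise ValueError(f"reference gene missing in (tissue, bio_rep): {sorted(set(missing))}")
    tgt["dct"] = tgt["ct"].to_numpy() - ref.loc[key].to_numpy()
    cal_mean = (
        tgt[tgt["tissue"] == calibrator].groupby("gene")["dct"].mean()
    )
    absent = sorted(set(tgt["gene"]) - set(cal_mean.index))
    if absent:
        raise ValueError(f"calibrator tissue missing for genes: {absent}")
    tgt["ddct"] = tgt["dct"] - cal_mean.loc[tgt["gene"]].to_numpy()
    tgt["rel_expr"] = np.power(2.0, -tgt["ddct"])
    out = (
        tgt.groupby(["gene", "tissue"])["rel_expr"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
        .reset_index()
    )
    out.attrs["calibrator"] = calibrator
    out.attrs["reference_gene"] = reference_gene
    return out


def read_metabolite_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"tissue", "compound", "mean"}
    if not needed <= set(df.columns):
        raise ValueError(f"metabolite table needs columns {sorted(needed)}")
    if (df["mean"] < 0).any():
        raise ValueError("metabolite content must be non-negative")
    return df


def expr_metabolite_corr(rel: pd.DataFrame, met: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of tissue-wise expression means vs metabolite content.

    Tissues are matched by id; missing tissues are dropped pairwise with the
    n actually used reported per (gene, compound).  Fewer than 3 shared
    tissues, or zero variance on either side, yields r = NaN.
    """
    overall = set(rel["tissue"]) & set(met["tissue"])
    if len(overall) < 3:
        raise ValueError(f"only {len(overall)} shared tissues; need at least 3")
    rows = []
    for gene, gdf in rel.groupby("gene"):
        gexpr = gdf.set_index("tissue")["mean"]
        for compound, mdf in met.groupby("compound"):
            mexpr = mdf.set_index("tissue")["mean"]
            shared = sorted(set(gexpr.index) & set(mexpr.index))
            x = gexpr.loc[shared].to_numpy(dtype=float)
            y = mexpr.loc[shared].to_numpy(dtype=float)
            if len(shared) < 3 or x.std() == 0 or y.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"gene": gene, "compound": compound, "r": r, "n": len(shared)})
    return pd.DataFrame(rows, columns=["gene", "compound", "r", "n"])
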