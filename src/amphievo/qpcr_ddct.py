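"""Relative qPCR quantification by the 2^-ddCt method.

Technical replicates are averaged first within (gene, time, biological
replicate); dCt = Ct_target - Ct_reference per biological replicate;
ddCt = mean dCt(t) - mean dCt(baseline); RQ = 2^-ddCt. Significance versus
baseline is a Welch t-test on per-replicate dCt values (the test operates
on dCt, which is approximately normal, not on RQ), BH-adjusted across time
points within each gene.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from amphievo.codon_selection.scans import bh_adjust

REQUIRED_COLUMNS = ("gene", "time", "bio_rep", "tech_rep", "ct")


def _validate(ct: pd.DataFrame, reference_gene: str):
    missing = set(REQUIRED_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent")
    bad = ct["ct"].dropna() <= 0
    if bad.any():
        raise ValueError("Ct values must be positive (NaN marks failed wells)")


def delta_ct(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per (gene, time, bio_rep) dCt after dropping failed wells and
    averaging technical replicates."""
    _validate(ct, reference_gene)
    clean = ct.dropna(subset=["ct"])
    means = (
        clean.groupby(["gene", "time", "bio_rep"])["ct"].mean().rename("ct").reset_index()
    )
    ref = means[means["gene"] == reference_gene].set_index(["time", "bio_rep"])["ct"]
    targets = means[means["gene"] != reference_gene].copy()
    keys = list(zip(targets["time"], targets["bio_rep"]))
    targets["ct_ref"] = [ref.get(k, np.nan) for k in keys]
    dropped = targets["ct_ref"].isna()
    if dropped.any():
        warnings.warn("reference gene missing for some (time, bio_rep); rows set NA")
    targets["dct"] = targets["ct"] - targets["ct_ref"]
    return targets[["gene", "time", "bio_rep", "dct"]]


def relative_quantification(
    ct: pd.DataFrame,
    reference_gene: str = "ACTIN",
    baseline_time=None,
) -> pd.DataFrame:
    """RQ = 2^-ddCt per gene and time point.

    Columns: gene, time, n_bio_reps, mean_dct, ddct, rq, sd_dct.
    """
    d = delta_ct(ct, reference_gene)
    times = list(pd.unique(ct["time"]))
    baseline_time = times[0] if baseline_time is None else baseline_time
    if baseline_time not in times:
        raise ValueError("baseline time absent from Ct table")
    rows = []
    for gene, sub in d.groupby("gene"):
        base = sub.loc[sub["time"] == baseline_time, "dct"].dropna()
        base_mean = base.mean() if len(base) else np.nan
        for t, tsub in sub.groupby("time"):
            vals = tsub["dct"].dropna()
            mean_dct = vals.mean() if len(vals) else np.nan
            ddct = mean_dct - base_mean
            rows.append(
                {
                    "gene": gene,
                    "time": t,
                    "n_bio_reps": int(len(vals)),
                    "mean_dct": mean_dct,
                    "sd_dct": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "ddct": ddct,
                    "rq": float(2.0 ** (-ddct)) if np.isfinite(ddct) else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out["time_order"] = out["time"].map({t: i for i, t in enumerate(times)})
    return out.sort_values(["gene", "time_order"]).drop(columns="time_order").reset_index(drop=True)


def timecourse_significance(
    ct: pd.DataFrame,
    reference_gene: str = "ACTIN",
    baseline_time=None,
) -> pd.DataFrame:
    """Welch t-test of per-replicate dCt at each time vs baseline, BH-adjusted
    across time points within each gene."""
    d = delta_ct(ct, reference_gene)
    times = list(pd.unique(ct["time"]))
    baseline_time = times[0] if baseline_time is None else baseline_time
    rows = []
    for gene, sub in d.groupby("gene"):
        base = sub.loc[sub["time"] == baseline_time, "dct"].dropna()
        for t, tsub in sub.groupby("time"):
            if t == baseline_time:
                continue
            vals = tsub["dct"].dropna()
            if len(vals) < 2 or len(base) < 2:
                warnings.warn(f"{gene} at {t}: <2 replicates, p set to NA")
                p = np.nan
            elif vals.std(ddof=1) == 0 and base.std(ddof=1) == 0:
                p = 1.0 if np.isclose(vals.mean(), base.mean()) else 0.0
            else:
                p = float(ttest_ind(vals, base, equal_var=False).pvalue)
            rows.append({"gene": gene, "time": t, "p": p})
    out = pd.DataFrame(rows)
    adj = []
    for gene, sub in out.groupby("gene"):
        ps = sub["p"].to_numpy()
        finite = np.isfinite(ps)
        a = np.full_like(ps, np.nan)
        if finite.any():
            a[finite] = bh_adjust(ps[finite])
        adj.append(pd.Series(a, index=sub.index))
    out["p_adj"] = pd.concat(adj).sort_index()
    return out
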