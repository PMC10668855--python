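"""Synthetic qPCR Ct tables with known fold-change truth.

The target gene's dCt against the reference encodes -log2(fold-change)
relative to the baseline time point, plus Gaussian per-well noise, so the
2^-ddCt pipeline should recover the planted truth.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def make_qpcr_table(
    truth: pd.DataFrame,
    reps: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    n_technical: int = 3,
    reference_gene: str = "ACTIN",
    baseline_time=None,
    fail_rate: float = 0.0,
    base_ct: float = 20.0,
) -> pd.DataFrame:
    """Build a Ct table from a genes x time-points fold-change matrix.

    ``truth``: index = gene names, columns = time points, values =
    fold-change vs baseline (first column by default). The reference gene is
    appended with fold-change 1 everywhere. Columns of the result:
    gene, time, bio_rep, tech_rep, ct (NaN = failed well).
    """
    if reps < 2:
        warnings.warn("fewer than 2 biological replicates: significance untestable")
    rng = np.random.default_rng(seed)
    times = list(truth.columns)
    baseline_time = times[0] if baseline_time is None else baseline_time
    if baseline_time not in times:
        raise ValueError("baseline time absent from truth table")
    genes = list(truth.index)
    if reference_gene in genes:
        raise ValueError("reference gene must not appear in the truth table")

    rows = []
    gene_offsets = {g: base_ct + 2.0 * i for i, g in enumerate(genes)}
    for t in times:
        for b in range(reps):
            ref_ct = base_ct + rng.normal(0, noise_sd)
            for gene in genes:
                fold = float(truth.loc[gene, t])
                if fold <= 0:
                    raise ValueError("fold-changes must be positive")
                dct = -np.log2(fold)  # ddCt target; dCt(baseline) == 0 offset
                mean_ct = gene_offsets[gene] + dct + (ref_ct - base_ct)
                for k in range(n_technical):
                    ct = mean_ct + rng.normal(0, noise_sd)
                    if fail_rate and rng.random() < fail_rate:
                        ct = np.nan
                    rows.append(
                        {"gene": gene, "time": t, "bio_rep": b, "tech_rep": k, "ct": ct}
                    )
            for k in range(n_technical):
                rows.append(
                    {
                        "gene": reference_gene,
                        "time": t,
                        "bio_rep": b,
                        "tech_rep": k,
                        "ct": ref_ct + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
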