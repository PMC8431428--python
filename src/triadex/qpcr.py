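"""qPCR relative quantification (2^−ΔΔCT) and RNA-seq concordance.

Per sample, ΔCT = CT_target − CT_reference removes loading differences;
per genotype, ΔΔCT = mean ΔCT − mean ΔCT of the calibrator genotype, and
relative expression is 2^−ΔΔCT (1 for the calibrator by construction).
Replicates are aggregated at the ΔCT level, the standard Livak practice.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats


def ddct(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_genotype: str,
) -> pd.DataFrame:
    """Relative expression per (genotype, gene) by the 2^−ΔΔCT method.

    Parameters
    ----------
    ct
        Long table with columns sample_id, genotype, gene, replicate, CT.
    reference_gene
        Internal-control gene, required in every sample.
    calibrator_genotype
        Genotype whose ΔCT anchors ΔΔCT = 0.

    Returns
    -------
    DataFrame with one row per (genotype, gene ≠ reference): delta_ct
    (replicate mean), ddct, rel_expr = 2^−ΔΔCT, rel_expr_sd (sd of
    per-replicate 2^−ΔΔCT values) and n_replicates.
    """
    required = {"sample_id", "genotype", "gene", "CT"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    if not np.isfinite(ct["CT"]).all():
        raise ValueError("CT values must be finite")

    ref = ct[ct["gene"] == reference_gene].set_index("sample_id")["CT"]
    targets = ct[ct["gene"] != reference_gene].copy()
    samples_missing_ref = set(targets["sample_id"]) - set(ref.index)
    if samples_missing_ref:
        raise ValueError(
            f"reference gene {reference_gene!r} missing in samples: "
            f"{sorted(samples_missing_ref)[:5]}"
        )
    if calibrator_genotype not in set(ct["genotype"]):
        raise ValueError(f"calibrator genotype {calibrator_genotype!r} not present")

    targets["delta_ct"] = targets["CT"] - ref.loc[targets["sample_id"]].to_numpy()
    mean_dct = (
        targets.groupby(["genotype", "gene"])["delta_ct"].mean().rename("delta_ct")
    )
    cal = mean_dct.xs(calibrator_genotype, level="genotype")

    rows = []
    for (genotype, gene), dct_mean in mean_dct.items():
        if gene not in cal.index:
            raise ValueError(f"gene {gene!r} absent from calibrator genotype")
        dd = dct_mean - cal[gene]
        reps = targets[
            (targets["genotype"] == genotype) & (targets["gene"] == gene)
        ]["delta_ct"].to_numpy()
        rel_reps = 2.0 ** (-(reps - cal[gene]))
        rows.append(
            dict(
                genotype=genotype,
                gene=gene,
                delta_ct=float(dct_mean),
                ddct=float(dd),
                rel_expr=float(2.0 ** (-dd)),
                rel_expr_sd=float(rel_reps.std(ddof=1)) if len(reps) > 1 else np.nan,
                n_replicates=len(reps),
            )
        )
    return pd.DataFrame(rows)


def concordance(
    qpcr_rel: pd.Series,
    rnaseq_expr: pd.Series,
) -> Tuple[float, float]:
    """Direction agreement and rank correlation of qPCR vs RNA-seq.

    Both inputs are indexed by (gene, genotype).  For every gene and
    every genotype pair the sign of the difference is compared between
    platforms (ties count as agreement only if tied in both); the first
    return value is the agreeing fraction.  The second is the Spearman
    rank correlation across all shared (gene, genotype) points.
    """
    shared = qpcr_rel.index.intersection(rnaseq_expr.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared (gene, genotype) points")
    q = qpcr_rel.loc[shared]
    r = rnaseq_expr.loc[shared]

    agree = total = 0
    for gene in q.index.get_level_values(0).unique():
        qg = q.xs(gene, level=0)
        rg = r.xs(gene, level=0)
        genos = list(qg.index)
        for i in range(len(genos)):
            for j in range(i + 1, len(genos)):
                dq = np.sign(qg[genos[i]] - qg[genos[j]])
                dr = np.sign(rg[genos[i]] - rg[genos[j]])
                agree += int(dq == dr)
                total += 1
    if total == 0:
        raise ValueError("no genotype pairs to compare")
    rho, _ = stats.spearmanr(q.to_numpy(), r.to_numpy())
    return agree / total, float(rho)
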