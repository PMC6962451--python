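"""Condition-pair contrasts, expression filtering and DEP calling.

All statistics are computed in log2 space: a group mean is the arithmetic
mean of log2 abundances (the geometric mean of ratios), the fold change is
the difference of group means, and significance comes from the unpaired
two-tailed pooled-variance (Student) t-test. A protein is a differentially
expressed protein (DEP) versus the reference when |log2 FC| >= log2(1.5)
and p <= 0.05 (both thresholds configurable; comparisons inclusive by
default).

Degenerate-variance convention
------------------------------
With very few replicates, both groups can be exactly constant. The t
statistic then degenerates and we take its limit: equal constants give
p = 1.0 (no evidence of change), different constants give p = 0.0 (the
infinite-t limit). The undefined marker (NaN) is reserved for groups with
fewer than two observations, where no variance estimate exists at all;
proteins with undefined p are excluded from DEP calling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, ValidationError
from .io import AbundanceMatrix, SampleAnnotation

CONTRAST_COLUMNS = [
    "protein_id", "mean_log2_a", "mean_log2_b", "log2_fc", "p_value", "n_a", "n_b",
]

DEP_COLUMNS = ["protein_id", "direction", "baseline_log2_fc", "baseline_p"]


def filter_expressed(matrix: AbundanceMatrix, annotation: SampleAnnotation) -> list[str]:
    """Proteins quantified in at least one sample of every condition.

    This defines the protein universe for all downstream analyses; proteins
    never detected in some condition cannot be anchored to the reference.
    """
    annotation.check_covers(matrix)
    present = matrix.data.notna()
    keep = pd.Series(True, index=matrix.data.index)
    for condition in annotation.conditions_present:
        samples = [s for s in annotation.samples_for(condition) if s in matrix.data.columns]
        if not samples:
            continue
        keep &= present[samples].any(axis=1)
    return list(matrix.data.index[keep])


def _group_stats(log2_values: pd.DataFrame, samples: list[str]):
    block = log2_values[samples].to_numpy(dtype=float)
    n = np.sum(~np.isnan(block), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(block, axis=1) / n
    mean = np.where(n > 0, mean, np.nan)
    # sum of squared deviations; 0 when n < 2
    dev = block - mean[:, None]
    ss = np.nansum(dev * dev, axis=1)
    return mean, ss, n


def compute_contrast(
    matrix: AbundanceMatrix,
    annotation: SampleAnnotation,
    cond_a: str,
    cond_b: str,
) -> pd.DataFrame:
    """Per-protein log2 fold change and Student t-test of cond_a vs cond_b.

    Returns one row per protein with columns ``protein_id, mean_log2_a,
    mean_log2_b, log2_fc, p_value, n_a, n_b``. Group means use the available
    (non-missing) values only; ``n_a``/``n_b`` record actual usage. p is NaN
    (undefined) when either group has fewer than two values.
    """
    annotation.check_covers(matrix)
    samples_a = [s for s in annotation.samples_for(cond_a) if s in matrix.data.columns]
    samples_b = [s for s in annotation.samples_for(cond_b) if s in matrix.data.columns]
    log2_values = matrix.log2()
    mean_a, ss_a, n_a = _group_stats(log2_values, samples_a)
    mean_b, ss_b, n_b = _group_stats(log2_values, samples_b)

    diff = mean_a - mean_b
    df = n_a + n_b - 2
    defined = (n_a >= 2) & (n_b >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = np.where(df > 0, (ss_a + ss_b) / np.where(df > 0, df, 1), np.nan)
        se = np.sqrt(sp2 * (1.0 / np.where(n_a > 0, n_a, np.nan)
                            + 1.0 / np.where(n_b > 0, n_b, np.nan)))
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), np.where(df > 0, df, 1))
    p = np.where(defined, p, np.nan)
    # degenerate zero pooled variance: take the limit of the t statistic
    zero_var = defined & (sp2 == 0.0)
    p = np.where(zero_var & (diff == 0.0), 1.0, p)
    p = np.where(zero_var & (diff != 0.0), 0.0, p)

    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "log2_fc": diff,
            "p_value": p,
            "n_a": n_a.astype(int),
            "n_b": n_b.astype(int),
        }
    )


def call_deps(
    contrasts: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    strict_p: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Filter a contrast table down to DEPs.

    Inclusion requires |log2_fc| >= log2(fc_threshold) and a defined p-value
    passing the significance threshold (inclusive ``p <= p_threshold`` by
    default, strict with ``strict_p``). With ``fdr=True`` the p-values are
    Benjamini-Hochberg adjusted first (off by default; the anchored-filter
    convention applies no multiple-testing correction).
    """
    if fc_threshold < 1:
        raise ValidationError(f"fc_threshold must be >= 1, got {fc_threshold}")
    if not (0 < p_threshold <= 1):
        raise ValidationError(f"p_threshold must be in (0, 1], got {p_threshold}")
    log2_fc = contrasts["log2_fc"].to_numpy(dtype=float)
    p = contrasts["p_value"].to_numpy(dtype=float)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        defined = ~np.isnan(p)
        adjusted = np.full_like(p, np.nan)
        if defined.any():
            adjusted[defined] = multipletests(p[defined], method="fdr_bh")[1]
        p = adjusted
    band = np.log2(fc_threshold)
    fold_ok = np.abs(log2_fc) >= band
    sig_ok = (p < p_threshold) if strict_p else (p <= p_threshold)
    sig_ok = np.where(np.isnan(p), False, sig_ok)
    selected = fold_ok & sig_ok & ~np.isnan(log2_fc)
    out = pd.DataFrame(
        {
            "protein_id": contrasts.loc[selected, "protein_id"].to_numpy(),
            "direction": np.where(log2_fc[selected] > 0, "up", "down"),
            "baseline_log2_fc": log2_fc[selected],
            "baseline_p": p[selected],
        }
    )
    return out.reset_index(drop=True)


def contrast_lookup(contrasts: pd.DataFrame, proteins) -> pd.DataFrame:
    """Rows of a contrast table for the given proteins, in their order.

    Raises :class:`ConsistencyError` if any protein is absent.
    """
    indexed = contrasts.set_index("protein_id")
    missing = [p for p in proteins if p not in indexed.index]
    if missing:
        raise ConsistencyError(f"proteins absent from contrast table: {missing[:5]}")
    return indexed.loc[list(proteins)].reset_index()
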