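"""Differential methylation (per peak) and differential expression (per gene).

Both tests share the same contract: a log2 fold change (group B relative to
group A), a two-sided p-value, a Benjamini-Hochberg FDR across features, and
a direction call (UP / DOWN / NDE) at ``fdr < alpha``.

Peak test
---------
The default peak test ("nb") works on per-replicate log2 IP/input enrichment
with a negative-binomial variance model, var(count) = mu + phi*mu^2, whose
dispersion component phi is estimated *jointly across all peaks* from the
pooled within-group residual variance (strength borrowing in the spirit of
edgeR's common dispersion).  That makes the test well calibrated in small
designs (3 vs 3) where per-peak variance estimates alone would be hopeless,
while still accounting for biological overdispersion.  A pooled Fisher's
exact test on the summed IP/input 2x2 table is available as
``method="fisher"``; it treats the pooled counts as Poisson and is
anti-conservative when replicates are overdispersed, so it is kept for its
transparent 2x2 semantics rather than as the default.

Gene test
---------
A Wald test on log2 fold change of size-factor-normalized means with an NB
variance whose per-gene method-of-moments dispersion is shrunk halfway
toward the common (across-genes) dispersion.  The reference distribution is
Student's t with Satterthwaite-style moderated degrees of freedom: the
shrunk variance estimate mixes a per-gene component (pooled within-group
df) with a common component estimated from all genes (effectively infinite
df), giving df_eff = df_pooled / w^2 where w is the per-gene weight.  This
corrects the small-sample anti-conservatism of a plain normal reference
without the over-correction of a raw t(df_pooled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import CountTable

logger = logging.getLogger("merip_conjoint")

UP, DOWN, NDE = "UP", "DOWN", "NDE"
LN2_SQ = math.log(2) ** 2

#: weight of the per-gene moment dispersion in the shrinkage mix
DISPERSION_SHRINK_WEIGHT = 0.5

RESULT_COLUMNS = ("log2fc", "pvalue", "fdr", "direction")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalize_library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Only features with all-positive counts enter the reference; if none
    exist, falls back to total-count factors (normalized to geometric mean 1)
    with a warning.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        logs = np.log(arr[positive])
        ref = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - ref, axis=0))
    else:
        logger.warning(
            "no feature with all-positive counts; using total-count size factors"
        )
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            factors = np.ones(arr.shape[1])
        else:
            factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.columns)


def _directions(log2fc: np.ndarray, fdr: np.ndarray, alpha: float) -> np.ndarray:
    out = np.full(log2fc.shape, NDE, dtype=object)
    out[(fdr < alpha) & (log2fc > 0)] = UP
    out[(fdr < alpha) & (log2fc < 0)] = DOWN
    return out


# ---------------------------------------------------------------------------
# Peak test
# ---------------------------------------------------------------------------

def pooled_fisher_test(
    ip_a: int, input_a: int, ip_b: int, input_b: int
) -> Tuple[float, float]:
    """Two-sided Fisher's exact p and log2 enrichment FC for one 2x2 table.

    log2FC = log2[(IP_b/input_b)/(IP_a/input_a)], with a Haldane 0.5
    continuity correction on all cells when any cell is zero (for the fold
    change only, never for the exact test).
    """
    table = np.array([[ip_a, input_a], [ip_b, input_b]], dtype=np.int64)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    cells = table.astype(float)
    if (cells == 0).any():
        cells = cells + 0.5
    log2fc = math.log2((cells[1, 0] / cells[1, 1]) / (cells[0, 0] / cells[0, 1]))
    return float(p), float(log2fc)


def _group_matrices(
    table: CountTable, group: str
) -> Tuple[np.ndarray, np.ndarray, List[str], List[str]]:
    ip_cols = table.samples_in(group, "IP")
    in_cols = table.samples_in(group, "input")
    if not ip_cols or not in_cols:
        raise ValueError(f"group {group!r} needs >= 1 IP and >= 1 input sample")
    return (
        table.counts[ip_cols].to_numpy(float),
        table.counts[in_cols].to_numpy(float),
        ip_cols,
        in_cols,
    )


def test_diff_peaks(
    table: CountTable,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    method: str = "nb",
) -> pd.DataFrame:
    """Differential methylation per peak, group B relative to group A.

    Returns a frame indexed by peak id with columns ``log2fc``, ``pvalue``,
    ``fdr`` and ``direction``.
    """
    ip_a, in_a, ip_a_cols, in_a_cols = _group_matrices(table, group_a)
    ip_b, in_b, ip_b_cols, in_b_cols = _group_matrices(table, group_b)
    sf_ip = normalize_library_sizes(table.counts[ip_a_cols + ip_b_cols])
    sf_in = normalize_library_sizes(table.counts[in_a_cols + in_b_cols])
    ip_a /= sf_ip[ip_a_cols].to_numpy()
    ip_b /= sf_ip[ip_b_cols].to_numpy()
    in_a /= sf_in[in_a_cols].to_numpy()
    in_b /= sf_in[in_b_cols].to_numpy()

    if method == "fisher":
        pvals = np.empty(len(table.counts))
        lfcs = np.empty(len(table.counts))
        for i in range(len(table.counts)):
            pvals[i], lfcs[i] = pooled_fisher_test(
                int(round(ip_a[i].sum())),
                int(round(in_a[i].sum())),
                int(round(ip_b[i].sum())),
                int(round(in_b[i].sum())),
            )
    elif method == "nb":
        pvals, lfcs = _nb_enrichment_test(ip_a, in_a, ip_b, in_b)
    else:
        raise ValueError(f"unknown peak test method {method!r}")

    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "log2fc": lfcs,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": _directions(lfcs, fdr, alpha),
        },
        index=table.counts.index,
    )


def _nb_enrichment_test(
    ip_a: np.ndarray, in_a: np.ndarray, ip_b: np.ndarray, in_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Moderated z-test on per-replicate log2 enrichment (see module docstring)."""
    pseudo = 0.5
    y_a = np.log2((ip_a + pseudo) / (in_a + pseudo))
    y_b = np.log2((ip_b + pseudo) / (in_b + pseudo))
    n_a, n_b = y_a.shape[1], y_b.shape[1]
    lfc = y_b.mean(axis=1) - y_a.mean(axis=1)

    mu = {
        "ip_a": ip_a.mean(axis=1), "in_a": in_a.mean(axis=1),
        "ip_b": ip_b.mean(axis=1), "in_b": in_b.mean(axis=1),
    }
    # Poisson (counting) part of var(y) per replicate, natural-log scale
    c_a = 1.0 / (mu["ip_a"] + pseudo) + 1.0 / (mu["in_a"] + pseudo)
    c_b = 1.0 / (mu["ip_b"] + pseudo) + 1.0 / (mu["in_b"] + pseudo)

    # common dispersion from the pooled within-group residual variance:
    # E[pooled var(y) * ln2^2] ~ mean Poisson part + 2*phi
    df_a, df_b = max(n_a - 1, 0), max(n_b - 1, 0)
    if df_a + df_b > 0:
        ss = (
            ((y_a - y_a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            + ((y_b - y_b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        )
        pooled_var = ss / (df_a + df_b)
        c_mean = (df_a * c_a + df_b * c_b) / (df_a + df_b)
        phi = max(0.0, float(np.mean(pooled_var * LN2_SQ - c_mean)) / 2.0)
    else:
        phi = 0.0

    var_lfc = ((c_a + 2 * phi) / n_a + (c_b + 2 * phi) / n_b) / LN2_SQ
    se = np.sqrt(np.maximum(var_lfc, 1e-12))
    z = lfc / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return pvals, lfc


# ---------------------------------------------------------------------------
# Gene test
# ---------------------------------------------------------------------------

def test_diff_genes(
    table: CountTable,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression per gene, group B relative to group A (NB-Wald
    with moment dispersion shrunk 50% toward the common dispersion)."""
    cols_a = table.samples_in(group_a)
    cols_b = table.samples_in(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    sf = normalize_library_sizes(table.counts[cols_a + cols_b])
    a = table.counts[cols_a].to_numpy(float) / sf[cols_a].to_numpy()
    b = table.counts[cols_b].to_numpy(float) / sf[cols_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    df = n_a + n_b - 2

    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    mu_pooled = np.concatenate([a, b], axis=1).mean(axis=1)
    ss = (
        ((a - mu_a[:, None]) ** 2).sum(axis=1)
        + ((b - mu_b[:, None]) ** 2).sum(axis=1)
    )
    var_pooled = ss / df

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_gene = np.where(
            mu_pooled > 0,
            np.clip((var_pooled - mu_pooled) / np.maximum(mu_pooled, 1e-12) ** 2, 0, None),
            0.0,
        )
    expressed = mu_pooled > 0
    phi_common = float(phi_gene[expressed].mean()) if expressed.any() else 0.0
    w = DISPERSION_SHRINK_WEIGHT
    phi = w * phi_gene + (1 - w) * phi_common

    eps = 0.5
    lfc = np.log2((mu_b + eps) / (mu_a + eps))
    v_a = (mu_a + phi * mu_a**2) / n_a
    v_b = (mu_b + phi * mu_b**2) / n_b
    var_lfc = (v_a / (mu_a + eps) ** 2 + v_b / (mu_b + eps) ** 2) / LN2_SQ
    se = np.sqrt(np.maximum(var_lfc, 1e-12))
    z = lfc / se
    # Satterthwaite-style moderated df for the shrunk variance estimate
    df_eff = df / (w**2)
    pvals = 2 * stats.t.sf(np.abs(z), df=df_eff)
    all_zero = ~expressed
    pvals[all_zero] = 1.0
    lfc[all_zero] = 0.0

    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": _directions(lfc, fdr, alpha),
        },
        index=table.counts.index,
    )


# ---------------------------------------------------------------------------
# Intensities, volcano labels, qPCR
# ---------------------------------------------------------------------------

def peak_log2_intensity(
    table: CountTable, group: str, pseudo: float = 0.5, use_input: bool = True
) -> pd.Series:
    """Per-peak log2 intensity for one group.

    Intensity is the size-factor-normalized mean IP over mean input ratio
    (``use_input=False`` switches to the raw normalized IP mean).
    """
    ip_cols = table.samples_in(group, "IP")
    sf_ip = normalize_library_sizes(table.counts[ip_cols])
    ip = (table.counts[ip_cols].to_numpy(float) / sf_ip.to_numpy()).mean(axis=1)
    if use_input:
        in_cols = table.samples_in(group, "input")
        sf_in = normalize_library_sizes(table.counts[in_cols])
        inp = (table.counts[in_cols].to_numpy(float) / sf_in.to_numpy()).mean(axis=1)
        vals = np.log2((ip + pseudo) / (inp + pseudo))
    else:
        vals = np.log2(ip + pseudo)
    return pd.Series(vals, index=table.counts.index, name=group)


def log2_intensity_cdf(
    intensities_by_group: Mapping[str, Sequence[float]]
) -> Dict[str, pd.DataFrame]:
    """Empirical CDFs per group: sorted unique values with cumulative k/n.

    Duplicate values collapse into a single step of the combined height.
    """
    out: Dict[str, pd.DataFrame] = {}
    for group, values in intensities_by_group.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            out[group] = pd.DataFrame(columns=["value", "cdf"])
            continue
        if not np.isfinite(arr).all():
            raise ValueError(f"group {group!r}: intensities must be finite")
        uniq, counts = np.unique(arr, return_counts=True)
        out[group] = pd.DataFrame(
            {"value": uniq, "cdf": np.cumsum(counts) / arr.size}
        )
    return out


def volcano_labels(
    results: pd.DataFrame,
    top_n: int = 10,
    lfc_cut: float = 4.0,
    alpha: float = 0.05,
) -> List:
    """Feature ids to label on a volcano plot: the ``top_n`` most significant
    differential features plus every feature with |log2FC| strictly above
    ``lfc_cut``."""
    sig = results[results["fdr"] < alpha]
    top = sig.sort_values(["fdr", "pvalue"], kind="mergesort").head(top_n)
    extreme = results[results["log2fc"].abs() > lfc_cut]
    labels = list(dict.fromkeys(list(top.index) + list(extreme.index)))
    return labels


@dataclass(frozen=True)
class QpcrRecord:
    """Replicate-mean Ct values for one target gene in a treated/control pair."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self):
        for name in (
            "ct_target_treated",
            "ct_reference_treated",
            "ct_target_control",
            "ct_reference_control",
        ):
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"missing Ct value: {name}")
            if not (value > 0):
                raise ValueError(f"Ct values must be positive ({name}={value})")

    @property
    def delta_ct_treated(self) -> float:
        return self.ct_target_treated - self.ct_reference_treated

    @property
    def delta_ct_control(self) -> float:
        return self.ct_target_control - self.ct_reference_control

    @property
    def delta_delta_ct(self) -> float:
        return self.delta_ct_treated - self.delta_ct_control


def ddct_relative_expression(record: QpcrRecord) -> float:
    """Relative expression by the 2^-ddCt method."""
    return 2.0 ** (-record.delta_delta_ct)
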