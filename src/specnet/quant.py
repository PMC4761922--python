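"""Spectral-count quantification: normalization, inclusion filtering,
differential expression, volcano construction, the spectra-per-kDa abundance
index and the ddCt qPCR helper.

Normalization rescales each sample to the mean raw total:
``n_ij = s_ij * mean_j(S_j) / S_j`` where ``S_j`` is sample j's total
assigned spectra, so every normalized column total equals the mean total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import SpectralCountTable, TableValidationError

logger = logging.getLogger(__name__)

SIG_TIERS = ("ns", "p05", "p01")


@dataclass
class NormalizedTable:
    """Normalized spectra with the provenance totals used to compute them."""

    values: pd.DataFrame          # proteins x samples, float
    groups: dict[str, str]
    sample_totals: pd.Series      # raw totals S_j
    mean_total: float             # S-bar

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize(table: SpectralCountTable) -> NormalizedTable:
    """Scale every sample to the mean raw spectral total."""
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise TableValidationError(f"sample {zero.index[0]!r} has zero total spectra")
    mean_total = float(totals.mean())
    values = table.counts * (mean_total / totals)
    return NormalizedTable(
        values=values.astype(float),
        groups=dict(table.groups),
        sample_totals=totals.astype(float),
        mean_total=mean_total,
    )


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided pooled-variance (classic unpaired) t-test.

    Returns (t, p, degenerate).  With zero pooled variance the test is
    degenerate: equal means report p = 1.0, unequal means p = 0.0.
    """
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    dmean = x.mean() - y.mean()
    if sp2 == 0.0:
        return (0.0, 1.0, True) if dmean == 0.0 else (np.inf, 0.0, True)
    t = dmean / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), nx + ny - 2)
    return float(t), float(min(p, 1.0)), False


def differential(
    norm: NormalizedTable,
    case: str,
    control: str,
    unique_peptides: pd.DataFrame | None = None,
    epsilon: float = 0.5,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-protein unpaired two-tailed t-test on normalized spectra.

    Fold change is ``(mean_case + epsilon) / (mean_control + epsilon)``;
    ``passed_filter`` is True iff the protein has >= 2 unique peptides in at
    least one sample.  Proteins failing the filter carry no p-value.  A BH
    adjusted-p column is emitted for information only; tiers use raw p.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    groups = norm.groups
    case_samples = [s for s in norm.sample_ids if groups[s] == case]
    ctrl_samples = [s for s in norm.sample_ids if groups[s] == control]
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise TableValidationError(
            f"need >=2 samples per group, got {len(case_samples)} {case!r} "
            f"and {len(ctrl_samples)} {control!r}"
        )
    X = norm.values[case_samples].to_numpy()
    Y = norm.values[ctrl_samples].to_numpy()

    if unique_peptides is not None:
        passed = unique_peptides.reindex(norm.values.index).max(axis=1) >= 2
    else:
        logger.warning("no unique-peptide evidence supplied; all proteins pass the filter")
        passed = pd.Series(True, index=norm.values.index)

    mean_case = X.mean(axis=1)
    mean_ctrl = Y.mean(axis=1)
    fc = (mean_case + epsilon) / (mean_ctrl + epsilon)

    t_vals = np.full(len(norm.values), np.nan)
    p_vals = np.full(len(norm.values), np.nan)
    degen = np.zeros(len(norm.values), dtype=bool)
    for i in range(len(norm.values)):
        if not passed.iloc[i]:
            continue
        if welch:
            t, p = stats.ttest_ind(X[i], Y[i], equal_var=False)
            if np.isnan(p):  # zero variance in both groups
                t, p, d = _pooled_t(X[i], Y[i])
                degen[i] = d
            t_vals[i], p_vals[i] = float(t), float(p)
        else:
            t_vals[i], p_vals[i], degen[i] = _pooled_t(X[i], Y[i])
    if degen.any():
        logger.info("%d protein(s) with degenerate (zero-variance) t-test", int(degen.sum()))

    tier = np.where(p_vals <= 0.01, "p01", np.where(p_vals <= 0.05, "p05", "ns"))
    tier = np.where(np.isnan(p_vals), "ns", tier)

    adj = np.full(len(p_vals), np.nan)
    ok = ~np.isnan(p_vals)
    if ok.any():
        adj[ok] = multipletests(p_vals[ok], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "t_stat": t_vals,
            "p_value": p_vals,
            "p_adjusted_bh": adj,
            "degenerate": degen,
            "passed_filter": passed.to_numpy(),
            "tier": tier,
        },
        index=norm.values.index,
    )
    out.index.name = "accession"
    return out


def volcano(de: pd.DataFrame) -> pd.DataFrame:
    """Volcano coordinates (log2 FC vs -log10 p) for filter-passing proteins."""
    kept = de[de["passed_filter"]].copy()
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(kept["p_value"])
    out = pd.DataFrame(
        {
            "log2_fc": kept["log2_fc"],
            "neg_log10_p": neg_log10_p,
            "tier": kept["tier"],
            "direction": np.where(
                kept["fold_change"] > 1, "up", np.where(kept["fold_change"] < 1, "down", "flat")
            ),
        },
        index=kept.index,
    )
    out.index.name = "accession"
    return out


AGGREGATION_MODES = ("mean_all", "sum_all", "mean_group")


def abundance_index(
    table: SpectralCountTable | NormalizedTable,
    meta: pd.DataFrame,
    mode: str = "mean_all",
    group: str | None = None,
) -> pd.DataFrame:
    """Spectra-per-kDa abundance index with dense descending rank.

    ``mode`` selects the numerator aggregate: mean over all samples
    (default), sum over all samples, or the mean over one group's samples.
    """
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    values = table.values if isinstance(table, NormalizedTable) else table.counts
    groups = table.groups
    if mode == "mean_all":
        agg = values.mean(axis=1)
    elif mode == "sum_all":
        agg = values.sum(axis=1)
    else:
        if group is None:
            raise ValueError("mode 'mean_group' requires a group name")
        cols = [s for s in values.columns if groups[s] == group]
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        agg = values[cols].mean(axis=1)

    mass = meta["mass_kda"].reindex(values.index)
    missing = mass.index[~np.isfinite(mass)].tolist()
    if missing:
        raise TableValidationError(f"missing molecular mass for accessions: {missing}")
    ratio = agg / mass
    out = pd.DataFrame(
        {
            "gene_symbol": meta["gene_symbol"].reindex(values.index),
            "aggregate_spectra": agg.astype(float),
            "mass_kda": mass.astype(float),
            "ratio": ratio.astype(float),
        },
        index=values.index,
    )
    out["rank"] = out["ratio"].rank(method="dense", ascending=False).astype(int)
    out.index.name = "accession"
    return out.sort_values(["rank", "gene_symbol"])


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR expression: FC = 2**-ddCt against a housekeeping gene."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
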