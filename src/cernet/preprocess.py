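"""Expression filtering/normalization, DE labeling, and gene-centric
aggregation of methylation and copy number.

The negative-binomial exact test and moderated linear-model statistics used
by typical RNA-seq workflows are deliberately not reproduced here: DE labels
are a pipeline input, and :func:`simple_de_test` is a documented two-group
surrogate for synthetic runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    ExpressionMatrix,
    GeneAnnotation,
    ProbeAnnotation,
    SegmentTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "DELabelTable",
    "counts_to_cpm",
    "cpm_filter",
    "simple_de_test",
    "log_and_znormalize",
    "promoter_methylation",
    "segments_to_gene_cna",
    "bh_adjust",
    "bonferroni_adjust",
]


@dataclass
class PreprocessConfig:
    cpm_threshold: float = 1.0
    de_alpha: float = 0.01
    log_offset: float = 0.001
    promoter_min_upstream: int = 200
    promoter_max_upstream: int = 1500
    adjust_method: str = "bh"  # "bh" or "bonferroni"

    def __post_init__(self) -> None:
        for name in (
            "cpm_threshold",
            "de_alpha",
            "log_offset",
            "promoter_min_upstream",
            "promoter_max_upstream",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.adjust_method not in {"bh", "bonferroni"}:
            raise ValueError("adjust_method must be 'bh' or 'bonferroni'")


@dataclass
class DELabelTable:
    """Per-feature differential-expression labels.

    ``table`` columns: feature_id, log_fold_change, adjusted_p, is_DE.
    The label invariant is is_DE <=> adjusted_p < de_alpha.
    """

    table: pd.DataFrame
    de_alpha: float = 0.01

    def __post_init__(self) -> None:
        t = self.table
        needed = {"feature_id", "log_fold_change", "adjusted_p", "is_DE"}
        missing = needed - set(t.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        p = t["adjusted_p"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("adjusted p-values must lie in [0, 1]")
        expect = p < self.de_alpha
        if (t["is_DE"].to_numpy(dtype=bool) != expect).any():
            raise ValueError("is_DE labels inconsistent with adjusted_p < de_alpha")

    @property
    def de_ids(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_DE"], "feature_id"])

    @classmethod
    def all_de(cls, feature_ids, de_alpha: float = 0.01) -> "DELabelTable":
        """A table marking every feature DE (for post-DE synthetic data)."""
        return cls(
            pd.DataFrame(
                {
                    "feature_id": list(feature_ids),
                    "log_fold_change": 0.0,
                    "adjusted_p": 0.0,
                    "is_DE": True,
                }
            ),
            de_alpha,
        )


def counts_to_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to counts-per-million, per sample."""
    if m.unit != "raw_count":
        raise ValueError(f"expected raw_count matrix, got {m.unit}")
    libsize = m.values.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = m.values.div(libsize, axis=1) * 1e6
    return ExpressionMatrix(cpm, m.feature_kind, "cpm", dict(m.sample_groups))


def cpm_filter(
    m: ExpressionMatrix,
    groups: dict[str, str] | None = None,
    cfg: PreprocessConfig | None = None,
) -> list[str]:
    """Low-expression filter.

    With t = max(#normal, #tumor) samples, a feature is kept iff its CPM is
    below ``cpm_threshold`` in at most t samples (dropped when the low-CPM
    count strictly exceeds t).
    """
    cfg = cfg or PreprocessConfig()
    groups = groups if groups is not None else m.sample_groups
    n_normal = sum(1 for s in m.sample_ids if groups.get(s) == "normal")
    n_tumor = sum(1 for s in m.sample_ids if groups.get(s) == "tumor")
    if n_normal == 0 or n_tumor == 0:
        raise ValueError("both normal and tumor groups must be non-empty")
    t = max(n_normal, n_tumor)
    cpm = counts_to_cpm(m) if m.unit == "raw_count" else m
    low = (cpm.values < cfg.cpm_threshold).sum(axis=1)
    return [f for f, n_low in low.items() if n_low <= t]


def simple_de_test(
    m: ExpressionMatrix,
    groups: dict[str, str] | None = None,
    method: str = "wilcoxon",
    cfg: PreprocessConfig | None = None,
) -> DELabelTable:
    """Two-group DE surrogate (rank-sum or Welch t), BH-adjusted.

    Log fold change is mean(log2 tumor) - mean(log2 normal), computed on the
    input as given when already log-like, else on log2(x + offset).
    """
    cfg = cfg or PreprocessConfig()
    groups = groups if groups is not None else m.sample_groups
    if method not in {"wilcoxon", "welch_t"}:
        raise ValueError(f"unknown method {method!r}")
    normal = [s for s in m.sample_ids if groups.get(s) == "normal"]
    tumor = [s for s in m.sample_ids if groups.get(s) == "tumor"]
    if len(normal) < 2 or len(tumor) < 2:
        raise ValueError("need >= 2 samples per group")

    vals = m.values
    if m.unit in {"log2", "zscore", "cna", "arbitrary"}:
        logv = vals
    else:
        logv = np.log2(vals + cfg.log_offset)

    pvals = np.empty(m.n_features)
    lfc = np.empty(m.n_features)
    a = vals[tumor].to_numpy(dtype=float)
    b = vals[normal].to_numpy(dtype=float)
    la = logv[tumor].to_numpy(dtype=float)
    lb = logv[normal].to_numpy(dtype=float)
    for i in range(m.n_features):
        lfc[i] = la[i].mean() - lb[i].mean()
        if np.ptp(a[i]) == 0 and np.ptp(b[i]) == 0 and a[i][0] == b[i][0]:
            warnings.warn(f"constant feature {m.feature_ids[i]!r}: p set to 1")
            pvals[i] = 1.0
            continue
        if method == "wilcoxon":
            pvals[i] = stats.mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
        else:
            pvals[i] = stats.ttest_ind(a[i], b[i], equal_var=False).pvalue
    adj = (
        bh_adjust(pvals)
        if cfg.adjust_method == "bh"
        else bonferroni_adjust(pvals)
    )
    return DELabelTable(
        pd.DataFrame(
            {
                "feature_id": m.feature_ids,
                "log_fold_change": lfc,
                "adjusted_p": adj,
                "is_DE": adj < cfg.de_alpha,
            }
        ),
        cfg.de_alpha,
    )


def log_and_znormalize(
    m: ExpressionMatrix,
    tumor_sample_ids: list[str] | None = None,
    cfg: PreprocessConfig | None = None,
) -> ExpressionMatrix:
    """log2(x + offset), then per-feature z-normalization over tumor samples.

    Output is restricted to the tumor samples.  Zero-variance rows after the
    log transform are dropped (logged), never imputed.
    """
    cfg = cfg or PreprocessConfig()
    if tumor_sample_ids is None:
        tumor_sample_ids = [
            s for s in m.sample_ids if m.sample_groups.get(s) == "tumor"
        ]
    missing = set(tumor_sample_ids) - set(m.sample_ids)
    if missing:
        raise ValueError(f"tumor samples not in matrix: {sorted(missing)}")
    sub = m.values[tumor_sample_ids]
    logged = np.log2(sub + cfg.log_offset)
    sd = logged.std(axis=1, ddof=0)
    dropped = list(logged.index[sd == 0])
    if dropped:
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped)
    kept = logged.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(kept.std(axis=1, ddof=0), axis=0)
    groups = {s: "tumor" for s in tumor_sample_ids}
    return ExpressionMatrix(z, m.feature_kind, "zscore", groups)


def znormalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Plain per-feature z-normalization (no log), dropping constant rows."""
    sd = m.values.std(axis=1, ddof=0)
    kept = m.values.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(kept.std(axis=1, ddof=0), axis=0)
    return ExpressionMatrix(z, m.feature_kind, "zscore", dict(m.sample_groups))


def promoter_methylation(
    beta: ExpressionMatrix,
    probes: ProbeAnnotation,
    genes: GeneAnnotation,
    cfg: PreprocessConfig | None = None,
) -> ExpressionMatrix:
    """Aggregate probe beta values to gene promoters.

    A probe belongs to a gene's promoter when its position lies within
    [tss - 1500, tss - 200] on '+' strand genes and [tss + 200, tss + 1500]
    on '-' strand genes, both bounds inclusive.  The gene value is the
    arithmetic mean of its in-window probes; genes with no in-window probe
    are absent from the output.
    """
    cfg = cfg or PreprocessConfig()
    if beta.unit != "beta":
        raise ValueError(f"expected beta matrix, got {beta.unit}")
    probe_tab = probes.table.set_index("probe_id")
    rows = {}
    lo, hi = cfg.promoter_min_upstream, cfg.promoter_max_upstream
    for _, g in genes.table.iterrows():
        if g["strand"] == "+":
            win_lo, win_hi = g["tss"] - hi, g["tss"] - lo
        else:
            win_lo, win_hi = g["tss"] + lo, g["tss"] + hi
        sel = probe_tab[
            (probe_tab["chromosome"] == g["chromosome"])
            & (probe_tab["position"] >= win_lo)
            & (probe_tab["position"] <= win_hi)
        ].index
        sel = [p for p in sel if p in beta.values.index]
        if not sel:
            continue
        rows[g["gene_id"]] = beta.values.loc[sel].mean(axis=0)
    if not rows:
        return ExpressionMatrix(
            pd.DataFrame(columns=beta.values.columns, dtype=float),
            "mRNA",
            "beta",
            dict(beta.sample_groups),
        )
    out = pd.DataFrame(rows).T
    out.columns = beta.values.columns
    return ExpressionMatrix(out, "mRNA", "beta", dict(beta.sample_groups))


def segments_to_gene_cna(
    seg: SegmentTable, genes: GeneAnnotation
) -> ExpressionMatrix:
    """Gene-level copy number as the overlap-length-weighted mean of
    intersecting segment means.

    A gene with no overlapping segment in some sample is missing there;
    genes missing in any sample are dropped from the output (logged).
    """
    samples = sorted(seg.table["sample_id"].unique())
    data: dict[str, dict[str, float]] = {}
    for _, g in genes.table.iterrows():
        gs, ge = int(g["start"]), int(g["end"])
        hits = seg.table[
            (seg.table["chromosome"] == g["chromosome"])
            & (seg.table["start"] <= ge)
            & (seg.table["end"] >= gs)
        ]
        per_sample: dict[str, float] = {}
        for sample, grp in hits.groupby("sample_id"):
            ov = np.minimum(grp["end"].to_numpy(), ge) - np.maximum(
                grp["start"].to_numpy(), gs
            ) + 1
            per_sample[sample] = float(
                np.average(grp["segment_mean"].to_numpy(), weights=ov)
            )
        data[g["gene_id"]] = per_sample

    complete = {
        gid: vals
        for gid, vals in data.items()
        if set(vals) >= set(samples)
    }
    dropped = sorted(set(data) - set(complete))
    if dropped:
        logger.warning(
            "dropping %d gene(s) without CNA coverage in every sample: %s",
            len(dropped),
            dropped,
        )
    out = pd.DataFrame(
        {gid: [vals[s] for s in samples] for gid, vals in complete.items()},
        index=samples,
    ).T
    return ExpressionMatrix(out.astype(float), "mRNA", "cna", {})


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj p(i) = min_{j >= i} m * p(j) / j over the sorted p-values, capped
    at 1, mapped back to input order; ties receive equal adjusted values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bonferroni_adjust(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * len(p), 1.0)
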