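"""Step 3: candidate ceRNA pairs from shared miRNA regulators, filtered by
Pearson correlation, a hypergeometric shared-regulator test, and sensitivity
(partial) correlation with an empirical resampling null.

For a pair (i, j) with N total DE miRNAs, N_i / N_j regulators each and
N_ij shared, the over-representation p-value is

    p = 1 - sum_{k=0}^{N_ij - 1} C(N_j, k) C(N - N_j, N_i - k) / C(N, N_i)

Sensitivity correlation is SC = Corr(i, j) - PC(i, j | shared miRNAs); its
empirical p-value is the fraction of 1000 random same-size miRNA sets whose
sampled SC strictly exceeds the observed SC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, InteractionTable
from .preprocess import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "CeRNAConfig",
    "CeRNAPair",
    "candidate_pairs",
    "pearson_filter",
    "hypergeom_shared_pvalue",
    "hypergeom_filter",
    "partial_correlation",
    "sensitivity_correlation",
    "empirical_sc_pvalue",
    "sc_filter",
    "correlation_baseline",
    "infer_cerna_pairs",
    "pairs_to_frame",
]


@dataclass
class CeRNAConfig:
    min_corr: float = 0.5
    corr_p: float = 0.05
    hyper_alpha: float = 0.05
    sc_resamples: int = 1000
    sc_alpha: float = 0.05
    pc_p_alpha: float = 0.05
    sc_filter_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("corr_p", "hyper_alpha", "sc_alpha", "pc_p_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (-1 <= self.min_corr <= 1):
            raise ValueError("min_corr must lie in [-1, 1]")
        if self.sc_resamples <= 0:
            raise ValueError("sc_resamples must be positive")


@dataclass
class CeRNAPair:
    """All statistics for one candidate ceRNA pair (rna_i < rna_j)."""

    rna_i: str
    rna_j: str
    shared_mirnas: tuple[str, ...]
    n_total: int
    n_i: int
    n_j: int
    n_ij: int
    pearson_r: float = np.nan
    pearson_p: float = np.nan
    hyper_p: float = np.nan
    hyper_p_adj: float = np.nan
    pc: float = np.nan
    sc: float = np.nan
    pc_p: float = np.nan
    sc_empirical_p: float = np.nan
    passed: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rna_i > self.rna_j:
            raise ValueError("pair must be ordered rna_i < rna_j")
        if not (1 <= self.n_ij <= min(self.n_i, self.n_j) <= self.n_total):
            raise ValueError(
                f"invalid counts for ({self.rna_i}, {self.rna_j}): "
                f"N={self.n_total} Ni={self.n_i} Nj={self.n_j} Nij={self.n_ij}"
            )

    @property
    def corr(self) -> float:
        return self.pearson_r


def candidate_pairs(
    mirna_rna_net: InteractionTable, n_total_mirnas: int | None = None
) -> list[CeRNAPair]:
    """All unordered RNA pairs sharing at least one miRNA regulator.

    ``n_total_mirnas`` is N in the hypergeometric test — the size of the DE
    miRNA universe; it defaults to the number of distinct miRNAs in the
    network (log-noted, configurable upstream).
    """
    t2r = mirna_rna_net.targets_to_regulators()
    n_total = (
        n_total_mirnas
        if n_total_mirnas is not None
        else len(set(mirna_rna_net.table["regulator"]))
    )
    pairs: list[CeRNAPair] = []
    for a, b in combinations(sorted(t2r), 2):
        shared = t2r[a] & t2r[b]
        if not shared:
            continue
        pairs.append(
            CeRNAPair(
                rna_i=a,
                rna_j=b,
                shared_mirnas=tuple(sorted(shared)),
                n_total=n_total,
                n_i=len(t2r[a]),
                n_j=len(t2r[b]),
                n_ij=len(shared),
            )
        )
    return pairs


def _sym_corr(x: np.ndarray, y: np.ndarray) -> float:
    # symmetric in (x, y) to the last ulp, unlike np.corrcoef
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc * xc).sum() * (yc * yc).sum()))


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    r = max(-1.0, min(1.0, _sym_corr(x, y)))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * stats.t.sf(abs(t), n - 2))


def pearson_filter(
    pairs: list[CeRNAPair], expr: ExpressionMatrix, cfg: CeRNAConfig
) -> list[CeRNAPair]:
    """Fill pearson_r/p and keep pairs with r >= min_corr and p < corr_p."""
    kept = []
    for p in pairs:
        x = expr.row(p.rna_i)
        y = expr.row(p.rna_j)
        p.pearson_r, p.pearson_p = _pearson(x, y)
        ok = p.pearson_r >= cfg.min_corr and p.pearson_p < cfg.corr_p
        p.passed["pearson"] = ok
        if ok:
            kept.append(p)
    return kept


def hypergeom_shared_pvalue(n_total: int, n_i: int, n_j: int, n_ij: int) -> float:
    """P[overlap >= n_ij] when n_i of n_total miRNAs are drawn against a
    fixed set of n_j (hypergeometric upper tail)."""
    if not (1 <= n_ij <= min(n_i, n_j) <= n_total) or max(n_i, n_j) > n_total:
        raise ValueError(
            f"invalid hypergeometric bounds: N={n_total} Ni={n_i} Nj={n_j} Nij={n_ij}"
        )
    # survival function at n_ij - 1 gives P[X >= n_ij]
    p = float(stats.hypergeom.sf(n_ij - 1, n_total, n_j, n_i))
    return min(max(p, 0.0), 1.0)


def hypergeom_filter(pairs: list[CeRNAPair], cfg: CeRNAConfig) -> list[CeRNAPair]:
    """BH-adjust the hypergeometric p over the pairs reaching this stage and
    keep those with adjusted p < hyper_alpha."""
    if not pairs:
        return []
    for p in pairs:
        p.hyper_p = hypergeom_shared_pvalue(p.n_total, p.n_i, p.n_j, p.n_ij)
    adj = bh_adjust([p.hyper_p for p in pairs])
    kept = []
    for p, a in zip(pairs, adj):
        p.hyper_p_adj = float(a)
        ok = p.hyper_p_adj < cfg.hyper_alpha
        p.passed["hypergeom"] = ok
        if ok:
            kept.append(p)
    return kept


def partial_correlation(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given conditioning columns Z.

    Computed as the correlation of the residuals of x and y after linear
    regression (with intercept) on Z; the p-value uses the t statistic
    pc * sqrt((n - 2 - |Z|) / (1 - pc^2)) on n - 2 - |Z| df, two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if Z is None or (hasattr(Z, "size") and Z.size == 0):
        k = 0
        rx, ry = x, y
    else:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        k = Z.shape[1]
        if n <= k + 2:
            raise ValueError("need n > |Z| + 2 samples")
        A = np.column_stack([np.ones(n), Z])
        rank = np.linalg.matrix_rank(A)
        if rank < k + 1:
            raise ValueError(
                "conditioning set is rank deficient (collinear columns)"
            )
        coef_x, _, _, _ = np.linalg.lstsq(A, x, rcond=None)
        coef_y, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        rx = x - A @ coef_x
        ry = y - A @ coef_y
    # residual variance below float precision of the input scale means the
    # variable is (numerically) fully explained by Z
    tol = 1e-24
    if (
        rx.var() <= tol * max(x.var(), 1e-300)
        or ry.var() <= tol * max(y.var(), 1e-300)
    ):
        return 0.0, 1.0
    pc = max(-1.0, min(1.0, _sym_corr(rx, ry)))
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough samples for the partial-correlation test")
    if abs(pc) == 1.0:
        return pc, 0.0
    t = pc * np.sqrt(df / (1 - pc * pc))
    return pc, float(2 * stats.t.sf(abs(t), df))


def sensitivity_correlation(
    pair: CeRNAPair, expr: ExpressionMatrix, mirna_expr: ExpressionMatrix
) -> CeRNAPair:
    """Fill pc, pc_p and sc = corr - pc for the pair's shared miRNA set."""
    x = expr.row(pair.rna_i)
    y = expr.row(pair.rna_j)
    if np.isnan(pair.pearson_r):
        pair.pearson_r, pair.pearson_p = _pearson(x, y)
    Z = np.column_stack([mirna_expr.row(m) for m in pair.shared_mirnas])
    pair.pc, pair.pc_p = partial_correlation(x, y, Z)
    pair.sc = pair.pearson_r - pair.pc
    return pair


def empirical_sc_pvalue(
    pair: CeRNAPair,
    expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    mirna_pool: list[str],
    cfg: CeRNAConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Resampling null for SC.

    Draw N_ij miRNAs uniformly without replacement from ``mirna_pool``,
    recompute SC with that conditioning set, and report the fraction of
    ``sc_resamples`` draws whose sampled SC strictly exceeds the observed
    SC (so p = 0 is attainable; no pseudo-count).
    """
    if len(mirna_pool) < pair.n_ij:
        raise ValueError("miRNA pool smaller than the shared set")
    if len(mirna_pool) == pair.n_ij:
        warnings.warn(
            f"pool size equals N_ij for ({pair.rna_i}, {pair.rna_j}); "
            "empirical p is degenerate"
        )
    rng = rng or np.random.default_rng(cfg.seed)
    x = expr.row(pair.rna_i)
    y = expr.row(pair.rna_j)
    pool_rows = np.vstack([mirna_expr.row(m) for m in mirna_pool])
    exceed = 0
    for _ in range(cfg.sc_resamples):
        idx = rng.choice(len(mirna_pool), size=pair.n_ij, replace=False)
        pc, _ = partial_correlation(x, y, pool_rows[idx].T)
        if pair.pearson_r - pc > pair.sc:
            exceed += 1
    return exceed / cfg.sc_resamples


def sc_filter(pairs: list[CeRNAPair], cfg: CeRNAConfig) -> list[CeRNAPair]:
    """Keep pairs with sc > 0, pc_p < pc_p_alpha and empirical p < sc_alpha.

    With ``cfg.sc_filter_enabled = False`` the stage passes every pair
    through unchanged (the deactivated-filter variant)."""
    if not cfg.sc_filter_enabled:
        for p in pairs:
            p.passed["sc"] = True
        return list(pairs)
    kept = []
    for p in pairs:
        ok = (
            p.sc > 0
            and p.pc_p < cfg.pc_p_alpha
            and p.sc_empirical_p < cfg.sc_alpha
        )
        p.passed["sc"] = ok
        if ok:
            kept.append(p)
    return kept


def infer_cerna_pairs(
    mirna_rna_net: InteractionTable,
    expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    cfg: CeRNAConfig | None = None,
    n_total_mirnas: int | None = None,
    mirna_pool: list[str] | None = None,
) -> tuple[list[CeRNAPair], list[CeRNAPair]]:
    """Full step-3 stack.  Returns (final pairs, all candidate pairs).

    The resampling pool defaults to every miRNA with expression available.
    """
    cfg = cfg or CeRNAConfig()
    cand = candidate_pairs(mirna_rna_net, n_total_mirnas)
    pairs = pearson_filter(cand, expr, cfg)
    pairs = hypergeom_filter(pairs, cfg)
    pool = mirna_pool if mirna_pool is not None else list(mirna_expr.feature_ids)
    rng = np.random.default_rng(cfg.seed)
    if cfg.sc_filter_enabled:
        for p in pairs:
            sensitivity_correlation(p, expr, mirna_expr)
            p.sc_empirical_p = empirical_sc_pvalue(
                p, expr, mirna_expr, pool, cfg, rng
            )
        pairs = sc_filter(pairs, cfg)
    else:
        for p in pairs:
            sensitivity_correlation(p, expr, mirna_expr)
        pairs = sc_filter(pairs, cfg)
    return pairs, cand


def correlation_baseline(
    expr: ExpressionMatrix,
    putative_net: InteractionTable,
    mirna_expr: ExpressionMatrix,
    cfg: CeRNAConfig | None = None,
) -> tuple[list[CeRNAPair], list[CeRNAPair]]:
    """Correlation-only variant: keep miRNA->RNA edges with negative
    correlation (p < 0.05), then pair RNAs sharing such a miRNA and keep
    pairs passing only the Pearson stage."""
    cfg = cfg or CeRNAConfig()
    t = putative_net.table
    rows = []
    for reg, tgt in zip(t["regulator"], t["target"]):
        if reg not in mirna_expr.values.index or tgt not in expr.values.index:
            continue
        r, pv = _pearson(mirna_expr.row(reg), expr.row(tgt))
        if r < 0 and pv < 0.05:
            rows.append((reg, tgt))
    if not rows:
        return [], []
    df = pd.DataFrame(rows, columns=["regulator", "target"], dtype=str)
    df["regulator_kind"] = "miRNA"
    df["source"] = "corr_baseline"
    net = InteractionTable(df)
    cand = candidate_pairs(net)
    kept = pearson_filter(cand, expr, cfg)
    return kept, cand


def pairs_to_frame(pairs: list[CeRNAPair]) -> pd.DataFrame:
    """Serialize pairs (lexicographic order) with every statistic and flag."""
    rows = []
    for p in sorted(pairs, key=lambda q: (q.rna_i, q.rna_j)):
        rows.append(
            {
                "rna_i": p.rna_i,
                "rna_j": p.rna_j,
                "shared_mirnas": ";".join(p.shared_mirnas),
                "N": p.n_total,
                "N_i": p.n_i,
                "N_j": p.n_j,
                "N_ij": p.n_ij,
                "pearson_r": p.pearson_r,
                "pearson_p": p.pearson_p,
                "hyper_p": p.hyper_p,
                "hyper_p_adj": p.hyper_p_adj,
                "pc": p.pc,
                "sc": p.sc,
                "pc_p": p.pc_p,
                "sc_empirical_p": p.sc_empirical_p,
                "pass_pearson": p.passed.get("pearson", False),
                "pass_hypergeom": p.passed.get("hypergeom", False),
                "pass_sc": p.passed.get("sc", False),
            }
        )
    cols = [
        "rna_i", "rna_j", "shared_mirnas", "N", "N_i", "N_j", "N_ij",
        "pearson_r", "pearson_p", "hyper_p", "hyper_p_adj", "pc", "sc",
        "pc_p", "sc_empirical_p", "pass_pearson", "pass_hypergeom", "pass_sc",
    ]
    return pd.DataFrame(rows, columns=cols)
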