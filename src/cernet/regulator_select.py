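"""Step 2: per-RNA LASSO-based regulator selection.

For each RNA the response is its z-scored tumor expression; covariates are
its candidate miRNA expressions plus, for mRNAs, its own copy number,
promoter methylation, and candidate TF expressions.  Selection combines

* repeated 10-fold-CV LASSO at the one-standard-error lambda (fold
  assignment re-randomized per run; strict > threshold on selection count),
* a percentile bootstrap confidence-interval filter (full refit, lambda
  re-selected per resample), and
* retention of miRNAs with negative median coefficient only.

All randomness flows from a single seed; repeated invocation is bitwise
reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .core_io import InteractionTable

logger = logging.getLogger(__name__)

__all__ = [
    "LassoConfig",
    "RegressionDesign",
    "RegulatorSelection",
    "fit_lasso_one_se",
    "lasso_coefficients",
    "scaled_config",
    "stability_select",
    "bootstrap_ci_filter",
    "keep_negative_mirnas",
    "ols_select",
    "select_regulators",
    "rna_seed",
]

COVARIATE_KINDS = {"miRNA", "CNA", "DNAm", "TF"}


@dataclass
class LassoConfig:
    n_runs: int = 100
    freq_threshold: int = 75
    n_bootstrap: int = 500
    ci_level: float = 0.95
    n_folds: int = 10
    lambda_rule: str = "one_se"
    lambda_grid_size: int = 100
    lambda_min_ratio: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")
        for name in ("n_runs", "freq_threshold", "n_bootstrap", "n_folds",
                     "lambda_grid_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RegressionDesign:
    """Response and named covariate columns for one RNA.

    ``X`` is n_samples x n_covariates, column order matching
    ``covariate_names`` / ``covariate_kinds``.
    """

    rna_id: str
    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str]
    covariate_kinds: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float, order="F")
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y have inconsistent sample counts")
        if self.X.shape[1] != len(self.covariate_names):
            raise ValueError("covariate names do not match X columns")
        if len(self.covariate_names) != len(self.covariate_kinds):
            raise ValueError("covariate kinds do not match names")
        bad = set(self.covariate_kinds) - COVARIATE_KINDS
        if bad:
            raise ValueError(f"unknown covariate kinds: {sorted(bad)}")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("duplicate covariate names")
        if self.X.shape[1] and (np.ptp(self.X, axis=0) == 0).any():
            const = [
                n for n, c in zip(self.covariate_names, np.ptp(self.X, axis=0))
                if c == 0
            ]
            raise ValueError(f"constant covariate column(s): {const}")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class RegulatorSelection:
    """Per-covariate selection outcome for one RNA.

    ``table`` columns: rna_id, covariate, kind, selection_count,
    median_coefficient, ci_lo, ci_hi, frequently_selected, kept.
    """

    table: pd.DataFrame
    n_runs: int
    freq_threshold: int

    def __post_init__(self) -> None:
        t = self.table
        freq = t["selection_count"].to_numpy() > self.freq_threshold
        if (t["frequently_selected"].to_numpy(dtype=bool) != freq).any():
            raise ValueError("frequently_selected inconsistent with counts")
        if (t["kept"] & ~t["frequently_selected"]).any():
            raise ValueError("kept covariate that is not frequently selected")

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["kept"]]


def scaled_config(cfg: LassoConfig, n_runs: int, n_bootstrap: int) -> LassoConfig:
    """Reduce run/bootstrap counts while keeping the selection-frequency
    threshold at the same fraction of runs (75/100 -> 37/50 etc.)."""
    frac = cfg.freq_threshold / cfg.n_runs
    return replace(
        cfg,
        n_runs=n_runs,
        n_bootstrap=n_bootstrap,
        freq_threshold=int(round(frac * n_runs)),
    )


def rna_seed(global_seed: int, rna_id: str) -> np.random.SeedSequence:
    """Per-RNA seed stream keyed by the RNA id, stable across feature sets."""
    return np.random.SeedSequence([int(global_seed), zlib.crc32(rna_id.encode())])


def _lambda_grid(Xc: np.ndarray, yc: np.ndarray, cfg: LassoConfig) -> np.ndarray:
    n = yc.shape[0]
    lam_max = np.max(np.abs(Xc.T @ yc)) / n
    if lam_max <= 0:
        lam_max = 1e-12
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.lambda_grid_size)


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(folds)
    return folds


@njit(cache=True)
def _cd_path(G: np.ndarray, c: np.ndarray, lam_n: np.ndarray,
             tol: float, max_iter: int) -> np.ndarray:
    """Coordinate-descent LASSO path on centered data.

    Solves min_b 1/(2n) ||y - Xb||^2 + alpha ||b||_1 at each penalty, using
    the Gram matrix G = X'X and covariance c = X'y; ``lam_n`` holds
    n * alpha in descending order (warm-started along the path).  The
    stationarity condition gives the soft-threshold update
    b_j = S(c_j - sum_{k != j} G_jk b_k, n*alpha) / G_jj.
    """
    p = G.shape[0]
    out = np.zeros((p, lam_n.shape[0]))
    b = np.zeros(p)
    for a in range(lam_n.shape[0]):
        lam = lam_n[a]
        for _ in range(max_iter):
            delta = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0.0:
                    b[j] = 0.0
                    continue
                rho = c[j]
                for k in range(p):
                    if k != j:
                        rho -= G[j, k] * b[k]
                if rho > lam:
                    bn = (rho - lam) / gjj
                elif rho < -lam:
                    bn = (rho + lam) / gjj
                else:
                    bn = 0.0
                d = abs(bn - b[j])
                if d > delta:
                    delta = d
                b[j] = bn
            if delta < tol:
                break
        out[:, a] = b
    return out


_CD_TOL = 1e-9
_CD_MAX_ITER = 10_000


def _path_coefs(Xc, yc, alphas) -> np.ndarray:
    # Xc, yc are pre-centered; path returned at the given (descending) alphas.
    G = Xc.T @ Xc
    c = Xc.T @ yc
    n = yc.shape[0]
    return _cd_path(G, c, np.asarray(alphas) * n, _CD_TOL, _CD_MAX_ITER)


def lasso_coefficients(design: RegressionDesign, lam: float) -> np.ndarray:
    """LASSO solution at a single penalty value (centered, unpenalized
    intercept).  Exposed for boundary checks and oracle comparisons."""
    Xc = design.X - design.X.mean(axis=0)
    yc = design.y - design.y.mean()
    return _path_coefs(Xc, yc, np.array([float(lam)]))[:, 0]


def fit_lasso_one_se(
    design: RegressionDesign,
    fold_seed: int | np.random.SeedSequence | np.random.Generator = 0,
    cfg: LassoConfig | None = None,
) -> tuple[np.ndarray, float]:
    """One LASSO fit at the one-standard-error lambda.

    The lambda grid holds ``lambda_grid_size`` log-spaced values from
    lambda_max = max_j |<x_j, y>| / n down to lambda_max * 1e-3 (computed on
    the centered full data).  Mean 10-fold CV error is evaluated on the
    grid; the chosen lambda is the largest whose mean CV error is within
    one standard error of the minimum.  Returns (coefficients, lambda).
    """
    cfg = cfg or LassoConfig()
    return _fit_one_se(design.X, design.y, cfg, _as_rng(fold_seed))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _fit_one_se(
    X: np.ndarray, y: np.ndarray, cfg: LassoConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    n, p = X.shape
    if n < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} samples, got {n}")
    if p < 1:
        raise ValueError("need at least one covariate")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = np.asfortranarray(X - xm)
    yc = y - ym
    alphas = _lambda_grid(Xc, yc, cfg)

    folds = _fold_assignment(n, cfg.n_folds, rng)
    cv_err = np.empty((cfg.n_folds, alphas.size))
    for k in range(cfg.n_folds):
        test = folds == k
        train = ~test
        Xtr = X[train]
        ytr = y[train]
        tm = Xtr.mean(axis=0)
        tym = ytr.mean()
        coefs = _path_coefs(np.asfortranarray(Xtr - tm), ytr - tym, alphas)
        pred = (X[test] - tm) @ coefs + tym  # (n_test, n_alphas)
        resid = pred - y[test][:, None]
        cv_err[k] = np.mean(resid**2, axis=0)
    mean_err = cv_err.mean(axis=0)
    i_min = int(np.argmin(mean_err))
    se_min = cv_err[:, i_min].std(ddof=1) / np.sqrt(cfg.n_folds)
    # alphas are descending: first index satisfying the rule is the largest λ
    ok = np.nonzero(mean_err <= mean_err[i_min] + se_min)[0]
    i_sel = int(ok[0])
    coefs_full = _path_coefs(Xc, yc, alphas)
    return coefs_full[:, i_sel].copy(), float(alphas[i_sel])


def stability_select(
    design: RegressionDesign, cfg: LassoConfig | None = None
) -> pd.DataFrame:
    """Repeat the one-SE LASSO fit ``n_runs`` times, varying only the CV
    fold assignment, and tally per-covariate selection counts.

    The median coefficient is taken over all runs, zeros included.
    Returns a frame with columns covariate, kind, selection_count,
    median_coefficient, frequently_selected.
    """
    cfg = cfg or LassoConfig()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_runs)
    coef_runs = np.empty((cfg.n_runs, design.p))
    for r in range(cfg.n_runs):
        coef, _ = _fit_one_se(design.X, design.y, cfg, np.random.default_rng(children[r]))
        coef_runs[r] = coef
    counts = (coef_runs != 0).sum(axis=0)
    med = np.median(coef_runs, axis=0)
    return pd.DataFrame(
        {
            "covariate": design.covariate_names,
            "kind": design.covariate_kinds,
            "selection_count": counts,
            "median_coefficient": med,
            "frequently_selected": counts > cfg.freq_threshold,
        }
    )


def bootstrap_ci_filter(
    design: RegressionDesign,
    stability: pd.DataFrame,
    cfg: LassoConfig | None = None,
) -> RegulatorSelection:
    """Percentile-bootstrap confidence intervals for frequently selected
    covariates.

    ``n_bootstrap`` resamples of the samples (with replacement, size n) are
    refit with the full one-SE procedure (lambda re-selected inside each
    resample).  A covariate is kept iff it is frequently selected, its
    median coefficient lies inside the percentile CI, and the CI excludes 0.
    """
    cfg = cfg or LassoConfig()
    ss = np.random.SeedSequence([cfg.seed, 1])
    rng = np.random.default_rng(ss)
    n = design.n
    boot = np.empty((cfg.n_bootstrap, design.p))
    b = 0
    while b < cfg.n_bootstrap:
        idx = rng.integers(0, n, n)
        yb = design.y[idx]
        Xb = design.X[idx]
        if np.ptp(yb) == 0 or (np.ptp(Xb, axis=0) == 0).any():
            logger.info("degenerate bootstrap resample redrawn (rna=%s)", design.rna_id)
            continue
        coef, _ = _fit_one_se(Xb, yb, cfg, rng)
        boot[b] = coef
        b += 1
    tail = (1 - cfg.ci_level) / 2
    lo = np.quantile(boot, tail, axis=0)
    hi = np.quantile(boot, 1 - tail, axis=0)

    t = stability.copy()
    t.insert(0, "rna_id", design.rna_id)
    t["ci_lo"] = lo
    t["ci_hi"] = hi
    med = t["median_coefficient"].to_numpy()
    t["kept"] = (
        t["frequently_selected"].to_numpy()
        & (lo <= med)
        & (med <= hi)
        & ((lo > 0) | (hi < 0))
    )
    return RegulatorSelection(t, cfg.n_runs, cfg.freq_threshold)


def keep_negative_mirnas(sel: RegulatorSelection) -> InteractionTable:
    """Kept miRNA covariates with negative median coefficient become
    directed miRNA -> RNA interactions; other kinds never become edges."""
    k = sel.kept
    mir = k[(k["kind"] == "miRNA") & (k["median_coefficient"] < 0)]
    df = pd.DataFrame(
        {
            "regulator": mir["covariate"].astype(str),
            "target": mir["rna_id"].astype(str),
            "regulator_kind": "miRNA",
            "source": "lasso_selected",
        }
    )
    return InteractionTable(df.reset_index(drop=True))


def regulator_kind_summary(selections: list[RegulatorSelection]) -> pd.DataFrame:
    """Counts of kept regulators by kind across RNAs (summary bookkeeping)."""
    kept = pd.concat([s.kept for s in selections], ignore_index=True) if selections else pd.DataFrame(columns=["kind"])
    counts = kept.groupby("kind").size() if len(kept) else pd.Series(dtype=int)
    return pd.DataFrame({"kind": counts.index, "n_kept": counts.to_numpy()})


def ols_select(design: RegressionDesign, alpha: float = 0.05) -> InteractionTable:
    """OLS variant: keep miRNAs with negative coefficient and t-test
    p-value below ``alpha`` in a plain multiple regression."""
    n, p = design.n, design.p
    if n <= p + 1:
        raise ValueError("need n > #covariates + 1 for OLS")
    A = np.column_stack([np.ones(n), design.X])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        raise ValueError("rank-deficient design matrix")
    coef, _, _, _ = np.linalg.lstsq(A, design.y, rcond=None)
    resid = design.y - A @ coef
    df_resid = n - p - 1
    sigma2 = resid @ resid / df_resid
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    rows = []
    for j, (name, kind) in enumerate(
        zip(design.covariate_names, design.covariate_kinds), start=1
    ):
        if kind == "miRNA" and coef[j] < 0 and pvals[j] < alpha:
            rows.append((name, design.rna_id))
    df = pd.DataFrame(rows or [], columns=["regulator", "target"], dtype=str)
    df["regulator_kind"] = "miRNA"
    df["source"] = "ols_selected"
    return InteractionTable(df)


def select_regulators(
    design: RegressionDesign, cfg: LassoConfig | None = None
) -> RegulatorSelection:
    """Full step-2 procedure for one RNA: stability selection followed by
    the bootstrap CI filter."""
    cfg = cfg or LassoConfig()
    stab = stability_select(design, cfg)
    return bootstrap_ci_filter(design, stab, cfg)


def build_design(
    rna_id: str,
    rna_expr,
    candidate_mirnas: list[str],
    mirna_expr,
    cna_row: np.ndarray | None = None,
    dnam_row: np.ndarray | None = None,
    tf_ids: list[str] | None = None,
    tf_expr=None,
) -> RegressionDesign:
    """Assemble a RegressionDesign from expression matrices.

    ``rna_expr`` / ``mirna_expr`` / ``tf_expr`` are ExpressionMatrix
    objects sharing the same tumor samples; CNA and methylation rows are
    standardized here if not already.
    """
    y = np.asarray(rna_expr, dtype=float)
    names: list[str] = []
    kinds: list[str] = []
    cols: list[np.ndarray] = []
    for m in candidate_mirnas:
        cols.append(mirna_expr.row(m))
        names.append(m)
        kinds.append("miRNA")
    if cna_row is not None:
        cols.append(_standardize(np.asarray(cna_row, dtype=float)))
        names.append(f"{rna_id}::CNA")
        kinds.append("CNA")
    if dnam_row is not None:
        cols.append(_standardize(np.asarray(dnam_row, dtype=float)))
        names.append(f"{rna_id}::DNAm")
        kinds.append("DNAm")
    for tf in tf_ids or []:
        cols.append(tf_expr.row(tf))
        names.append(tf)
        kinds.append("TF")
    X = np.column_stack(cols) if cols else np.empty((y.shape[0], 0))
    return RegressionDesign(rna_id, y, X, names, kinds)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd
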