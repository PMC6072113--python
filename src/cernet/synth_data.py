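"""Synthetic multi-omics fixtures with planted regulatory and ceRNA
structure.

The generator emits post-preprocessing data by default: z-scored tumor-only
expression for miRNAs, RNAs, and TFs, a gene-level CNA matrix, a promoter
methylation beta matrix, putative interaction tables (planted edges plus
decoys), all-DE label tables, and a ground-truth record.  RNA expression is
a linear function of its planted regulators plus Gaussian noise; members of
a ceRNA group share ``k_true`` strongly repressive miRNAs and a common
latent factor (residual co-regulation), so planted pairs carry both a
miRNA-mediated and a direct co-expression component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, InteractionTable
from .evaluation import PerturbationTable
from .preprocess import DELabelTable

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "SyntheticData",
    "generate",
    "generate_perturbations",
    "scenario",
]


@dataclass
class SynthConfig:
    n_mirna: int = 30
    n_mrna: int = 80
    n_lncrna: int = 20
    n_tf: int = 10
    n_samples: int = 200
    effect_range: tuple[float, float] = (-0.8, -0.4)  # miRNA effects, negative
    noise_sd: float = 1.0
    k_true: int = 3
    n_cerna_groups: int = 0
    cerna_group_size: int = 2
    direct_effect: float = 0.5
    mirnas_per_rna: tuple[int, int] = (1, 3)
    decoy_factor: float = 3.0
    cna_effect_range: tuple[float, float] = (0.5, 1.0)
    dnam_effect_range: tuple[float, float] = (0.3, 0.8)
    tf_effect_range: tuple[float, float] = (0.3, 0.8)
    tf_per_mrna: tuple[int, int] = (0, 2)
    confounders: bool = True
    null_model: bool = False  # putative edges exist but carry zero effect
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_mrna", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.effect_range
        if not self.null_model and (lo >= 0 or hi >= 0):
            raise ValueError("miRNA effect range must be negative")
        if self.k_true > self.n_mirna:
            raise ValueError("k_true exceeds the miRNA count")
        if self.n_cerna_groups * self.cerna_group_size > self.n_mrna + self.n_lncrna:
            raise ValueError("ceRNA groups exceed the RNA count")


@dataclass
class SyntheticTruth:
    """Planted model parameters.

    ``mirna_effects[rna][mirna]`` holds the (negative) planted coefficient;
    ``assigned_mirnas`` additionally records zero-effect assignments under
    the null model so the putative table stays reconstructible.
    """

    mirna_effects: dict[str, dict[str, float]]
    assigned_mirnas: dict[str, set[str]]
    cna_effects: dict[str, float]
    dnam_effects: dict[str, float]
    tf_effects: dict[str, dict[str, float]]
    cerna_groups: list[list[str]]
    cerna_pairs: list[tuple[str, str]]
    noise_sd: float
    n_samples: int
    k_true: int
    seed: int

    def __post_init__(self) -> None:
        for rna, effs in self.mirna_effects.items():
            for m, c in effs.items():
                if c >= 0:
                    raise ValueError(f"planted miRNA effect must be negative "
                                     f"({m} -> {rna}: {c})")
        shared_min = {
            pair: len(
                set(self.mirna_effects.get(pair[0], {}))
                & set(self.mirna_effects.get(pair[1], {}))
            )
            for pair in self.cerna_pairs
        }
        bad = [p for p, k in shared_min.items() if k < self.k_true]
        if bad:
            raise ValueError(f"planted ceRNA pairs with < k_true shared miRNAs: {bad}")

    def planted_edges(self) -> set[tuple[str, str]]:
        return {
            (m, rna) for rna, effs in self.mirna_effects.items() for m in effs
        }

    def coregulated_pairs(self) -> set[tuple[str, str]]:
        """All unordered RNA pairs sharing >= 1 planted miRNA."""
        rnas = sorted(self.mirna_effects)
        out = set()
        for i, a in enumerate(rnas):
            for b in rnas[i + 1:]:
                if set(self.mirna_effects[a]) & set(self.mirna_effects[b]):
                    out.add((a, b))
        return out

    def coregulation_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.mirna_effects)
        g.add_edges_from(self.coregulated_pairs())
        return g


@dataclass
class SyntheticData:
    mirna_expr: ExpressionMatrix
    rna_expr: ExpressionMatrix  # mRNA + lncRNA, z-scored
    tf_expr: ExpressionMatrix
    cna: ExpressionMatrix
    dnam: ExpressionMatrix
    putative: InteractionTable
    tf_net: InteractionTable
    de_mirnas: DELabelTable
    de_rnas: DELabelTable
    truth: SyntheticTruth
    rna_kinds: dict[str, str] = field(default_factory=dict)

    @property
    def mrna_ids(self) -> list[str]:
        return [r for r, k in self.rna_kinds.items() if k == "mRNA"]

    @property
    def lncrna_ids(self) -> list[str]:
        return [r for r, k in self.rna_kinds.items() if k == "lncRNA"]


def _zscore_rows(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, ddof=0, keepdims=True)
    return (a - mu) / sd


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def generate(cfg: SynthConfig) -> SyntheticData:
    """Draw one synthetic dataset under the planted linear model."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    mirna_ids = [f"miR-{i:03d}" for i in range(cfg.n_mirna)]
    mrna_ids = [f"gene-{i:03d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"lnc-{i:03d}" for i in range(cfg.n_lncrna)]
    tf_ids = [f"TF-{i:02d}" for i in range(cfg.n_tf)]
    rna_ids = mrna_ids + lnc_ids
    rna_kinds = {r: ("mRNA" if r in set(mrna_ids) else "lncRNA") for r in rna_ids}

    M = _zscore_rows(rng.standard_normal((cfg.n_mirna, n)))
    TF = (
        _zscore_rows(rng.standard_normal((cfg.n_tf, n)))
        if cfg.n_tf
        else np.empty((0, n))
    )
    cna_raw = rng.standard_normal((cfg.n_mrna, n))
    dnam_beta = 1.0 / (1.0 + np.exp(-rng.standard_normal((cfg.n_mrna, n))))
    mi_index = {m: i for i, m in enumerate(mirna_ids)}
    tf_index = {t: i for i, t in enumerate(tf_ids)}

    # --- plant miRNA regulators -------------------------------------------
    mirna_effects: dict[str, dict[str, float]] = {r: {} for r in rna_ids}
    assigned: dict[str, set[str]] = {r: set() for r in rna_ids}
    groups: list[list[str]] = []
    latent: dict[str, np.ndarray] = {}
    direct: dict[str, float] = {}

    perm = list(rng.permutation(cfg.n_mirna))
    grouped_rnas: list[str] = []
    for g in range(cfg.n_cerna_groups):
        members = rna_ids[
            g * cfg.cerna_group_size: (g + 1) * cfg.cerna_group_size
        ]
        grouped_rnas.extend(members)
        if len(perm) >= cfg.k_true:
            shared = [mirna_ids[perm.pop()] for _ in range(cfg.k_true)]
        else:
            shared = [
                mirna_ids[i]
                for i in rng.choice(cfg.n_mirna, cfg.k_true, replace=False)
            ]
        L = rng.standard_normal(n)
        for r in members:
            for m in shared:
                mirna_effects[r][m] = float(rng.uniform(*cfg.effect_range))
            assigned[r] |= set(shared)
            latent[r] = L
            direct[r] = cfg.direct_effect
        groups.append(list(members))

    lo, hi = cfg.mirnas_per_rna
    for r in rna_ids:
        if r in set(grouped_rnas):
            continue
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(cfg.n_mirna, size=min(k, cfg.n_mirna), replace=False)
        for i in chosen:
            m = mirna_ids[i]
            assigned[r].add(m)
            if not cfg.null_model:
                mirna_effects[r][m] = float(rng.uniform(*cfg.effect_range))

    # --- confounders for mRNAs --------------------------------------------
    cna_effects: dict[str, float] = {}
    dnam_effects: dict[str, float] = {}
    tf_effects: dict[str, dict[str, float]] = {}
    tf_assigned: dict[str, set[str]] = {r: set() for r in mrna_ids}
    if cfg.confounders and not cfg.null_model:
        for r in mrna_ids:
            cna_effects[r] = float(rng.uniform(*cfg.cna_effect_range))
            dnam_effects[r] = -float(rng.uniform(*cfg.dnam_effect_range))
            n_tf = int(rng.integers(cfg.tf_per_mrna[0], cfg.tf_per_mrna[1] + 1))
            if n_tf and cfg.n_tf:
                chosen = rng.choice(cfg.n_tf, size=min(n_tf, cfg.n_tf), replace=False)
                effs = {}
                for i in chosen:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    effs[tf_ids[i]] = sign * float(rng.uniform(*cfg.tf_effect_range))
                tf_effects[r] = effs
                tf_assigned[r] |= set(effs)

    # --- build expression --------------------------------------------------
    rna_rows = np.empty((len(rna_ids), n))
    for i, r in enumerate(rna_ids):
        y = cfg.noise_sd * rng.standard_normal(n)
        for m, c in mirna_effects[r].items():
            y = y + c * M[mi_index[m]]
        if r in latent:
            y = y + direct[r] * latent[r]
        if r in cna_effects:
            y = y + cna_effects[r] * _standardize(cna_raw[mrna_ids.index(r)])
        if r in dnam_effects:
            y = y + dnam_effects[r] * _standardize(dnam_beta[mrna_ids.index(r)])
        for t, c in tf_effects.get(r, {}).items():
            y = y + c * TF[tf_index[t]]
        rna_rows[i] = y
    rna_rows = _zscore_rows(rna_rows)

    # --- interaction tables: planted/assigned edges plus decoys -----------
    put_rows = []
    for r in rna_ids:
        for m in sorted(assigned[r]):
            put_rows.append((m, r, "planted"))
        n_decoy = int(round(cfg.decoy_factor * len(assigned[r])))
        others = [m for m in mirna_ids if m not in assigned[r]]
        if n_decoy and others:
            chosen = rng.choice(len(others), size=min(n_decoy, len(others)),
                                replace=False)
            for i in sorted(chosen):
                put_rows.append((others[i], r, "decoy"))
    putative = InteractionTable(
        pd.DataFrame(put_rows, columns=["regulator", "target", "source"]).assign(
            regulator_kind="miRNA"
        )[["regulator", "target", "regulator_kind", "source"]]
    )

    tf_rows = []
    for r in mrna_ids:
        for t in sorted(tf_assigned[r]):
            tf_rows.append((t, r, "planted"))
        others = [t for t in tf_ids if t not in tf_assigned[r]]
        n_decoy = min(len(tf_assigned[r]), len(others))
        if n_decoy:
            chosen = rng.choice(len(others), size=n_decoy, replace=False)
            for i in sorted(chosen):
                tf_rows.append((others[i], r, "decoy"))
    tf_net = InteractionTable(
        pd.DataFrame(tf_rows or [], columns=["regulator", "target", "source"]).assign(
            regulator_kind="TF"
        )[["regulator", "target", "regulator_kind", "source"]]
    )

    samples = [f"S{j:03d}" for j in range(n)]
    tumor = {s: "tumor" for s in samples}

    def mat(rows: np.ndarray, ids: list[str], kind: str, unit: str) -> ExpressionMatrix:
        return ExpressionMatrix(
            pd.DataFrame(rows, index=ids, columns=samples), kind, unit, dict(tumor)
        )

    cerna_pairs = [
        (a, b) if a < b else (b, a)
        for g in groups
        for idx, a in enumerate(g)
        for b in g[idx + 1:]
    ]
    truth = SyntheticTruth(
        mirna_effects={r: e for r, e in mirna_effects.items() if e},
        assigned_mirnas=assigned,
        cna_effects=cna_effects,
        dnam_effects=dnam_effects,
        tf_effects=tf_effects,
        cerna_groups=groups,
        cerna_pairs=sorted(cerna_pairs),
        noise_sd=cfg.noise_sd,
        n_samples=n,
        k_true=cfg.k_true,
        seed=cfg.seed,
    )
    return SyntheticData(
        mirna_expr=mat(M, mirna_ids, "miRNA", "zscore"),
        rna_expr=mat(rna_rows, rna_ids, "mixed", "zscore"),
        tf_expr=mat(TF, tf_ids, "mRNA", "zscore") if cfg.n_tf else mat(
            np.empty((0, n)), [], "mRNA", "zscore"
        ),
        cna=mat(cna_raw, mrna_ids, "mRNA", "cna"),
        dnam=mat(dnam_beta, mrna_ids, "mRNA", "beta"),
        putative=putative,
        tf_net=tf_net,
        de_mirnas=DELabelTable.all_de(mirna_ids),
        de_rnas=DELabelTable.all_de(rna_ids),
        truth=truth,
        rna_kinds=rna_kinds,
    )


def generate_perturbations(
    truth: SyntheticTruth,
    knockdown_fraction: float = 0.5,
    kd_effect: float = 0.3,
    fc_noise_sd: float = 0.0,
    timepoint: str = "96h",
    seed: int = 0,
) -> PerturbationTable:
    """Knockdown experiments consistent with the planted model.

    Downstream genes sharing >= 1 planted miRNA with the knocked-down gene
    (partners under miRNA reallocation) receive fold change
    exp(-kd_effect * shared repression strength) < 1; non-partners receive
    fold change 1, both times multiplicative log-normal noise.
    """
    rng = np.random.default_rng(seed)
    rnas = sorted(truth.mirna_effects)
    n_kd = max(1, int(round(knockdown_fraction * len(rnas))))
    kd = sorted(rng.choice(len(rnas), size=n_kd, replace=False))
    upstreams = [rnas[i] for i in kd]
    rows = []
    for u in upstreams:
        mir_u = set(truth.mirna_effects[u])
        for d in rnas:
            if d == u:
                continue
            shared = mir_u & set(truth.mirna_effects[d])
            if shared:
                strength = sum(abs(truth.mirna_effects[d][m]) for m in shared)
                fc = float(np.exp(-kd_effect * strength))
            else:
                fc = 1.0
            if fc_noise_sd > 0:
                fc *= float(np.exp(fc_noise_sd * rng.standard_normal()))
            rows.append((u, d, fc, timepoint))
    return PerturbationTable(
        pd.DataFrame(rows, columns=["upstream", "downstream", "fold_change",
                                    "timepoint"])
    )


_SCENARIOS = {
    "recovery": dict(
        n_mirna=30, n_mrna=80, n_lncrna=20, n_tf=10, n_samples=200,
        effect_range=(-0.8, -0.4), noise_sd=1.0, decoy_factor=3.0,
        mirnas_per_rna=(1, 3), confounders=True,
    ),
    "null": dict(
        n_mirna=30, n_mrna=80, n_lncrna=20, n_tf=0, n_samples=200,
        noise_sd=1.0, decoy_factor=3.0, mirnas_per_rna=(1, 3),
        confounders=False, null_model=True,
    ),
    "cerna": dict(
        n_mirna=15, n_mrna=20, n_lncrna=10, n_tf=0, n_samples=200,
        effect_range=(-0.8, -0.6), noise_sd=0.5, k_true=3,
        n_cerna_groups=8, cerna_group_size=2, direct_effect=0.5,
        mirnas_per_rna=(1, 2), decoy_factor=2.0, confounders=False,
    ),
    "perturb": dict(
        n_mirna=15, n_mrna=20, n_lncrna=10, n_tf=0, n_samples=200,
        effect_range=(-0.8, -0.6), noise_sd=0.5, k_true=3,
        n_cerna_groups=8, cerna_group_size=2, direct_effect=0.5,
        mirnas_per_rna=(1, 2), decoy_factor=2.0, confounders=False,
    ),
}


def scenario(name: str, seed: int = 0, **overrides) -> SyntheticData:
    """Preset generator configurations: recovery, null, cerna, perturb."""
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    params = dict(_SCENARIOS[name])
    params.update(overrides)
    return generate(SynthConfig(seed=seed, **params))
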