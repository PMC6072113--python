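"""Knockdown-based network evaluation: Ratio Fold Change and accuracy.

For a downstream gene, RFC is the mean expression fold change after
knockdown of its ceRNA partners divided by the mean fold change after
knockdown of upstream genes that are not its partners; network accuracy is
the percentage of evaluable downstream genes with RFC < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationTable",
    "ratio_fold_change",
    "network_accuracy",
    "accuracy_report",
]


@dataclass
class PerturbationTable:
    """Knockdown fold changes: columns upstream, downstream, fold_change,
    timepoint.  Fold changes are linear scale and strictly positive."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"upstream", "downstream", "fold_change", "timepoint"}
        missing = needed - set(self.table.columns)
        if missing:
            raise ValueError(f"perturbation table missing columns: {sorted(missing)}")
        if (self.table["fold_change"] <= 0).any():
            raise ValueError("fold changes must be > 0")
        if self.table.duplicated(["upstream", "downstream", "timepoint"]).any():
            raise ValueError("duplicate (upstream, downstream, timepoint) rows")

    def at_timepoint(self, timepoint: str) -> pd.DataFrame:
        return self.table[self.table["timepoint"] == timepoint]

    @property
    def timepoints(self) -> list[str]:
        return sorted(self.table["timepoint"].unique())


def _partners(network, node: str) -> set[str]:
    if isinstance(network, nx.Graph):
        return set(network.neighbors(node)) if node in network else set()
    return set(network.get(node, set()))


def ratio_fold_change(
    downstream: str,
    network,
    perturb: PerturbationTable,
    timepoint: str,
    agg: str = "mean",
) -> float | None:
    """RFC for one downstream gene, or None when it has no partner or no
    non-partner among the knocked-down upstream genes at the timepoint."""
    sub = perturb.at_timepoint(timepoint)
    sub = sub[(sub["downstream"] == downstream) & (sub["upstream"] != downstream)]
    partners = _partners(network, downstream)
    fc_partner = sub.loc[sub["upstream"].isin(partners), "fold_change"].to_numpy()
    fc_other = sub.loc[~sub["upstream"].isin(partners), "fold_change"].to_numpy()
    if fc_partner.size == 0 or fc_other.size == 0:
        logger.info("downstream %r not evaluable at %r", downstream, timepoint)
        return None
    if agg == "mean":
        return float(fc_partner.mean() / fc_other.mean())
    if agg == "geometric":
        return float(
            np.exp(np.log(fc_partner).mean() - np.log(fc_other).mean())
        )
    raise ValueError(f"unknown aggregation {agg!r}")


def network_accuracy(
    network,
    perturb: PerturbationTable,
    timepoint: str,
    agg: str = "mean",
) -> float:
    """Percentage of evaluable downstream genes with RFC < 1."""
    sub = perturb.at_timepoint(timepoint)
    downstreams = sorted(sub["downstream"].unique())
    rfcs = []
    for d in downstreams:
        rfc = ratio_fold_change(d, network, perturb, timepoint, agg)
        if rfc is not None:
            rfcs.append(rfc)
    if not rfcs:
        raise ValueError(f"no evaluable downstream genes at timepoint {timepoint!r}")
    return 100.0 * sum(1 for r in rfcs if r < 1) / len(rfcs)


def accuracy_report(
    network, perturb: PerturbationTable, agg: str = "mean"
) -> pd.DataFrame:
    """Per-timepoint accuracy table."""
    rows = []
    for tp in perturb.timepoints:
        rows.append(
            {"timepoint": tp, "accuracy": network_accuracy(network, perturb, tp, agg)}
        )
    return pd.DataFrame(rows, columns=["timepoint", "accuracy"])
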