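"""Step 1: assemble the putative DE-miRNA -> DE-RNA interaction network.

Interaction tables arrive pre-aggregated (union across sources); this module
restricts them to differentially expressed regulators and targets.  A small
seed-complementarity scanner is included purely to fabricate fixture
interaction tables from sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import InteractionTable
from .preprocess import DELabelTable

__all__ = ["PutativeNetwork", "restrict_to_de", "seed_match_scan"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SITE_TYPES = ("6mer", "7mer-m8", "7mer-A1", "8mer")


@dataclass
class PutativeNetwork:
    """miRNA -> RNA interactions among DE features only."""

    interactions: InteractionTable
    de_mirna_ids: set[str]
    de_rna_ids: set[str]

    def __post_init__(self) -> None:
        t = self.interactions.table
        if not set(t["regulator"]) <= self.de_mirna_ids:
            raise ValueError("putative network contains non-DE miRNA regulators")
        if not set(t["target"]) <= self.de_rna_ids:
            raise ValueError("putative network contains non-DE targets")

    def __len__(self) -> int:
        return len(self.interactions)

    def candidates_of(self, target: str) -> set[str]:
        return self.interactions.regulators_of(target)

    def targets_to_regulators(self) -> dict[str, set[str]]:
        return self.interactions.targets_to_regulators()


def restrict_to_de(
    interactions: InteractionTable,
    de_mirnas: DELabelTable,
    de_rnas: DELabelTable,
) -> PutativeNetwork:
    """Keep only interactions whose miRNA and target are both DE."""
    if len(interactions) == 0:
        raise ValueError("empty interaction table")
    mirna_ids = de_mirnas.de_ids
    rna_ids = de_rnas.de_ids
    t = interactions.table
    kept = t[
        t["regulator"].isin(mirna_ids)
        & t["target"].isin(rna_ids)
        & (t["regulator_kind"] == "miRNA")
    ]
    if kept.empty:
        raise ValueError(
            "no interactions between DE miRNAs and DE RNAs; review DE thresholds"
        )
    return PutativeNetwork(
        InteractionTable(kept.reset_index(drop=True)), mirna_ids, rna_ids
    )


def _norm(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def seed_match_scan(
    mirna_seqs: dict[str, str],
    utr_seqs: dict[str, str],
    site_types: tuple[str, ...] = SITE_TYPES,
    source_tag: str = "seed_scan",
) -> InteractionTable:
    """Canonical seed-site scan (fixture generator, not a target predictor).

    A (miRNA, RNA) pair is reported when the reverse complement of the
    miRNA seed occurs in the RNA's 3'UTR: positions 2-7 for 6mer, 2-8 for
    7mer-m8; the A1-type sites additionally require an A opposite miRNA
    position 1, i.e. immediately 3' of the seed match on the UTR.
    """
    unknown = set(site_types) - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site types: {sorted(unknown)}")
    rows = []
    for mid, mseq in mirna_seqs.items():
        m = _norm(mseq, f"miRNA {mid}")
        if len(m) < 8:
            raise ValueError(f"miRNA {mid} shorter than 8 nt")
        seed6 = m[1:7]
        seed7 = m[1:8]
        for rid, useq in utr_seqs.items():
            u = _norm(useq, f"UTR {rid}")
            hit = False
            if "6mer" in site_types and _revcomp(seed6) in u:
                hit = True
            if not hit and "7mer-m8" in site_types and _revcomp(seed7) in u:
                hit = True
            if not hit and "7mer-A1" in site_types:
                if _revcomp(seed6) + "A" in u:
                    hit = True
            if not hit and "8mer" in site_types:
                if _revcomp(seed7) + "A" in u:
                    hit = True
            if hit:
                rows.append((mid, rid))
    df = pd.DataFrame(
        rows or [], columns=["regulator", "target"], dtype=str
    )
    df["regulator_kind"] = "miRNA"
    df["source"] = source_tag
    return InteractionTable(df)
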