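"""Intersection of differentially regulated transcripts and proteins into a
shared signature, matched on canonicalized gene symbols and required to agree
in direction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_tables import canonicalize

logger = logging.getLogger(__name__)

_COLUMNS = ["gene_symbol", "protein_fc", "protein_p", "transcript_fc", "transcript_p"]


@dataclass
class SharedSignature:
    """Genes significant and concordant on both sides, ordered by protein
    fold change descending (ties broken lexicographically)."""

    shared_up: pd.DataFrame
    shared_down: pd.DataFrame
    discordant: pd.DataFrame | None = None
    unmatched_protein_symbols: int = 0
    unmatched_transcript_symbols: int = 0

    @property
    def up_genes(self) -> set[str]:
        return set(self.shared_up["gene_symbol"])

    @property
    def down_genes(self) -> set[str]:
        return set(self.shared_down["gene_symbol"])


def _order(df: pd.DataFrame, ascending: bool = False) -> pd.DataFrame:
    return df.sort_values(
        ["protein_fc", "gene_symbol"], ascending=[ascending, True]
    ).reset_index(drop=True)


def intersect_signatures(
    protein_de: pd.DataFrame,
    transcripts: pd.DataFrame,
    alias_map: Mapping[str, str] | None = None,
    p_cut: float = 0.05,
    transcript_fc_cut: float | None = None,
    permissive: bool = False,
) -> SharedSignature:
    """Intersect significant proteins and transcripts by gene symbol.

    ``protein_de`` needs columns gene_symbol, fold_change, p_value (rows
    failing the inclusion filter should already be excluded or carry NaN p).
    A gene is shared-up when FC > 1 and p <= p_cut on both sides; shared-down
    analogously.  ``permissive`` additionally reports direction-discordant
    matches for audit.
    """
    prot = protein_de[["gene_symbol", "fold_change", "p_value"]].dropna().copy()
    prot["gene_symbol"] = [canonicalize(s, alias_map) for s in prot["gene_symbol"]]
    # one record per gene: keep the most significant protein evidence
    prot = prot.sort_values(["p_value", "gene_symbol"]).drop_duplicates("gene_symbol")

    tr = transcripts[["gene_symbol", "fold_change", "p_value", "direction"]].copy()
    tr["gene_symbol"] = [canonicalize(s, alias_map) for s in tr["gene_symbol"]]
    tr = tr.sort_values(["p_value", "gene_symbol"]).drop_duplicates("gene_symbol")

    merged = prot.merge(tr, on="gene_symbol", suffixes=("_protein", "_transcript"))
    n_unmatched_prot = len(prot) - len(merged)
    n_unmatched_tr = len(tr) - len(merged)
    if n_unmatched_prot or n_unmatched_tr:
        logger.info(
            "unmatched symbols: %d protein-side, %d transcript-side",
            n_unmatched_prot,
            n_unmatched_tr,
        )

    prot_sig = merged["p_value_protein"] <= p_cut
    tr_sig = merged["p_value_transcript"] <= p_cut
    if transcript_fc_cut is not None:
        tr_fold_ok = (merged["fold_change_transcript"] >= transcript_fc_cut) | (
            merged["fold_change_transcript"] <= 1.0 / transcript_fc_cut
        )
        tr_sig &= tr_fold_ok
    sig = merged[prot_sig & tr_sig].copy()

    prot_up = sig["fold_change_protein"] > 1
    prot_down = sig["fold_change_protein"] < 1
    tr_up = sig["direction"] == "up"
    tr_down = sig["direction"] == "down"

    def take(mask: pd.Series) -> pd.DataFrame:
        sub = sig[mask]
        return pd.DataFrame(
            {
                "gene_symbol": sub["gene_symbol"],
                "protein_fc": sub["fold_change_protein"],
                "protein_p": sub["p_value_protein"],
                "transcript_fc": sub["fold_change_transcript"],
                "transcript_p": sub["p_value_transcript"],
            }
        )

    up = _order(take(prot_up & tr_up))
    down = _order(take(prot_down & tr_down), ascending=True)
    discordant = None
    if permissive:
        discordant = _order(take((prot_up & tr_down) | (prot_down & tr_up)))
    return SharedSignature(
        shared_up=up,
        shared_down=down,
        discordant=discordant,
        unmatched_protein_symbols=n_unmatched_prot,
        unmatched_transcript_symbols=n_unmatched_tr,
    )
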