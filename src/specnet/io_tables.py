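"""Readers, writers and validation for the tabular formats used by the pipeline.

All tables travel as TSV (UTF-8).  Gene symbols are uppercased at ingest so
that matching across tables is case-insensitive; an optional alias table
(symbol -> canonical symbol) can be applied before any cross-table match.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Average (isotope-abundance weighted) residue masses in Da, ExPASy-style.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
MEAN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)

ECM_CATEGORIES = frozenset({"collagen", "proteoglycan", "glycoprotein", "laminin", "other"})
GO_NAMESPACES = frozenset({"BP", "MF", "CC"})

UNIQUE_PEPTIDE_SUFFIX = ".unique_peptides"


class TableValidationError(ValueError):
    """A table violated one of its documented invariants."""


# ---------------------------------------------------------------------------
# SpectralCountTable


@dataclass
class SpectralCountTable:
    """Integer assigned-spectra matrix (proteins x samples) with group labels.

    ``counts`` holds raw assigned spectra.  ``unique_peptides`` (same shape)
    holds the peptide evidence used by the inclusion filter; when absent it
    defaults to the counts themselves (every spectrum treated as potential
    peptide evidence).
    """

    counts: pd.DataFrame
    groups: Mapping[str, str]
    unique_peptides: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.counts.index.name = "accession"
        if self.unique_peptides is not None:
            self.unique_peptides.index.name = "accession"
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise TableValidationError(f"duplicate protein accession: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise TableValidationError(f"duplicate sample id: {dup!r}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            bad = np.argwhere(arr != np.floor(arr))
            if bad.size:
                i, j = bad[0]
                raise TableValidationError(
                    f"non-integer count at protein {c.index[i]!r}, sample {c.columns[j]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise TableValidationError(
                f"negative count at protein {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        missing = [s for s in c.columns if s not in self.groups]
        if missing:
            raise TableValidationError(f"samples without a group label: {missing}")
        if self.unique_peptides is not None:
            up = self.unique_peptides
            if list(up.index) != list(c.index) or list(up.columns) != list(c.columns):
                raise TableValidationError("unique_peptides shape/labels differ from counts")
            if (up.to_numpy() < 0).any():
                raise TableValidationError("negative unique-peptide count")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def peptide_evidence(self) -> pd.DataFrame:
        """Unique-peptide matrix, falling back to counts when not provided."""
        return self.unique_peptides if self.unique_peptides is not None else self.counts

    def group_samples(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.sample_ids:
            out.setdefault(self.groups[s], []).append(s)
        return out

    def require_differential_design(self) -> None:
        sizes = {g: len(v) for g, v in self.group_samples().items()}
        ok = [g for g, n in sizes.items() if n >= 2]
        if len(ok) < 2:
            raise TableValidationError(
                f"differential analysis needs >=2 groups with >=2 samples each, got {sizes}"
            )


def read_count_table(path: str | Path, group_map: Mapping[str, str]) -> SpectralCountTable:
    """Read a count TSV (first column accession, one column per sample).

    Columns named ``<sample>.unique_peptides`` are split into the parallel
    peptide-evidence matrix.  Missing cells read as 0 (an unidentified
    protein has zero assigned spectra); the number of filled cells is logged.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise TableValidationError(f"duplicate protein accession: {dup!r} in {path}")
    pep_cols = [c for c in df.columns if c.endswith(UNIQUE_PEPTIDE_SUFFIX)]
    count_cols = [c for c in df.columns if not c.endswith(UNIQUE_PEPTIDE_SUFFIX)]

    def _to_int(frame: pd.DataFrame, what: str) -> pd.DataFrame:
        n_missing = int(frame.isna().to_numpy().sum())
        if n_missing:
            logger.warning("%s: %d missing %s cells read as 0", path, n_missing, what)
            frame = frame.fillna("0")
        out = pd.DataFrame(index=frame.index)
        for col in frame.columns:
            vals = pd.to_numeric(frame[col], errors="coerce")
            if vals.isna().any():
                row = frame.index[vals.isna()][0]
                raise TableValidationError(
                    f"non-numeric {what} at protein {row!r}, sample {col!r}"
                )
            if (vals != np.floor(vals)).any():
                row = frame.index[vals != np.floor(vals)][0]
                raise TableValidationError(
                    f"non-integer {what} at protein {row!r}, sample {col!r}"
                )
            if (vals < 0).any():
                row = frame.index[vals < 0][0]
                raise TableValidationError(
                    f"negative {what} at protein {row!r}, sample {col!r}"
                )
            out[col] = vals.astype(np.int64)
        return out

    counts = _to_int(df[count_cols], "count")
    unknown = [s for s in counts.columns if s not in group_map]
    if unknown:
        raise TableValidationError(f"samples absent from group_map: {unknown}")
    unique = None
    if pep_cols:
        pep = _to_int(df[pep_cols], "unique-peptide count")
        pep.columns = [c[: -len(UNIQUE_PEPTIDE_SUFFIX)] for c in pep.columns]
        unique = pep.reindex(columns=counts.columns).fillna(0).astype(np.int64)
    groups = {s: group_map[s] for s in counts.columns}
    return SpectralCountTable(counts=counts, groups=groups, unique_peptides=unique)


def write_count_table(table: SpectralCountTable, path: str | Path) -> None:
    out = table.counts.copy()
    if table.unique_peptides is not None:
        for s in table.sample_ids:
            out[s + UNIQUE_PEPTIDE_SUFFIX] = table.unique_peptides[s]
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Protein metadata


def mass_from_sequence(sequence: str, tolerate_x: bool = False) -> float:
    """Average molecular mass of a protein sequence, in kDa.

    Sum of average residue masses plus one water.  ``X`` is rejected unless
    ``tolerate_x`` is set, in which case it contributes the mean residue mass.
    """
    if not sequence:
        raise TableValidationError("empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(sequence.upper()):
        if aa in AVERAGE_RESIDUE_MASS:
            total += AVERAGE_RESIDUE_MASS[aa]
        elif aa == "X" and tolerate_x:
            total += MEAN_RESIDUE_MASS
        else:
            raise TableValidationError(
                f"non-standard amino-acid letter {aa!r} at position {pos}"
            )
    return total / 1000.0


def read_protein_meta(path: str | Path, fasta: str | Path | None = None,
                      tolerate_x: bool = True) -> pd.DataFrame:
    """Protein metadata TSV -> DataFrame indexed by accession.

    Columns: gene_symbol (uppercased), description, mass_kda, ecm_category.
    A FASTA file may supply masses for accessions whose mass_kda is missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    required = {"accession", "gene_symbol"}
    if not required.issubset(df.columns):
        raise TableValidationError(f"protein metadata missing columns {required - set(df.columns)}")
    if df["accession"].duplicated().any():
        dup = df["accession"][df["accession"].duplicated()].iloc[0]
        raise TableValidationError(f"duplicate accession in metadata: {dup!r}")
    df = df.set_index("accession")
    df["gene_symbol"] = df["gene_symbol"].astype(str).str.upper()
    if "description" not in df.columns:
        df["description"] = ""
    if "mass_kda" not in df.columns:
        df["mass_kda"] = np.nan
    if "ecm_category" in df.columns:
        bad = set(df["ecm_category"].dropna()) - ECM_CATEGORIES
        if bad:
            raise TableValidationError(f"unknown ecm_category values: {sorted(bad)}")
    else:
        df["ecm_category"] = "other"
    if fasta is not None:
        from Bio import SeqIO

        for rec in SeqIO.parse(str(fasta), "fasta"):
            acc = rec.id.split("|")[1] if "|" in rec.id else rec.id
            if acc in df.index and not np.isfinite(df.at[acc, "mass_kda"]):
                df.at[acc, "mass_kda"] = mass_from_sequence(str(rec.seq), tolerate_x=tolerate_x)
    if (df["mass_kda"].dropna() <= 0).any():
        bad = df.index[df["mass_kda"] <= 0][0]
        raise TableValidationError(f"non-positive mass_kda for accession {bad!r}")
    return df


def write_protein_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.reset_index()
    cols = ["accession", "gene_symbol", "description", "mass_kda", "ecm_category"]
    out[[c for c in cols if c in out.columns]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Edge table (String-style association scores)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """3-column TSV (node_a, node_b, score) -> validated edge DataFrame.

    Scores on a 0-1000 scale (String raw) are auto-detected (max > 1) and
    normalized to [0, 1].  Self-edges are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise TableValidationError(f"edge table {path} needs 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :3]
    df.columns = ["node_a", "node_b", "score"]
    df["node_a"] = df["node_a"].astype(str).str.upper()
    df["node_b"] = df["node_b"].astype(str).str.upper()
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    if df["score"].isna().any():
        row = int(df.index[df["score"].isna()][0])
        raise TableValidationError(f"non-numeric score at row {row}")
    if (df["score"] < 0).any():
        row = int(df.index[df["score"] < 0][0])
        raise TableValidationError(f"negative score at row {row}")
    if df["score"].max() > 1:
        if df["score"].max() > 1000:
            row = int(df.index[df["score"] > 1000][0])
            raise TableValidationError(f"score out of range at row {row}")
        logger.info("%s: scores on 0-1000 scale, normalizing to [0,1]", path)
        df["score"] = df["score"] / 1000.0
    self_loops = df["node_a"] == df["node_b"]
    if self_loops.any():
        logger.warning("%s: dropped %d self-edge(s)", path, int(self_loops.sum()))
        df = df[~self_loops]
    return df.reset_index(drop=True)


def write_edge_table(edges: pd.DataFrame, path: str | Path) -> None:
    edges[["node_a", "node_b", "score"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotations (4-column TSV or GMT)


def read_annotations(path: str | Path, default_namespace: str = "BP") -> pd.DataFrame:
    """Term annotations -> DataFrame (term_id, term_name, namespace, gene_symbol).

    Accepts the 4-column TSV dialect or GMT (detected by ``.gmt`` suffix).
    Duplicate (term_id, gene_symbol) pairs collapse to one record with a
    warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                term_id, term_name = parts[0], parts[1]
                for g in parts[2:]:
                    if g:
                        rows.append((term_id, term_name, default_namespace, g.upper()))
        df = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace", "gene_symbol"])
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"term_id", "term_name", "namespace", "gene_symbol"}
        if not need.issubset(df.columns):
            raise TableValidationError(f"annotation table missing columns {need - set(df.columns)}")
        df = df[["term_id", "term_name", "namespace", "gene_symbol"]]
        df["gene_symbol"] = df["gene_symbol"].str.upper()
    bad_ns = set(df["namespace"]) - GO_NAMESPACES
    if bad_ns:
        raise TableValidationError(f"unknown namespace values: {sorted(bad_ns)}")
    dup = df.duplicated(subset=["term_id", "gene_symbol"])
    if dup.any():
        logger.warning("%s: %d duplicate (term, gene) pairs collapsed", path, int(dup.sum()))
        df = df[~dup]
    if df.empty:
        raise TableValidationError(f"annotation table {path} has no records")
    return df.reset_index(drop=True)


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann[["term_id", "term_name", "namespace", "gene_symbol"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcript differential-expression table


def read_transcript_table(path: str | Path) -> pd.DataFrame:
    """Transcript DE TSV -> DataFrame (gene_symbol, fold_change, p_value, direction)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str})
    need = {"gene_symbol", "fold_change", "p_value", "direction"}
    if not need.issubset(df.columns):
        raise TableValidationError(f"transcript table missing columns {need - set(df.columns)}")
    df = df[["gene_symbol", "fold_change", "p_value", "direction"]].copy()
    df["gene_symbol"] = df["gene_symbol"].str.upper()
    if (df["fold_change"] <= 0).any():
        row = df["gene_symbol"][df["fold_change"] <= 0].iloc[0]
        raise TableValidationError(f"non-positive fold change for {row!r}")
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        row = df["gene_symbol"][(df["p_value"] < 0) | (df["p_value"] > 1)].iloc[0]
        raise TableValidationError(f"p_value outside [0,1] for {row!r}")
    bad_dir = set(df["direction"]) - {"up", "down"}
    if bad_dir:
        raise TableValidationError(f"unknown direction values: {sorted(bad_dir)}")
    inconsistent = ((df["direction"] == "up") & (df["fold_change"] < 1)) | (
        (df["direction"] == "down") & (df["fold_change"] > 1)
    )
    if inconsistent.any():
        row = df["gene_symbol"][inconsistent].iloc[0]
        raise TableValidationError(f"direction inconsistent with fold change for {row!r}")
    return df.reset_index(drop=True)


def write_transcript_table(tr: pd.DataFrame, path: str | Path) -> None:
    tr[["gene_symbol", "fold_change", "p_value", "direction"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alias map


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (symbol, canonical) -> uppercase alias mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableValidationError(f"alias table {path} needs 2 columns")
    return {
        str(a).upper(): str(b).upper()
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def canonicalize(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    s = symbol.upper()
    if alias_map:
        s = alias_map.get(s, s)
    return s
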