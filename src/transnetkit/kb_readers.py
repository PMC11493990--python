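"""Readers for the six reference knowledge-base table dialects.

Each loader parses a single-header TSV, applies the documented filters and
returns a pandas DataFrame whose ``.attrs["report"]`` holds a
:class:`LoaderReport` with row-conservation counts (``input_rows ==
retained + rejected + dropped_unresolved``).  Column semantics mirror the
public databases the dialects are modelled on (ChIP-Atlas target-gene
tables, miRTarBase, STRING links, KEGG reaction/EC/gene mappings, BRENDA
activator/inhibitor tables, TCDB transporter–substrate tables); downloading
and converting the real databases is out of scope.

Filters follow the tool's stated defaults: STRING-style combined scores are
kept when >= 400 (the database's "medium confidence" default), transporter
substrates are kept when linked to fewer than 50 other compounds and the
transporter is membrane-localized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

__all__ = [
    "KnowledgeBase",
    "LoaderReport",
    "KBFormatError",
    "load_tf_targets",
    "load_mirna_targets",
    "load_ppi",
    "load_metabolic_reactions",
    "load_allosteric",
    "load_transporters",
    "load_knowledge_base",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class KBFormatError(ValueError):
    """Raised when a knowledge-base file violates its documented dialect."""


@dataclass
class LoaderReport:
    input_rows: int = 0
    retained: int = 0
    rejected: int = 0
    dropped_unresolved: int = 0
    warnings: list = field(default_factory=list)

    def conserves_rows(self) -> bool:
        return self.input_rows == self.retained + self.rejected + self.dropped_unresolved


@dataclass(frozen=True)
class KnowledgeBase:
    """Immutable collection of the six filtered interaction tables."""

    tf_targets: pd.DataFrame
    mirna_targets: pd.DataFrame
    ppi_links: pd.DataFrame
    reactions: pd.DataFrame
    allosteric: pd.DataFrame
    transporters: pd.DataFrame


def _read_tsv(path: PathLike, required: list[str], kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KBFormatError(
            f"{kind} table {path} missing required column(s): {', '.join(missing)}"
        )
    return df


def _attach(df: pd.DataFrame, report: LoaderReport) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    df.attrs["report"] = report
    return df


def load_tf_targets(
    path: PathLike,
    tss_window_kb: float = 1,
    score_threshold: float = 0,
) -> pd.DataFrame:
    """Load ChIP-experiment target-gene rows.

    Rows are target-gene calls per ChIP experiment with a peak-caller
    binding score; only rows windowed at ``tss_window_kb`` from the TSS and
    scoring at least ``score_threshold`` are retained.  The window is a row
    attribute matched exactly — tables are ingested already windowed.
    """
    cols = ["experiment_id", "tf_name", "target_gene", "binding_score", "tss_window_kb"]
    df = _read_tsv(path, cols, "tf_targets")
    report = LoaderReport(input_rows=len(df))
    try:
        scores = df["binding_score"].astype(float)
        windows = df["tss_window_kb"].astype(float)
    except ValueError as exc:
        bad = _first_bad_numeric(df, ["binding_score", "tss_window_kb"])
        raise KBFormatError(
            f"tf_targets: unparseable numeric value at line {bad}"
        ) from exc
    keep = (
        (windows == float(tss_window_kb))
        & (scores >= float(score_threshold))
        & (df["tf_name"] != "")
        & (df["target_gene"] != "")
    )
    out = df.loc[keep, cols].copy()
    out["binding_score"] = out["binding_score"].astype(float)
    out["tss_window_kb"] = out["tss_window_kb"].astype(float)
    report.retained = len(out)
    report.rejected = report.input_rows - report.retained
    if report.input_rows and not report.retained:
        msg = f"tf_targets: no rows at window {tss_window_kb} kb / score >= {score_threshold}"
        report.warnings.append(msg)
        logger.warning(msg)
    return _attach(out, report)


def _first_bad_numeric(df: pd.DataFrame, cols: list[str]) -> int:
    for i, row in df.iterrows():
        for c in cols:
            try:
                float(row[c])
            except ValueError:
                return int(i) + 2  # 1-based line number incl. header
    return -1


def load_mirna_targets(path: PathLike) -> pd.DataFrame:
    """Load (miRNA, target gene) support pairs, deduplicated."""
    cols = ["mirna_id", "target_gene", "support_type"]
    df = _read_tsv(path, cols, "mirna_targets")
    report = LoaderReport(input_rows=len(df))
    ok = (df["mirna_id"] != "") & (df["target_gene"] != "")
    report.rejected = int((~ok).sum())
    out = df.loc[ok].drop_duplicates(subset=["mirna_id", "target_gene"])
    # dedup removals count as rejected so row conservation holds
    report.rejected += int(ok.sum()) - len(out)
    report.retained = len(out)
    return _attach(out[cols].copy(), report)


def load_ppi(path: PathLike, score_threshold: int = 400) -> pd.DataFrame:
    """Load STRING-style links, keep combined_score >= threshold, and
    canonicalize each unordered pair to a single row with the maximum score."""
    cols = ["protein_a", "protein_b", "combined_score"]
    df = _read_tsv(path, cols, "ppi_links")
    report = LoaderReport(input_rows=len(df))
    try:
        scores = df["combined_score"].astype(int)
    except ValueError as exc:
        raise KBFormatError("ppi_links: combined_score must be integer") from exc
    if ((scores < 0) | (scores > 1000)).any():
        raise KBFormatError("ppi_links: combined_score outside [0, 1000]")
    df = df.assign(combined_score=scores)
    keep = df["combined_score"] >= int(score_threshold)
    kept = df.loc[keep].copy()
    a = kept[["protein_a", "protein_b"]].min(axis=1)
    b = kept[["protein_a", "protein_b"]].max(axis=1)
    kept["protein_a"], kept["protein_b"] = a, b
    out = (
        kept.sort_values("combined_score", ascending=False)
        .drop_duplicates(subset=["protein_a", "protein_b"])
        .sort_index()
    )
    report.retained = len(out)
    report.rejected = report.input_rows - report.retained
    return _attach(out[cols].copy(), report)


def load_metabolic_reactions(path: PathLike) -> pd.DataFrame:
    """Load reaction association rows.

    Each row links one reaction to exactly one of: a catalysing gene (via
    its EC number; ``compound_id`` and ``role`` empty) or a compound in a
    ``substrate``/``product`` role.  ``pathway_id`` is retained for layout.
    """
    cols = ["reaction_id", "ec_number", "gene", "compound_id", "role", "pathway_id"]
    df = _read_tsv(path, cols, "reactions")
    report = LoaderReport(input_rows=len(df))
    bad_roles = sorted(
        set(df.loc[(df["compound_id"] != "") & ~df["role"].isin(["substrate", "product"]), "role"])
    )
    if bad_roles:
        raise KBFormatError(f"reactions: unknown role value(s): {', '.join(bad_roles)}")
    is_gene_row = (df["gene"] != "") & (df["compound_id"] == "")
    is_compound_row = (df["compound_id"] != "") & (df["gene"] == "")
    ok = (df["reaction_id"] != "") & (is_gene_row | is_compound_row)
    report.rejected = int((~ok).sum())
    out = df.loc[ok].drop_duplicates(subset=["reaction_id", "ec_number", "gene", "compound_id", "role"])
    report.rejected += int(ok.sum()) - len(out)
    report.retained = len(out)
    return _attach(out[cols].copy(), report)


def load_allosteric(path: PathLike, name_map: pd.DataFrame) -> pd.DataFrame:
    """Load BRENDA-style activator/inhibitor rows and resolve compound names
    to canonical compound ids.

    Resolution priority: InChIKey, exact canonical name, then the synonym
    table; first hit wins.  Unresolved rows are dropped and counted.  A
    compound listed as both activator and inhibitor of the same enzyme is
    kept as two rows flagged ``ambiguous`` rather than dropped.
    """
    cols = ["ec_number", "compound_name", "inchikey", "mode"]
    df = _read_tsv(path, cols, "allosteric")
    for c in ("compound_id", "name"):
        if c not in name_map.columns:
            raise KBFormatError(f"allosteric name_map missing required column: {c}")
    report = LoaderReport(input_rows=len(df))
    bad_modes = sorted(set(df.loc[~df["mode"].isin(["activator", "inhibitor"]), "mode"]))
    if bad_modes:
        raise KBFormatError(f"allosteric: unknown mode value(s): {', '.join(bad_modes)}")

    by_inchikey: dict[str, str] = {}
    if "inchikey" in name_map.columns:
        for _, r in name_map.iterrows():
            if r.get("inchikey", ""):
                by_inchikey.setdefault(str(r["inchikey"]), str(r["compound_id"]))
    by_name = {str(r["name"]).lower(): str(r["compound_id"]) for _, r in name_map.iterrows() if r["name"]}
    by_synonym: dict[str, str] = {}
    if "synonyms" in name_map.columns:
        for _, r in name_map.iterrows():
            for syn in str(r.get("synonyms", "")).split("|"):
                if syn:
                    by_synonym.setdefault(syn.lower(), str(r["compound_id"]))

    resolved = []
    for _, row in df.iterrows():
        cid = by_inchikey.get(row["inchikey"]) if row["inchikey"] else None
        if cid is None:
            cid = by_name.get(row["compound_name"].lower())
        if cid is None:
            cid = by_synonym.get(row["compound_name"].lower())
        if cid is None:
            report.dropped_unresolved += 1
            continue
        resolved.append((row["ec_number"], cid, row["mode"]))
    out = pd.DataFrame(resolved, columns=["ec_number", "compound_id", "mode"]).drop_duplicates()
    report.rejected = report.input_rows - report.dropped_unresolved - len(out)
    both = out.groupby(["ec_number", "compound_id"])["mode"].transform("nunique") > 1
    out = out.assign(ambiguous=both)
    report.retained = len(out)
    if report.dropped_unresolved:
        logger.warning("allosteric: %d unresolved compound name(s) dropped", report.dropped_unresolved)
    return _attach(out, report)


def load_transporters(path: PathLike, max_compound_degree: int = 50) -> pd.DataFrame:
    """Load TCDB-style transporter–substrate rows.

    Substrate compounds linked to ``max_compound_degree`` or more other
    compounds (ChEBI ontology degree) are removed, as are transporters not
    localized on the cellular membrane.
    """
    cols = ["transporter_id", "gene", "compound_id", "chebi_degree", "membrane_localized"]
    df = _read_tsv(path, cols, "transporters")
    report = LoaderReport(input_rows=len(df))
    try:
        degree = df["chebi_degree"].astype(int)
    except ValueError as exc:
        raise KBFormatError("transporters: chebi_degree must be integer") from exc
    if (degree < 0).any():
        raise KBFormatError("transporters: negative chebi_degree")
    membrane = df["membrane_localized"].str.lower().isin(["true", "1", "yes"])
    keep = (degree < int(max_compound_degree)) & membrane
    out = df.loc[keep].copy()
    out["chebi_degree"] = out["chebi_degree"].astype(int)
    out["membrane_localized"] = True
    report.retained = len(out)
    report.rejected = report.input_rows - report.retained
    if report.input_rows and not report.retained:
        msg = "transporters: all rows removed by degree/membrane filters"
        report.warnings.append(msg)
        logger.warning(msg)
    return _attach(out[cols].copy(), report)


#: canonical column sets of the six post-load tables
TABLE_COLUMNS = {
    "tf_targets": ["experiment_id", "tf_name", "target_gene", "binding_score", "tss_window_kb"],
    "mirna_targets": ["mirna_id", "target_gene", "support_type"],
    "ppi_links": ["protein_a", "protein_b", "combined_score"],
    "reactions": ["reaction_id", "ec_number", "gene", "compound_id", "role", "pathway_id"],
    "allosteric": ["ec_number", "compound_id", "mode", "ambiguous"],
    "transporters": ["transporter_id", "gene", "compound_id", "chebi_degree", "membrane_localized"],
}


def empty_table(kind: str) -> pd.DataFrame:
    """An empty table with the canonical columns of ``kind``."""
    return pd.DataFrame(columns=TABLE_COLUMNS[kind])


def load_knowledge_base(
    directory: PathLike,
    tss_window_kb: float = 1,
    tf_score_threshold: float = 0,
    ppi_score_threshold: int = 400,
    max_compound_degree: int = 50,
    filenames: Optional[Mapping[str, str]] = None,
    tables: Optional[set] = None,
) -> KnowledgeBase:
    """Load knowledge-base tables from a directory of fixture-dialect TSVs.

    Default filenames: ``tf_targets.tsv``, ``mirna_targets.tsv``,
    ``ppi_links.tsv``, ``reactions.tsv``, ``allosteric.tsv`` (+
    ``name_map.tsv``), ``transporters.tsv``.  ``tables`` restricts loading
    to a subset (e.g. ``{"tf_targets", "mirna_targets"}``); the remaining
    tables are empty.
    """
    directory = Path(directory)
    names = {
        "tf_targets": "tf_targets.tsv",
        "mirna_targets": "mirna_targets.tsv",
        "ppi_links": "ppi_links.tsv",
        "reactions": "reactions.tsv",
        "allosteric": "allosteric.tsv",
        "name_map": "name_map.tsv",
        "transporters": "transporters.tsv",
    }
    names.update(filenames or {})
    if tables is None:
        tables = set(TABLE_COLUMNS)
    unknown = tables - set(TABLE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown knowledge-base table(s): {sorted(unknown)}")
    loaded = {kind: empty_table(kind) for kind in TABLE_COLUMNS}
    if "tf_targets" in tables:
        loaded["tf_targets"] = load_tf_targets(
            directory / names["tf_targets"], tss_window_kb, tf_score_threshold
        )
    if "mirna_targets" in tables:
        loaded["mirna_targets"] = load_mirna_targets(directory / names["mirna_targets"])
    if "ppi_links" in tables:
        loaded["ppi_links"] = load_ppi(directory / names["ppi_links"], ppi_score_threshold)
    if "reactions" in tables:
        loaded["reactions"] = load_metabolic_reactions(directory / names["reactions"])
    if "allosteric" in tables:
        name_map = pd.read_csv(
            directory / names["name_map"], sep="\t", dtype=str, keep_default_na=False
        )
        loaded["allosteric"] = load_allosteric(directory / names["allosteric"], name_map)
    if "transporters" in tables:
        loaded["transporters"] = load_transporters(
            directory / names["transporters"], max_compound_degree
        )
    return KnowledgeBase(**loaded)
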