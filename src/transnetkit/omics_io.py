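"""User omics-table parsing.

Inputs are the simple two-column tables produced by upstream differential
analysis: one molecule identifier and one response token per row.  Only
molecules with a significant change appear — "unchanged" molecules are
simply absent from the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Set, Union

import pandas as pd

from .graph_core import Compartment, Direction, Layer

__all__ = [
    "OmicsTable",
    "OmicsFormatError",
    "parse_omics_table",
    "load_background_genes",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_TOKENS = {
    "increased": Direction.INCREASED,
    "up": Direction.INCREASED,
    "+1": Direction.INCREASED,
    "1": Direction.INCREASED,
    "decreased": Direction.DECREASED,
    "down": Direction.DECREASED,
    "-1": Direction.DECREASED,
}


class OmicsFormatError(ValueError):
    pass


@dataclass
class OmicsTable:
    """A per-layer, per-compartment list of changed molecules."""

    layer: Layer
    compartment: Compartment
    records: list = field(default_factory=list)  # list[(id, Direction)]
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        self.compartment = Compartment(self.compartment)
        seen: dict[str, Direction] = {}
        for ident, direction in self.records:
            direction = Direction(direction)
            if direction not in (Direction.INCREASED, Direction.DECREASED):
                raise OmicsFormatError(
                    f"omics record {ident!r}: direction must be increased/decreased"
                )
            if ident in seen and seen[ident] is not direction:
                raise OmicsFormatError(f"conflicting directions for id {ident!r}")
            seen[ident] = direction
        self.records = list(seen.items())

    @property
    def ids(self) -> Set[str]:
        return {ident for ident, _ in self.records}

    def ids_with(self, direction: Direction) -> Set[str]:
        direction = Direction(direction)
        return {ident for ident, d in self.records if d is direction}

    @property
    def directions(self) -> dict:
        return dict(self.records)

    def write(self, path: PathLike) -> None:
        df = pd.DataFrame(
            [(i, d.value) for i, d in self.records], columns=["id", "response"]
        )
        df.to_csv(path, sep="\t", index=False)


def parse_omics_table(
    path: PathLike,
    layer: Layer,
    compartment: Compartment = Compartment.TISSUE,
    condition_label: str = "",
) -> OmicsTable:
    """Parse a two-column (id, response) TSV/CSV into an :class:`OmicsTable`.

    Response tokens are normalized case-insensitively from
    ``increased/up/+1`` and ``decreased/down/-1``.  Duplicate ids with the
    same direction collapse; conflicting directions raise.  A first line
    whose second field is not a recognised token is treated as a header.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, header=None, keep_default_na=False)
    if df.shape[1] < 2:
        raise OmicsFormatError(f"{path}: expected two columns (id, response)")
    df = df.iloc[:, :2]
    df.columns = ["id", "response"]
    start = 0
    if len(df) and str(df.iloc[0, 1]).strip().lower() not in _TOKENS:
        start = 1  # header line
    records = []
    seen: dict[str, Direction] = {}
    conflicts = []
    for offset, (_, row) in enumerate(df.iloc[start:].iterrows()):
        lineno = start + offset + 1
        ident = str(row["id"]).strip()
        token = str(row["response"]).strip().lower()
        if not ident:
            raise OmicsFormatError(f"{path}:{lineno}: empty molecule id")
        if token not in _TOKENS:
            raise OmicsFormatError(
                f"{path}:{lineno}: unknown response token {row['response']!r}"
            )
        direction = _TOKENS[token]
        if ident in seen:
            if seen[ident] is not direction:
                conflicts.append(ident)
            continue
        seen[ident] = direction
        records.append((ident, direction))
    if conflicts:
        raise OmicsFormatError(
            f"{path}: conflicting directions for id(s): {', '.join(sorted(set(conflicts)))}"
        )
    return OmicsTable(
        layer=layer,
        compartment=compartment,
        records=records,
        condition_label=condition_label or path.stem,
    )


def load_background_genes(
    path: PathLike, uploaded_ids: Optional[Sequence[str]] = None
) -> Set[str]:
    """Load a background gene list (one id per line) for TF enrichment.

    The background should be a superset of the uploaded mRNA ids; missing
    ids are logged as a warning (enrichment builders then enforce their own
    policy).  An empty file is an error — a supplied background cannot be
    empty.
    """
    path = Path(path)
    ids = {line.strip() for line in path.read_text().splitlines() if line.strip()}
    if not ids:
        raise OmicsFormatError(f"{path}: background gene list is empty")
    if uploaded_ids:
        missing = sorted(set(uploaded_ids) - ids)
        if missing:
            logger.warning(
                "background is missing %d uploaded gene(s): %s",
                len(missing),
                ", ".join(missing[:10]),
            )
    return ids
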