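"""Ligand-receptor interaction tables and cell-type signature collections.

Interaction partners may be heteromeric complexes written as colon-joined
gene symbols (``"ITGAX:ITGB2"``); a pair identifier joins the two partner
tokens with an underscore (``"THY1_ITGAX:ITGB2"``).  Signatures are named
marker-gene sets labelled with the cell type they identify.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionPair",
    "InteractionTable",
    "GeneSignature",
    "MalformedPartnerError",
    "parse_partner",
    "make_pair_id",
    "load_interaction_table",
    "load_signatures",
    "restrict_pairs",
    "bundled_interaction_table",
    "bundled_signatures",
]

COMPLEX_DELIMITER = ":"
PAIR_DELIMITER = "_"


class MalformedPartnerError(ValueError):
    """Raised for empty or partially empty partner tokens."""


def parse_partner(token: str) -> list[str]:
    """Split a (possibly complex) partner token into its subunit symbols.

    ``"TLR2"`` yields ``["TLR2"]``; ``"ITGAX:ITGB2"`` yields
    ``["ITGAX", "ITGB2"]``.  Subunit order is preserved and surrounding
    whitespace is stripped.

    Raises
    ------
    MalformedPartnerError
        If the token, or any colon-delimited component, is empty.
    """
    if token is None or not str(token).strip():
        raise MalformedPartnerError("empty partner token")
    parts = [p.strip() for p in str(token).strip().split(COMPLEX_DELIMITER)]
    if any(not p for p in parts):
        raise MalformedPartnerError(f"malformed partner token: {token!r}")
    return parts


def make_pair_id(partner_a: Sequence[str], partner_b: Sequence[str]) -> str:
    """Canonical pair identifier: colon-joined partners joined by ``_``."""
    return COMPLEX_DELIMITER.join(partner_a) + PAIR_DELIMITER + COMPLEX_DELIMITER.join(partner_b)


@dataclass(frozen=True)
class InteractionPair:
    """One ligand-receptor pair; either side may be a multi-subunit complex."""

    partner_a: tuple[str, ...]
    partner_b: tuple[str, ...]
    family: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        for side in (self.partner_a, self.partner_b):
            if not side:
                raise MalformedPartnerError("partner list must be non-empty")
            if any(not g for g in side):
                raise MalformedPartnerError("empty gene symbol in partner")
        object.__setattr__(self, "partner_a", tuple(self.partner_a))
        object.__setattr__(self, "partner_b", tuple(self.partner_b))

    @property
    def pair_id(self) -> str:
        return make_pair_id(self.partner_a, self.partner_b)

    @property
    def genes(self) -> frozenset[str]:
        """All member genes of both partners."""
        return frozenset(self.partner_a) | frozenset(self.partner_b)

    @property
    def is_autocrine_loop(self) -> bool:
        """True when a gene occurs on both sides of the pair."""
        return bool(set(self.partner_a) & set(self.partner_b))


@dataclass
class InteractionTable:
    """An ordered collection of unique interaction pairs."""

    pairs: list[InteractionPair] = field(default_factory=list)
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        if not self.allow_duplicates:
            seen: set[str] = set()
            for p in self.pairs:
                if p.pair_id in seen:
                    raise ValueError(f"duplicate pair: {p.pair_id}")
                seen.add(p.pair_id)
        loops = [p.pair_id for p in self.pairs if p.is_autocrine_loop]
        if loops:
            logger.info("%d pair(s) share a gene on both sides: %s", len(loops), loops[:5])

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[InteractionPair]:
        return iter(self.pairs)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out |= p.genes
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": [p.pair_id for p in self.pairs],
                "ligand": [COMPLEX_DELIMITER.join(p.partner_a) for p in self.pairs],
                "receptor": [COMPLEX_DELIMITER.join(p.partner_b) for p in self.pairs],
                "family": [p.family for p in self.pairs],
                "source": [p.source for p in self.pairs],
            }
        )


@dataclass(frozen=True)
class GeneSignature:
    """A named marker-gene set tagged with the cell type it identifies."""

    name: str
    genes: frozenset[str]
    cell_type: str
    compartment: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        genes = frozenset(self.genes)
        if not genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if any(not g for g in genes):
            raise ValueError(f"signature {self.name!r} contains an empty gene symbol")
        object.__setattr__(self, "genes", genes)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV, sniffing the delimiter from the extension/content."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    if path.suffix.lower() not in {".tsv", ".txt", ".csv"}:
        sep = None  # let pandas sniff
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                       comment="#", dtype=str)


def load_interaction_table(
    path: str | Path,
    ligand_column: str = "ligand",
    receptor_column: str = "receptor",
    uppercase: bool = True,
) -> InteractionTable:
    """Load an interaction table from delimited text.

    Expected columns: ligand and receptor partner tokens (``":"`` joins
    complex subunits) plus optional ``family`` and ``source`` annotations.
    Duplicate (ligand, receptor) rows are rejected.
    """
    df = _read_delimited(path)
    missing = [c for c in (ligand_column, receptor_column) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    pairs: list[InteractionPair] = []
    for _, row in df.iterrows():
        a = parse_partner(row[ligand_column])
        b = parse_partner(row[receptor_column])
        if uppercase:
            a = [g.upper() for g in a]
            b = [g.upper() for g in b]
        pairs.append(
            InteractionPair(
                partner_a=tuple(a),
                partner_b=tuple(b),
                family=row.get("family") if isinstance(row.get("family"), str) else None,
                source=row.get("source") if isinstance(row.get("source"), str) else None,
            )
        )
    table = InteractionTable(pairs)
    logger.info("loaded %d interaction pairs from %s", len(table), path)
    return table


def _load_signatures_tsv(path: Path, uppercase: bool) -> list[GeneSignature]:
    df = _read_delimited(path)
    required = {"name", "cell_type", "genes"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: signature TSV needs columns {sorted(required)}")
    out: list[GeneSignature] = []
    for _, row in df.iterrows():
        raw = row["genes"]
        if not isinstance(raw, str) or not raw.strip():
            raise ValueError(f"signature {row['name']!r} has an empty gene list")
        genes = [g.strip() for g in raw.split(",") if g.strip()]
        if uppercase:
            genes = [g.upper() for g in genes]
        compartment = row.get("compartment")
        out.append(
            GeneSignature(
                name=row["name"],
                genes=frozenset(genes),
                cell_type=row["cell_type"],
                compartment=compartment if isinstance(compartment, str) else None,
            )
        )
    return out


def _load_signatures_gmt(path: Path, uppercase: bool) -> list[GeneSignature]:
    out: list[GeneSignature] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT record with no genes: {fields[0]!r}")
        name, description = fields[0], fields[1]
        genes = [g.strip() for g in fields[2:] if g.strip()]
        if not genes:
            raise ValueError(f"{path}: GMT record with no genes: {name!r}")
        if uppercase:
            genes = [g.upper() for g in genes]
        out.append(GeneSignature(name=name, genes=frozenset(genes),
                                 cell_type=description or name))
    return out


def load_signatures(path: str | Path, uppercase: bool = True) -> list[GeneSignature]:
    """Load a signature collection from TSV (name, cell_type, compartment,
    comma-separated genes) or GMT (name, description, tab-separated genes).

    Signature names must be unique within the collection.
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sigs = _load_signatures_gmt(path, uppercase)
    else:
        sigs = _load_signatures_tsv(path, uppercase)
    names = [s.name for s in sigs]
    dups = {n for n in names if names.count(n) > 1}
    if dups:
        raise ValueError(f"duplicate signature names: {sorted(dups)}")
    logger.info("loaded %d signatures from %s", len(sigs), path)
    return sigs


def restrict_pairs(
    table: InteractionTable, universe: Iterable[str]
) -> tuple[InteractionTable, pd.DataFrame]:
    """Keep only pairs whose member genes (every subunit of both partners)
    are all present in ``universe``.

    Returns the restricted table and a report of dropped pairs with the
    symbols that were missing.  Idempotent; preserves pair order.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe must be non-empty")
    kept: list[InteractionPair] = []
    dropped: list[dict] = []
    for p in table:
        missing = sorted(p.genes - universe)
        if missing:
            dropped.append({"pair_id": p.pair_id, "missing": ",".join(missing)})
        else:
            kept.append(p)
    report = pd.DataFrame(dropped, columns=["pair_id", "missing"])
    if not kept:
        warnings.warn("no interaction pairs remain after restriction to the universe")
    return InteractionTable(kept, allow_duplicates=table.allow_duplicates), report


def _bundled(name: str) -> Path:
    return Path(str(_importlib_resources.files("scxtalk").joinpath("data", name)))


def bundled_interaction_table() -> InteractionTable:
    """The curated ligand-receptor collection shipped with the package."""
    return load_interaction_table(_bundled("ligand_receptor_pairs.tsv"))


def bundled_signatures() -> list[GeneSignature]:
    """The curated cell-type signature collection shipped with the package."""
    return load_signatures(_bundled("signatures.tsv"))
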