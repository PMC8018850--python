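"""Transaction databases of acupoint prescriptions.

A *prescription* is the set of acupoints one trial used together; a
collection of prescriptions forms a transaction database, the input to
frequent-itemset mining.  Acupoints are coded by meridian abbreviation
plus point number (``ST36``, ``CV12``).  The module also bundles the
17-trial diabetic-gastroparesis (DGP) database that ships with the
package, and implements item-frequency and itemset-support counting.

Two plain-text interchange formats are supported:

``basket``
    one prescription per line, ``source_id: item1,item2,...`` (the
    leading label is optional);
``long``
    delimited two-column text, ``source_id,item``, one row per item
    occurrence (comma or tab, auto-detected).
"""

from __future__ import annotations

import hashlib
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import pandas as pd

__all__ = [
    "normalize_item",
    "Prescription",
    "TransactionDB",
    "read_transactions",
    "write_transactions",
    "item_frequencies",
    "support_count",
    "dgp_fixture",
    "DGP_FORMULA_COUNT",
]

#: Number of distinct formula columns in the source dataset's reporting
#: convention; used as the support denominator in ``formulas`` mode.
DGP_FORMULA_COUNT = 14

_ITEM_RE = re.compile(r"^[A-Z]{1,4}[0-9]+$")


class ItemCodeError(ValueError):
    """Raised for acupoint codes that cannot be normalized."""


def normalize_item(raw: str) -> str:
    """Normalize an acupoint code: strip whitespace, uppercase, validate.

    A valid code is a meridian letter prefix followed by a point number,
    e.g. ``" cv12 "`` → ``"CV12"``.  Normalization is idempotent.

    Raises
    ------
    ItemCodeError
        If the token is empty or does not match letters-then-digits.
    """
    code = "".join(str(raw).split()).upper()
    if not code:
        raise ItemCodeError("empty acupoint code")
    if not _ITEM_RE.match(code):
        raise ItemCodeError(f"malformed acupoint code: {raw!r}")
    return code


@dataclass(frozen=True)
class Prescription:
    """One trial's set of acupoints, with its source label."""

    source_id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"prescription {self.source_id!r} has no items")
        object.__setattr__(self, "items", frozenset(self.items))

    @classmethod
    def from_raw(cls, source_id: str, raw_items: Iterable[str]) -> "Prescription":
        return cls(source_id, frozenset(normalize_item(t) for t in raw_items))

    def sorted_items(self) -> list[str]:
        return sorted(self.items)


TransactionsLike = Union["TransactionDB", Sequence[Iterable[str]]]


class TransactionDB:
    """An ordered collection of prescriptions over a shared vocabulary.

    Parameters
    ----------
    prescriptions : sequence of Prescription
        Kept in order; duplicate item sets from different sources are
        distinct transactions.
    support_denominator : int, optional
        The divisor used when converting itemset counts to fractional
        supports.  Defaults to the number of prescriptions, in which
        case every support lies in [0, 1].  A different denominator
        (e.g. the 14-formula reporting convention of the bundled DGP
        database) makes supports above 1 possible.
    """

    def __init__(
        self,
        prescriptions: Sequence[Prescription],
        support_denominator: int | None = None,
    ) -> None:
        self.prescriptions: list[Prescription] = list(prescriptions)
        if support_denominator is None:
            support_denominator = len(self.prescriptions)
        if support_denominator < 1:
            raise ValueError("support_denominator must be >= 1")
        self.support_denominator = int(support_denominator)

    @property
    def vocabulary(self) -> frozenset[str]:
        """Union of all prescription item sets."""
        out: set[str] = set()
        for p in self.prescriptions:
            out |= p.items
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.prescriptions)

    def __iter__(self) -> Iterator[Prescription]:
        return iter(self.prescriptions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransactionDB):
            return NotImplemented
        return (
            self.prescriptions == other.prescriptions
            and self.support_denominator == other.support_denominator
        )

    def __repr__(self) -> str:
        return (
            f"TransactionDB(n={len(self)}, vocab={len(self.vocabulary)}, "
            f"denominator={self.support_denominator})"
        )

    def itemsets(self) -> list[frozenset[str]]:
        return [p.items for p in self.prescriptions]

    def with_denominator(self, denominator: int) -> "TransactionDB":
        """Return a shallow copy using a different support denominator."""
        return TransactionDB(self.prescriptions, denominator)

    @classmethod
    def from_itemsets(
        cls,
        itemsets: Sequence[Iterable[str]],
        support_denominator: int | None = None,
        normalize: bool = False,
    ) -> "TransactionDB":
        """Build a database from bare item collections (labels ``t1..tn``)."""
        ps = []
        for i, items in enumerate(itemsets, start=1):
            if normalize:
                ps.append(Prescription.from_raw(f"t{i}", items))
            else:
                ps.append(Prescription(f"t{i}", frozenset(items)))
        return cls(ps, support_denominator)

    def content_hash(self) -> str:
        """Order-invariant SHA-256 of the database content.

        Hashes the sorted canonical ``source_id: items`` lines, so two
        databases holding the same prescriptions in different orders
        hash identically.
        """
        lines = sorted(
            f"{p.source_id}: {','.join(p.sorted_items())}" for p in self.prescriptions
        )
        return hashlib.sha256("\n".join(lines).encode("utf-8")).hexdigest()


def as_transaction_db(data: TransactionsLike) -> TransactionDB:
    """Coerce a list of item collections (or a TransactionDB) to a TransactionDB."""
    if isinstance(data, TransactionDB):
        return data
    return TransactionDB.from_itemsets(list(data))


def _parse_basket(text: str) -> list[Prescription]:
    prescriptions = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" in line:
            label, _, items_part = line.partition(":")
            label = label.strip()
        else:
            label, items_part = "", line
        tokens = [t for t in items_part.split(",") if t.strip()]
        if not tokens:
            raise ValueError(f"line {lineno}: prescription with zero items")
        if not label:
            label = f"t{len(prescriptions) + 1}"
        prescriptions.append(Prescription.from_raw(label, tokens))
    return prescriptions


def _parse_long(text: str) -> list[Prescription]:
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    frame = pd.read_csv(
        io.StringIO(text), sep=delim, header=None, names=["source_id", "item"],
        dtype=str, comment="#", skip_blank_lines=True,
    )
    if frame.empty:
        raise ValueError("no rows in long-format input")
    prescriptions = []
    # groupby(sort=False) preserves first-appearance order of the sources
    for source_id, group in frame.groupby("source_id", sort=False):
        prescriptions.append(Prescription.from_raw(str(source_id), group["item"]))
    return prescriptions


def read_transactions(path: str | Path, format: str = "basket") -> TransactionDB:
    """Read a transaction database from delimited text.

    Duplicate items within a prescription collapse (set semantics);
    duplicate prescriptions remain distinct transactions.  The default
    support denominator is the number of prescriptions.
    """
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"empty transaction file: {path}")
    if format == "basket":
        prescriptions = _parse_basket(text)
    elif format == "long":
        prescriptions = _parse_long(text)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'basket' or 'long')")
    if not prescriptions:
        raise ValueError(f"no prescriptions parsed from {path}")
    return TransactionDB(prescriptions)


def write_transactions(db: TransactionDB, path: str | Path, format: str = "basket") -> None:
    """Write a database as basket or long delimited text (UTF-8)."""
    lines: list[str] = []
    if format == "basket":
        for p in db:
            lines.append(f"{p.source_id}: {','.join(p.sorted_items())}")
    elif format == "long":
        for p in db:
            for item in p.sorted_items():
                lines.append(f"{p.source_id},{item}")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'basket' or 'long')")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def dgp_fixture(denominator: str | int = "n") -> TransactionDB:
    """The bundled 17-trial diabetic-gastroparesis acupoint database.

    Parameters
    ----------
    denominator : {"n", "formulas"} or int
        ``"n"`` (default) divides supports by the 17 transactions;
        ``"formulas"`` uses the source dataset's 14-formula reporting
        convention (supports may exceed 1); an integer is used as-is.
    """
    ref = resources.files("acumine.data") / "dgp_rcts.basket"
    prescriptions = _parse_basket(ref.read_text(encoding="utf-8"))
    db = TransactionDB(prescriptions)
    return db.with_denominator(resolve_denominator(denominator, db))


def resolve_denominator(mode: str | int, db: TransactionDB) -> int:
    """Resolve a denominator mode to an integer for a given database."""
    if isinstance(mode, int) and not isinstance(mode, bool):
        return mode
    if mode == "n":
        return len(db)
    if mode == "formulas":
        return DGP_FORMULA_COUNT
    try:
        return int(mode)
    except (TypeError, ValueError):
        raise ValueError(
            f"unknown denominator mode {mode!r} (expected 'n', 'formulas' or an integer)"
        ) from None


def item_frequencies(db: TransactionDB) -> pd.DataFrame:
    """Per-item occurrence counts across prescriptions.

    Returns a DataFrame with columns ``item``, ``count`` (number of
    prescriptions containing the item) and ``fraction``
    (count / support denominator), sorted by count descending with ties
    broken lexicographically by code.
    """
    if len(db) == 0:
        raise ValueError("empty transaction database")
    counts: dict[str, int] = {}
    for p in db:
        for item in p.items:
            counts[item] = counts.get(item, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    frame = pd.DataFrame(rows, columns=["item", "count"])
    frame["fraction"] = frame["count"] / db.support_denominator
    return frame


def support_count(db: TransactionDB, itemset: Iterable[str]) -> tuple[int, float]:
    """Occurrence count and fractional support of an itemset.

    The count is the number of prescriptions whose item set contains
    every member of ``itemset``; the support divides by the database's
    configured denominator.  Items absent from the vocabulary simply
    yield a zero count.
    """
    target = frozenset(itemset)
    if not target:
        raise ValueError("itemset must be non-empty")
    count = sum(1 for p in db if target <= p.items)
    return count, count / db.support_denominator
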