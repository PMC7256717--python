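"""Transaction data model and I/O for acupoint prescription databases.

A *transaction* is one study's full acupoint prescription treated as an
unordered item set; a :class:`TransactionDB` is an ordered collection of
transactions together with the item universe (the union of all codes).

Acupoint codes follow the WHO standard nomenclature: an uppercase meridian or
category prefix followed by a point number (``BL13``, ``ST36``, ``CV17``,
``EXB1``). Literature sources abbreviate some prefixes (``L5`` for ``LU5``,
``Du14`` for ``GV14``); :func:`normalize_code` resolves these through an
extensible alias table shipped as data.

Three on-disk dialects are supported and round-trip losslessly:

* **basket** — one transaction per line, ``id: ITEM,ITEM,...``;
* **long CSV** — two columns ``transaction_id,item``, one row per pair;
* **matrix CSV** — a binary incidence matrix, items as rows or columns
  (auto-detected from the header token).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

from .errors import NormalizationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

Format = Literal["basket", "long_csv", "matrix_csv"]

#: canonical code shape after normalization: 2-3 letter prefix + point number
CODE_PATTERN = re.compile(r"^[A-Z]{2,3}[0-9]+$")
_RAW_PATTERN = re.compile(r"^([A-Z]+)\s*0*([0-9]+)$")


def load_aliases() -> dict[str, str]:
    """Return the prefix alias table (e.g. ``L -> LU``) bundled with the package.

    The table is data, not code: users may pass their own mapping to
    :func:`normalize_code` or :func:`read_transactions` to extend it.
    """
    text = resources.files("acurules").joinpath("data/aliases.csv").read_text("utf-8")
    reader = csv.DictReader(text.splitlines())
    return {row["alias"]: row["canonical"] for row in reader}


_DEFAULT_ALIASES: dict[str, str] | None = None


def _default_aliases() -> dict[str, str]:
    global _DEFAULT_ALIASES
    if _DEFAULT_ALIASES is None:
        _DEFAULT_ALIASES = load_aliases()
    return _DEFAULT_ALIASES


def normalize_code(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize a free-text acupoint label to its canonical code.

    Uppercases, strips whitespace and leading zeros in the point number, and
    rewrites aliased meridian prefixes (``L5`` → ``LU5``). Unknown but
    well-formed codes pass through unchanged. Idempotent by construction.

    Raises
    ------
    NormalizationError
        If the token does not have prefix+number shape, or the result does not
        match the canonical pattern.
    """
    if aliases is None:
        aliases = _default_aliases()
    token = raw.strip().upper()
    if not token:
        raise NormalizationError("empty acupoint label")
    m = _RAW_PATTERN.match(token)
    if m is None:
        raise NormalizationError(f"cannot parse acupoint label {raw!r}")
    prefix, number = m.groups()
    prefix = aliases.get(prefix, prefix)
    code = f"{prefix}{number}"
    if not CODE_PATTERN.match(code):
        raise NormalizationError(f"label {raw!r} normalizes to non-canonical {code!r}")
    return code


@dataclass(frozen=True)
class Transaction:
    """One prescription: a study identifier plus its set of acupoint codes."""

    id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValidationError(f"transaction {self.id!r} has no items")
        object.__setattr__(self, "items", frozenset(self.items))

    def __contains__(self, code: str) -> bool:
        return code in self.items


@dataclass(frozen=True)
class TransactionDB:
    """Ordered collection of transactions plus the derived item universe."""

    transactions: tuple[Transaction, ...]
    universe: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "transactions", tuple(self.transactions))
        ids = [t.id for t in self.transactions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate transaction ids: {dupes}")
        universe = sorted(set().union(*(t.items for t in self.transactions))) if self.transactions else []
        object.__setattr__(self, "universe", tuple(universe))

    @property
    def n(self) -> int:
        return len(self.transactions)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.transactions)

    def __getitem__(self, study_id: str) -> Transaction:
        for t in self.transactions:
            if t.id == study_id:
                return t
        raise KeyError(study_id)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-item occurrence counts (number of transactions containing the item)."""

    entries: Mapping[str, int]

    def ranking(self) -> list[tuple[str, int]]:
        """Items sorted by count descending, ties broken alphabetically."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))

    def top(self, k: int) -> list[str]:
        return [item for item, _ in self.ranking()[:k]]


def item_frequencies(db: TransactionDB) -> FrequencyTable:
    """Count, for every item in the universe, how many transactions contain it."""
    counts = {item: 0 for item in db.universe}
    for t in db:
        for item in t.items:
            counts[item] += 1
    return FrequencyTable(counts)


def _make_transaction(tid: str, raw_items: Iterable[str], aliases, where: int | None) -> Transaction:
    codes = []
    for raw in raw_items:
        try:
            codes.append(normalize_code(raw, aliases))
        except NormalizationError as exc:
            raise ParseError(str(exc), line=where) from exc
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        logger.warning("transaction %r: duplicate codes %s collapsed", tid, dupes)
    if not codes:
        raise ParseError(f"transaction {tid!r} is empty", line=where)
    return Transaction(tid, frozenset(codes))


def _read_basket(path: Path, aliases) -> TransactionDB:
    transactions = []
    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line:
                tid, _, rest = line.partition(":")
                tid = tid.strip()
                if not tid:
                    raise ParseError("empty transaction id before ':'", line=lineno)
            else:
                tid, rest = f"T{len(transactions) + 1}", line
            raw_items = [tok for tok in rest.split(",") if tok.strip()]
            if not raw_items:
                raise ParseError(f"transaction {tid!r} is empty", line=lineno)
            transactions.append(_make_transaction(tid, raw_items, aliases, lineno))
    if not transactions:
        raise ParseError(f"no transactions found in {path}", line=None)
    return TransactionDB(tuple(transactions))


def _read_long_csv(path: Path, aliases) -> TransactionDB:
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001 - surfaced as our parse error
        raise ParseError(f"cannot parse CSV {path}: {exc}") from exc
    expected = ["transaction_id", "item"]
    if list(df.columns[:2]) != expected:
        raise ParseError(f"long CSV must have columns {expected}, got {list(df.columns)}", line=1)
    if df.empty:
        raise ParseError("no transaction rows", line=1)
    if df[expected].isna().any().any():
        bad = int(df[df[expected].isna().any(axis=1)].index[0]) + 2
        raise ParseError("missing transaction_id or item", line=bad)
    transactions = []
    # groups ordered by first appearance; rows with the same id need not be contiguous
    for tid, grp in df.groupby("transaction_id", sort=False):
        where = int(grp.index[0]) + 2  # header is line 1
        transactions.append(_make_transaction(str(tid), list(grp["item"]), aliases, where))
    return TransactionDB(tuple(transactions))


def _read_matrix_csv(path: Path, aliases) -> TransactionDB:
    try:
        df = pd.read_csv(path, index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse CSV {path}: {exc}") from exc
    header = (df.index.name or "").strip().lower()
    if header in {"item", "items"}:
        df = df.T  # items were rows; flip to transactions-as-rows
    elif header not in {"transaction_id", "id", "transaction"}:
        raise ParseError(
            f"matrix header token {df.index.name!r} is neither 'item' nor 'transaction_id'", line=1
        )
    if not set(df.to_numpy().ravel()) <= {"0", "1"}:
        bad = sorted(set(df.to_numpy().ravel()) - {"0", "1"})
        raise ParseError(f"matrix values must be 0 or 1, found {bad}")
    transactions = []
    for row_pos, (tid, row) in enumerate(df.iterrows(), start=2):
        raw_items = [str(col) for col, v in row.items() if v == "1"]
        transactions.append(_make_transaction(str(tid), raw_items, aliases, row_pos))
    return TransactionDB(tuple(transactions))


def read_transactions(
    path: str | Path, format: Format = "basket", aliases: Mapping[str, str] | None = None
) -> TransactionDB:
    """Read a transaction database, normalizing all item codes.

    Parameters
    ----------
    path:
        File to read (UTF-8).
    format:
        ``"basket"``, ``"long_csv"`` or ``"matrix_csv"``.
    aliases:
        Optional prefix alias table overriding the bundled one.

    Transaction order follows file order. Malformed input raises
    :class:`~acurules.errors.ParseError` naming the offending line;
    empty transactions and duplicate ids raise errors rather than being
    silently dropped.
    """
    path = Path(path)
    readers = {"basket": _read_basket, "long_csv": _read_long_csv, "matrix_csv": _read_matrix_csv}
    if format not in readers:
        raise ValidationError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path, aliases)


def write_transactions(db: TransactionDB, path: str | Path, format: Format = "basket") -> None:
    """Write ``db`` in the chosen dialect; readers reproduce it exactly."""
    path = Path(path)
    if format == "basket":
        lines = [f"{t.id}: {','.join(sorted(t.items))}" for t in db]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "long_csv":
        rows = [(t.id, item) for t in db for item in sorted(t.items)]
        pd.DataFrame(rows, columns=["transaction_id", "item"]).to_csv(path, index=False)
    elif format == "matrix_csv":
        data = {item: [int(item in t.items) for t in db] for item in db.universe}
        df = pd.DataFrame(data, index=[t.id for t in db])
        df.index.name = "transaction_id"
        df.to_csv(path)
    else:
        raise ValidationError(f"unknown format {format!r}")


def load_fixture() -> TransactionDB:
    """Return the bundled 12-study COPD acupuncture RCT database.

    Twelve randomized controlled trials of manual or warm acupuncture in
    stable COPD, each contributing its full prescription; after normalization
    the universe holds 27 distinct acupoints.
    """
    with resources.as_file(resources.files("acurules").joinpath("data/copd_rcts.basket")) as p:
        return read_transactions(p, "basket")
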