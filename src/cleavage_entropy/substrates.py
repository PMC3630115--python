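"""Cleavage-site table parsing and per-protease count matrices.

A substrate window spans the eight subpockets P4..P1 | P1'..P4' (scissile
bond between P1 and P1').  Slots beyond a substrate terminus carry a gap
symbol; ambiguous residues are treated as unknown.  Gap and unknown slots
are excluded per position, so every subpocket has its own effective total.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alphabet import (
    CANONICAL_RESIDUES,
    DEFAULT_ALPHABET,
    AminoAcidAlphabet,
    residue_index,
)
from .errors import (
    EmptyInputError,
    TableFormatError,
    ValidationError,
    WindowParseError,
)

logger = logging.getLogger(__name__)

#: Subpocket labels in window order (N-terminal P4 through C-terminal P4').
SUBPOCKETS: tuple[str, ...] = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")

#: ASCII column names accepted/emitted in delimited files.
SUBPOCKET_COLUMNS: tuple[str, ...] = ("P4", "P3", "P2", "P1", "P1p", "P2p", "P3p", "P4p")

N_SUBPOCKETS = 8

_SUBPOCKET_INDEX = {name: i for i, name in enumerate(SUBPOCKETS)}
_SUBPOCKET_INDEX.update({name: i for i, name in enumerate(SUBPOCKET_COLUMNS)})


def subpocket_index(name: str) -> int:
    """Index of a subpocket by label (accepts P1' and P1p spellings)."""
    try:
        return _SUBPOCKET_INDEX[name]
    except KeyError:
        raise ValidationError(f"unknown subpocket: {name!r}") from None


@dataclass(frozen=True)
class CleavageRecord:
    """One substrate's 8-slot window attributed to a protease."""

    protease_id: str
    window: tuple[str, ...]

    def __post_init__(self):
        if len(self.window) != N_SUBPOCKETS:
            raise ValidationError(
                f"window must have exactly {N_SUBPOCKETS} slots, got {len(self.window)}"
            )
        if not any(s in CANONICAL_RESIDUES for s in self.window):
            raise ValidationError("window contains no canonical residue")

    def slot(self, subpocket: str) -> str:
        return self.window[subpocket_index(subpocket)]


def parse_window(
    text: str, alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET
) -> tuple[str, ...]:
    """Parse an 8-character window string into slots in P4 -> P4' order.

    Lowercase is accepted and uppercased.  Raises :class:`WindowParseError`
    with the 1-based position of the first illegal character.
    """
    if len(text) != N_SUBPOCKETS:
        raise WindowParseError(
            f"window must be exactly {N_SUBPOCKETS} characters, got {len(text)}: {text!r}"
        )
    slots = []
    legal = set(alphabet.residues) | {alphabet.gap_symbol} | set(alphabet.unknown_symbols)
    for pos, ch in enumerate(text.upper(), start=1):
        if ch not in legal:
            raise WindowParseError(
                f"illegal character {ch!r} at position {pos} in window {text!r}",
                position=pos,
            )
        slots.append(ch)
    return tuple(slots)


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_cleavage_table(
    path: str | Path,
    *,
    permissive: bool = False,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
    error_sink: list | None = None,
) -> list[CleavageRecord]:
    """Read a delimited cleavage table into records, preserving row order.

    Two dialects are accepted: a ``window`` column of 8-character strings,
    or eight columns named P4..P4p, in both cases alongside ``protease_id``.
    Lines starting with ``#`` are provenance comments and are skipped.

    In strict mode (default) the first malformed row aborts the read; in
    permissive mode malformed rows are logged, collected into *error_sink*
    (if given) as ``(line_number, message)`` pairs, and skipped.
    """
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        numbered = [
            (lineno, line)
            for lineno, line in enumerate(fh, start=1)
            if line.strip() and not line.startswith("#")
        ]
    if not numbered:
        raise TableFormatError(f"no data rows in {path}")
    delim = _detect_delimiter(numbered[0][1])
    rows = list(csv.reader((line for _, line in numbered), delimiter=delim))
    header = [c.strip() for c in rows[0]]
    if "protease_id" not in header:
        raise TableFormatError(f"{path}: missing required column 'protease_id'")
    col = {name: i for i, name in enumerate(header)}

    if "window" in col:
        p_cols = None
    else:
        try:
            p_cols = [col[name] for name in SUBPOCKET_COLUMNS]
        except KeyError:
            raise TableFormatError(
                f"{path}: need either a 'window' column or all of {SUBPOCKET_COLUMNS}"
            ) from None

    records: list[CleavageRecord] = []
    for (lineno, _), cells in zip(numbered[1:], rows[1:]):
        try:
            if len(cells) != len(header):
                raise WindowParseError(
                    f"expected {len(header)} columns, got {len(cells)}"
                )
            pid = cells[col["protease_id"]].strip()
            if not pid:
                raise WindowParseError("empty protease_id")
            if p_cols is None:
                window = parse_window(cells[col["window"]].strip(), alphabet)
            else:
                window = parse_window(
                    "".join(cells[i].strip() for i in p_cols), alphabet
                )
            records.append(CleavageRecord(pid, window))
        except (WindowParseError, ValidationError) as exc:
            msg = f"{path}:{lineno}: {exc}"
            if not permissive:
                raise WindowParseError(msg, line=lineno) from exc
            logger.warning("skipping malformed row: %s", msg)
            if error_sink is not None:
                error_sink.append((lineno, str(exc)))
    return records


def write_cleavage_table(
    records: Iterable[CleavageRecord],
    path: str | Path,
    *,
    provenance: dict | None = None,
) -> None:
    """Write records in the single-``window``-column TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("protease_id\twindow\n")
        for rec in records:
            fh.write(f"{rec.protease_id}\t{''.join(rec.window)}\n")


@dataclass
class CountMatrix:
    """Raw occurrence counts: 20 residues x 8 subpockets for one protease."""

    protease_id: str
    counts: np.ndarray  # (20, 8) non-negative ints
    n_records: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (20, N_SUBPOCKETS):
            raise ValidationError(f"counts must be 20x{N_SUBPOCKETS}")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if (self.column_totals > self.n_records).any():
            raise ValidationError("column total exceeds number of records")

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def build_count_matrix(
    records: Sequence[CleavageRecord],
    protease_id: str,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
) -> CountMatrix:
    """Tally canonical residues per subpocket for one protease.

    Gap and unknown slots contribute to no residue count, so column totals
    may fall below ``n_records``.
    """
    selected = [r for r in records if r.protease_id == protease_id]
    if not selected:
        raise EmptyInputError(f"no records for protease {protease_id!r}")
    counts = np.zeros((20, N_SUBPOCKETS), dtype=np.int64)
    canonical = set(alphabet.residues)
    for rec in selected:
        for i, symbol in enumerate(rec.window):
            if symbol in canonical:
                counts[residue_index(symbol), i] += 1
    return CountMatrix(protease_id, counts, n_records=len(selected))


@dataclass
class SelectionResult:
    """Outcome of the substrate-count filter over a mixed dataset."""

    groups: dict[str, list[CleavageRecord]]
    #: (protease_id, n_records, included, reason) per protease seen.
    log: list[tuple[str, int, bool, str]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("protease_id\tn_records\tincluded\treason\n")
            for pid, n, included, reason in self.log:
                fh.write(f"{pid}\t{n}\t{str(included).lower()}\t{reason}\n")


def filter_proteases(
    records: Sequence[CleavageRecord],
    min_substrates: int = 100,
    exclude_ids: Iterable[str] = (),
) -> SelectionResult:
    """Group records per protease and keep those meeting the count cutoff.

    A protease passes if it has at least *min_substrates* records and its
    identifier is not in *exclude_ids*.  First-appearance order preserved.
    """
    if min_substrates < 1:
        raise ValidationError("min_substrates must be >= 1")
    exclude = set(exclude_ids)
    grouped: dict[str, list[CleavageRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.protease_id, []).append(rec)
    result = SelectionResult(groups={})
    for pid, group in grouped.items():
        if pid in exclude:
            result.log.append((pid, len(group), False, "excluded_by_id"))
        elif len(group) < min_substrates:
            result.log.append(
                (pid, len(group), False, f"below_min_substrates_{min_substrates}")
            )
        else:
            result.groups[pid] = group
            result.log.append((pid, len(group), True, "ok"))
    return result
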