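"""Reading and validating per-experiment DEG list files.

Each experiment is a delimited text file with a transcript (or gene) ID in
the first column and a gene symbol in the second.  The transcript column
exists to absorb inputs where several transcripts annotate the same gene;
the experiment is ultimately consumed as a *set* of gene symbols, so
duplicated symbols collapse.  Extra columns are ignored.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .errors import InputError, UsageError

log = logging.getLogger(__name__)

#: largest number of experiments a single comparison may hold
MAX_EXPERIMENTS = 8


@dataclass(frozen=True)
class DegRecord:
    """One row of a DEG list: an opaque transcript ID annotating a gene symbol."""

    transcript_id: str
    gene_symbol: str


@dataclass
class Experiment:
    """A named DEG list, viewed as a set of gene symbols.

    ``records`` preserves the file order; ``genes`` is the collapsed set of
    distinct symbols and is the representation every downstream stage uses.
    """

    name: str
    records: list[DegRecord] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return {rec.gene_symbol for rec in self.records}


def _split_row(line: str, delimiter: str) -> list[str]:
    return [cell.strip() for cell in line.rstrip("\n").rstrip("\r").split(delimiter)]


def parse_deg_file(
    stream: TextIO | str | Path,
    label: str,
    *,
    delimiter: str = "\t",
    header: str = "auto",
    case_insensitive: bool = False,
) -> Experiment:
    """Parse one DEG list into an :class:`Experiment`.

    Parameters
    ----------
    stream
        Open text stream, path, or raw text content.
    label
        Experiment name (usually derived from the filename).
    delimiter
        Single-character column separator; tab by default.
    header
        ``"auto"`` drops the first row iff its second cell never reappears
        as a gene symbol in the rest of the file; ``"yes"``/``"no"`` force
        the decision.
    case_insensitive
        Fold gene symbols to upper case at parse time.  Off by default
        because symbol case is meaningful in some organisms (e.g. mouse
        ``Tlr2`` vs human ``TLR2``).
    """
    if header not in ("auto", "yes", "no"):
        raise UsageError(f"header must be auto|yes|no, got {header!r}")
    if isinstance(stream, Path) or (
        isinstance(stream, str) and stream and "\n" not in stream and Path(stream).is_file()
    ):
        text = Path(stream).read_text(encoding="utf-8")
    elif isinstance(stream, str):
        text = stream
    else:
        text = stream.read()

    raw_lines = text.splitlines()
    rows: list[tuple[int, list[str]]] = []  # (1-based line number, cells)
    for lineno, line in enumerate(raw_lines, start=1):
        if not line.strip():
            continue  # blank/trailing lines are tolerated anywhere
        rows.append((lineno, _split_row(line, delimiter)))

    if not rows:
        raise InputError(f"{label}: empty DEG file")

    for lineno, cells in rows:
        if len(cells) < 2 or not cells[0] or not cells[1]:
            raise InputError(
                f"{label}: line {lineno}: expected at least 2 columns "
                "(transcript_id, gene_symbol)"
            )

    if header == "yes":
        rows = rows[1:]
        if not rows:
            raise InputError(f"{label}: file contains only a header row")
    elif header == "auto" and len(rows) > 1:
        # Drop row 1 iff its second cell never recurs as a gene symbol in the
        # rest of the file (a lone data row is always kept as data).
        first_symbol = rows[0][1][1]
        if case_insensitive:
            first_symbol = first_symbol.upper()
        rest_symbols = {
            cells[1].upper() if case_insensitive else cells[1] for _, cells in rows[1:]
        }
        if first_symbol not in rest_symbols:
            rows = rows[1:]

    seen: dict[str, str] = {}
    records: list[DegRecord] = []
    for lineno, cells in rows:
        tx, symbol = cells[0], cells[1]
        if case_insensitive:
            symbol = symbol.upper()
        if tx in seen:
            if seen[tx] != symbol:
                raise InputError(
                    f"{label}: line {lineno}: transcript ID {tx!r} annotated with "
                    f"two different symbols ({seen[tx]!r} vs {symbol!r})"
                )
            continue  # exact duplicate row: collapse silently
        seen[tx] = symbol
        records.append(DegRecord(tx, symbol))

    return Experiment(name=label, records=records)


def load_experiments(
    paths: Sequence[str | Path],
    labels: Sequence[str] | None = None,
    *,
    delimiter: str = "\t",
    header: str = "auto",
    case_insensitive: bool = False,
    cap: int = MAX_EXPERIMENTS,
) -> list[Experiment]:
    """Load ``n`` DEG files in order; the list position fixes the experiment
    index ``j`` (1-based) used by the region bit encoding."""
    paths = list(paths)
    if len(paths) < 2:
        raise UsageError("a Venn comparison needs at least 2 DEG files")
    if len(paths) > cap:
        raise UsageError(f"at most {cap} experiments supported, got {len(paths)}")
    if labels is None:
        labels = [Path(p).stem for p in paths]
    if len(labels) != len(paths):
        raise UsageError("number of labels must match number of files")
    if len(set(labels)) != len(labels):
        raise UsageError(f"duplicate experiment labels: {sorted(labels)}")
    return [
        parse_deg_file(
            Path(p),
            label,
            delimiter=delimiter,
            header=header,
            case_insensitive=case_insensitive,
        )
        for p, label in zip(paths, labels)
    ]


def write_deg_file(experiment: Experiment, stream: TextIO, *, delimiter: str = "\t") -> None:
    """Serialize an experiment's records back to the two-column dialect."""
    for rec in experiment.records:
        stream.write(f"{rec.transcript_id}{delimiter}{rec.gene_symbol}\n")
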