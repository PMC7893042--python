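"""Bulk TCR repertoire containers and AIRR-style rearrangement TSV I/O.

A *clonotype* is a unique TCRβ junction (CDR3) nucleotide sequence, optionally
extended with allele-stripped V/J gene context; a *repertoire* is the clonotype
frequency table of one sorted T-cell subset.  Rearrangement tables are read and
written as AIRR-C style tab-separated text (columns ``sequence_id, junction,
v_call, d_call, j_call, productive, duplicate_count, locus, cell_id``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import (
    ArgumentError,
    EmptyInputError,
    EmptyRepertoireError,
    MissingColumnError,
)

_NT_ALPHABET = frozenset("ACGTN")
_TRUE_STRINGS = {"T", "TRUE", "1", "YES", "Y"}
_FALSE_STRINGS = {"F", "FALSE", "0", "NO", "N", ""}

#: frequencies are exact count ratios; comparisons use this absolute tolerance
FREQ_TOL = 1e-9


def strip_allele(call: Optional[str]) -> Optional[str]:
    """Drop the ``*NN`` allele suffix from a gene call (``TRBV7-2*01`` → ``TRBV7-2``)."""
    if call is None:
        return None
    return call.split("*", 1)[0]


@dataclass(frozen=True)
class RearrangementRecord:
    """One observed V(D)J rearrangement (one row of a rearrangement table)."""

    sequence_id: str
    junction_nt: str
    productive: bool
    duplicate_count: int = 1
    v_call: Optional[str] = None
    d_call: Optional[str] = None
    j_call: Optional[str] = None
    locus: str = "TRB"
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.junction_nt or not set(self.junction_nt) <= _NT_ALPHABET:
            raise ArgumentError(
                f"junction must be a non-empty string over A/C/G/T/N, got "
                f"{self.junction_nt!r}"
            )
        if self.duplicate_count < 1:
            raise ArgumentError("duplicate_count must be >= 1")


@dataclass(frozen=True)
class Clonotype:
    """A unique clonotype key with its read count and within-repertoire frequency."""

    key: str
    count: int
    frequency: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ArgumentError("clonotype count must be >= 1")
        if not 0.0 < self.frequency <= 1.0 + FREQ_TOL:
            raise ArgumentError("clonotype frequency must lie in (0, 1]")


@dataclass
class Repertoire:
    """Clonotype frequency table of one sorted subset from one compartment.

    ``subset`` is typically one of Treg / Tconv / ActTconv / Teff_MAMI /
    Teff_IgG / Total and ``compartment`` PB (peripheral blood) or TT (tumor
    tissue); both are free-form labels.
    """

    clonotypes: dict[str, Clonotype]
    sample_id: Optional[str] = None
    subject_id: Optional[str] = None
    subset: Optional[str] = None
    compartment: Optional[str] = None
    key_mode: str = "junction_only"

    def __post_init__(self) -> None:
        if not self.clonotypes:
            raise EmptyRepertoireError("a repertoire must contain >= 1 clonotype")
        total = sum(c.frequency for c in self.clonotypes.values())
        if abs(total - 1.0) > 1e-6:
            raise ArgumentError(f"clonotype frequencies sum to {total}, not 1")

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes.values())

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    def frequencies(self) -> dict[str, float]:
        return {k: c.frequency for k, c in self.clonotypes.items()}

    def max_frequency(self) -> float:
        return max(c.frequency for c in self.clonotypes.values())


def _parse_bool(value: str) -> bool:
    v = value.strip().upper()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise ValueError(f"unparseable boolean {value!r}")


def read_rearrangements(path: str | Path) -> list[RearrangementRecord]:
    """Read a rearrangement TSV into records.

    Mandatory columns: ``junction`` and ``productive``; ``duplicate_count``
    defaults to 1 when absent.  Non-productive rows are retained (flagged via
    ``productive=False``).  Malformed rows (bad junction alphabet, unparseable
    booleans or counts) are skipped with a warning listing their line numbers.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty input file: {path}") from None
    if table.empty:
        raise EmptyInputError(f"no data rows in {path}")
    for column in ("junction", "productive"):
        if column not in table.columns:
            raise MissingColumnError(column, str(path))
    has = table.columns.__contains__

    records: list[RearrangementRecord] = []
    bad_lines: list[tuple[int, str]] = []
    for idx, row in enumerate(table.itertuples(index=False)):
        row = row._asdict()
        line_no = idx + 2  # 1-based, after the header line
        try:
            records.append(RearrangementRecord(
                sequence_id=row.get("sequence_id") or f"row{line_no}",
                junction_nt=row["junction"].strip().upper(),
                productive=_parse_bool(row["productive"]),
                duplicate_count=int(row["duplicate_count"]) if has("duplicate_count")
                and row["duplicate_count"].strip() else 1,
                v_call=row.get("v_call") or None,
                d_call=row.get("d_call") or None,
                j_call=row.get("j_call") or None,
                locus=row.get("locus") or "TRB",
                cell_id=row.get("cell_id") or None,
            ))
        except (ArgumentError, ValueError) as exc:
            bad_lines.append((line_no, str(exc)))
    if bad_lines:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad_lines)
        warnings.warn(f"{path}: rejected {len(bad_lines)} malformed row(s): {detail}",
                      stacklevel=2)
    return records


def write_rearrangements(records: Iterable[RearrangementRecord],
                         path: str | Path) -> None:
    """Write records as a rearrangement TSV (inverse of :func:`read_rearrangements`)."""
    rows = [{
        "sequence_id": r.sequence_id,
        "junction": r.junction_nt,
        "v_call": r.v_call or "",
        "d_call": r.d_call or "",
        "j_call": r.j_call or "",
        "productive": "T" if r.productive else "F",
        "duplicate_count": r.duplicate_count,
        "locus": r.locus,
        "cell_id": r.cell_id or "",
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def clonotype_key(record: RearrangementRecord, key_mode: str) -> str:
    """Clonotype identity of a record: the junction alone, or junction plus
    allele-stripped V/J context (``junction_vj``)."""
    if key_mode == "junction_only":
        return record.junction_nt
    if key_mode == "junction_vj":
        return "|".join((record.junction_nt,
                         strip_allele(record.v_call) or "",
                         strip_allele(record.j_call) or ""))
    raise ArgumentError(f"unknown key_mode {key_mode!r}")


def aggregate_clonotypes(records: Iterable[RearrangementRecord],
                         key_mode: str = "junction_only",
                         **metadata) -> Repertoire:
    """Collapse productive records into a clonotype frequency table.

    Only productive (in-frame) records contribute.  Counts are summed per
    clonotype key and frequencies normalised to 1.  Total productive read
    count is conserved: the clonotype counts sum to the duplicate counts of
    the productive records.
    """
    counts: dict[str, int] = {}
    for record in records:
        if not record.productive:
            continue
        key = clonotype_key(record, key_mode)
        counts[key] = counts.get(key, 0) + record.duplicate_count
    if not counts:
        raise EmptyRepertoireError("no productive records to aggregate")
    total = sum(counts.values())
    clonotypes = {k: Clonotype(k, n, n / total) for k, n in sorted(counts.items())}
    return Repertoire(clonotypes=clonotypes, key_mode=key_mode, **metadata)


def repertoire_to_records(rep: Repertoire) -> list[RearrangementRecord]:
    """Flatten a clonotype table back into one productive record per clonotype.

    With ``junction_only`` keys the round trip through
    :func:`write_rearrangements` / :func:`read_rearrangements` /
    :func:`aggregate_clonotypes` reproduces the clonotype table exactly.
    """
    records = []
    for i, (key, clone) in enumerate(sorted(rep.clonotypes.items())):
        junction = key.split("|", 1)[0]
        parts = key.split("|")
        records.append(RearrangementRecord(
            sequence_id=f"{rep.sample_id or 'rep'}-{i}",
            junction_nt=junction,
            productive=True,
            duplicate_count=clone.count,
            v_call=parts[1] if len(parts) == 3 and parts[1] else None,
            j_call=parts[2] if len(parts) == 3 and parts[2] else None,
        ))
    return records


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Write the clonotype table as TSV with columns key, count, frequency."""
    spectrum = frequency_spectrum(rep)
    rows = [{"key": k, "count": rep.clonotypes[k].count, "frequency": f}
            for k, f in spectrum]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def frequency_spectrum(rep: Repertoire) -> list[tuple[str, float]]:
    """Clonotypes ordered by decreasing frequency (lexicographic tie-break)."""
    return sorted(((k, c.frequency) for k, c in rep.clonotypes.items()),
                  key=lambda kv: (-kv[1], kv[0]))


def fraction_above(rep: Repertoire, threshold: float) -> float:
    """Summed frequency of clonotypes expanded above ``threshold``.

    The study's headline use is threshold 0.01: the repertoire mass carried by
    clonotypes individually above 1%.
    """
    if not 0.0 < threshold < 1.0:
        raise ArgumentError("threshold must lie strictly between 0 and 1")
    return sum(c.frequency for c in rep.clonotypes.values()
               if c.frequency > threshold)


def frequency_histogram(rep: Repertoire) -> list[tuple[float, int]]:
    """Group clonotypes with identical counts (hence identical frequencies).

    Returns (frequency, number of clonotypes at that frequency) sorted by
    decreasing frequency; the group sizes sum to the clonotype total.
    """
    groups: dict[int, int] = {}
    for clone in rep.clonotypes.values():
        groups[clone.count] = groups.get(clone.count, 0) + 1
    total = rep.total_count
    return [(count / total, n)
            for count, n in sorted(groups.items(), reverse=True)]
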