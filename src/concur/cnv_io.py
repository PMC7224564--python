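"""Reading, validating and filtering CNV call data in PLINK ``.cnv`` format.

A PLINK ``.cnv`` file is whitespace-delimited with header
``FID IID CHR BP1 BP2 TYPE SCORE SITES`` (SCORE/SITES optional).  The TYPE
column carries the copy number: an integer dosage (0, 1, 3, 4, ...), a
continuous intensity-derived dosage, or a categorical ``DUP``/``DEL`` code.
Samples are identified by ``FID_IID``.  Samples that carry no CNV at all are
legal and analytically meaningful (they anchor the zero profile curve); since
a ``.cnv`` file cannot list them, they are declared through a roster file
(one sample id per line).

Only autosomes 1-22 are analysed; records on X, Y or MT are dropped with a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DosageMode",
    "CNVRecord",
    "CNVDataset",
    "RegionSet",
    "read_plink_cnv",
    "write_plink_cnv",
    "read_roster",
    "read_regions",
    "classify_event",
    "subset_by_regions",
]

AUTOSOMES = frozenset(range(1, 23))

#: Event-type labels.
DUP: str = "DUP"
DEL: str = "DEL"
NORMAL: str = "NORMAL"


@dataclass(frozen=True)
class DosageMode:
    """How dosage values in the TYPE column are interpreted.

    ``integer`` mode calls > 2 a duplication and < 2 a deletion.
    ``continuous`` mode uses platform calling thresholds (defaults: copy
    number >= 2.3 is a duplication, <= 1.7 a deletion; values in between are
    treated as normal diploid).  ``categorical`` mode expects literal
    ``DUP``/``DEL`` codes (numeric values are binarized by the integer rule).
    ``exponent_c`` is the exponent of the dosage transform |d - 2|^c.
    """

    kind: Literal["categorical", "integer", "continuous"] = "integer"
    dup_threshold: float = 2.3
    del_threshold: float = 1.7
    exponent_c: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "integer", "continuous"):
            raise ValueError(f"unknown dosage mode kind: {self.kind!r}")
        if not (self.del_threshold < 2.0 < self.dup_threshold):
            raise ValueError(
                "thresholds must bracket the diploid value: "
                f"del={self.del_threshold}, dup={self.dup_threshold}"
            )
        if self.exponent_c < 0:
            raise ValueError("exponent_c must be non-negative")


@dataclass(frozen=True)
class CNVRecord:
    """One CNV event: a genomic interval [bp1, bp2) with a copy-number value.

    Intervals are half-open, so event length is ``bp2 - bp1``.  ``dosage``
    is a non-negative number, or the string ``"DUP"``/``"DEL"`` in
    categorical data.
    """

    sample_id: str
    chrom: int
    bp1: int
    bp2: int
    dosage: float | str

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"chrom must be an autosome 1-22, got {self.chrom}")
        if self.bp2 <= self.bp1:
            raise ValueError(
                f"bp2 must exceed bp1, got [{self.bp1}, {self.bp2}) "
                f"for sample {self.sample_id}"
            )
        if isinstance(self.dosage, str):
            if self.dosage not in (DUP, DEL):
                raise ValueError(f"unknown categorical dosage code: {self.dosage!r}")
        elif self.dosage < 0:
            raise ValueError(f"dosage must be non-negative, got {self.dosage}")

    @property
    def length(self) -> int:
        return self.bp2 - self.bp1


_FRAME_COLUMNS = ["sample_id", "chrom", "bp1", "bp2", "dosage"]


@dataclass
class CNVDataset:
    """All CNV events of a study sample plus the roster of analysed samples.

    The roster is an ordered list of unique sample ids; it fixes the row and
    column order of every kernel matrix built from the dataset and may
    contain samples with zero events.
    """

    records: list[CNVRecord]
    roster: list[str]
    mode: DosageMode = field(default_factory=DosageMode)

    def __post_init__(self) -> None:
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("roster contains duplicate sample ids")
        known = set(self.roster)
        for rec in self.records:
            if rec.sample_id not in known:
                raise ValueError(
                    f"record sample {rec.sample_id!r} is not in the roster"
                )

    def __len__(self) -> int:
        return len(self.roster)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame (columns sample_id, chrom, bp1, bp2, dosage)."""
        if not self.records:
            return pd.DataFrame(columns=_FRAME_COLUMNS)
        return pd.DataFrame(
            [(r.sample_id, r.chrom, r.bp1, r.bp2, r.dosage) for r in self.records],
            columns=_FRAME_COLUMNS,
        )

    def events_by_sample(self) -> dict[str, list[CNVRecord]]:
        out: dict[str, list[CNVRecord]] = {s: [] for s in self.roster}
        for rec in self.records:
            out[rec.sample_id].append(rec)
        return out

    def subset_samples(self, sample_ids: Sequence[str]) -> "CNVDataset":
        """Restrict to the given samples (order defines the new roster)."""
        keep = set(sample_ids)
        missing = keep - set(self.roster)
        if missing:
            raise KeyError(f"samples not in roster: {sorted(missing)[:5]}")
        recs = [r for r in self.records if r.sample_id in keep]
        return CNVDataset(recs, list(sample_ids), self.mode)


@dataclass
class RegionSet:
    """A named collection of genomic intervals (1-based, half-open).

    Intervals may overlap; they are unioned per chromosome before use.
    """

    name: str
    intervals: list[tuple[int, int, int]]  # (chrom, start, end)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if chrom not in AUTOSOMES:
                raise ValueError(f"region chrom must be an autosome, got {chrom}")
            if end <= start:
                raise ValueError(f"region end must exceed start: ({start}, {end})")

    def merged(self) -> dict[int, list[tuple[int, int]]]:
        """Per-chromosome union of intervals, sorted and disjoint."""
        by_chrom: dict[int, list[tuple[int, int]]] = {}
        for chrom, s, e in sorted(self.intervals):
            ivs = by_chrom.setdefault(chrom, [])
            if ivs and s <= ivs[-1][1]:
                ivs[-1] = (ivs[-1][0], max(ivs[-1][1], e))
            else:
                ivs.append((s, e))
        return by_chrom


def classify_event(dosage: float | str, mode: DosageMode) -> str:
    """Classify a dosage as DUP, DEL or NORMAL under the given mode.

    Integer mode: > 2 is DUP, < 2 is DEL, exactly 2 is NORMAL.  Continuous
    mode applies the calling thresholds (>= dup_threshold is DUP,
    <= del_threshold is DEL).  Categorical mode passes stored codes through
    and binarizes numeric values by the integer rule.
    """
    if isinstance(dosage, str):
        if dosage in (DUP, DEL):
            return dosage
        raise ValueError(f"unknown categorical dosage code: {dosage!r}")
    if dosage < 0:
        raise ValueError("dosage must be non-negative")
    if mode.kind == "continuous":
        if dosage >= mode.dup_threshold:
            return DUP
        if dosage <= mode.del_threshold:
            return DEL
        return NORMAL
    # integer rule, also used to binarize numeric values in categorical mode
    if dosage > 2:
        return DUP
    if dosage < 2:
        return DEL
    return NORMAL


def _parse_dosage(token: str, mode: DosageMode, lineno: int) -> float | str:
    if mode.kind == "categorical":
        up = token.upper()
        if up in (DUP, DEL):
            return up
        try:
            value = float(token)
        except ValueError:
            raise ValueError(
                f"line {lineno}: unknown TYPE code {token!r} in categorical mode"
            ) from None
        return value
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"line {lineno}: malformed numeric TYPE field {token!r}") from None


_SEX_CHROMS = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}


def read_plink_cnv(
    path: str | Path,
    mode: DosageMode | None = None,
    roster_path: str | Path | None = None,
) -> CNVDataset:
    """Read a PLINK ``.cnv`` file into a :class:`CNVDataset`.

    The roster is the unique ``FID_IID`` pairs in file order; a roster file
    (one id per line) may extend it with zero-CNV samples.  Non-autosomal
    records are dropped with a logged warning.
    """
    mode = mode or DosageMode()
    path = Path(path)
    records: list[CNVRecord] = []
    roster: list[str] = []
    seen: set[str] = set()
    n_dropped = 0

    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 6 or [c.upper() for c in header[:6]] != [
            "FID", "IID", "CHR", "BP1", "BP2", "TYPE",
        ]:
            raise ValueError(
                f"{path}: expected header 'FID IID CHR BP1 BP2 TYPE [SCORE SITES]', "
                f"got {' '.join(header)!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 fields")
            fid, iid, chrom_s, bp1_s, bp2_s, type_s = fields[:6]
            # FID and IID are joined with "_"; when they coincide the bare id
            # is used so that writer output round-trips
            sample_id = iid if fid == iid else f"{fid}_{iid}"
            chrom_key = chrom_s.upper().removeprefix("CHR")
            if chrom_key in _SEX_CHROMS:
                n_dropped += 1
                if sample_id not in seen:
                    seen.add(sample_id)
                    roster.append(sample_id)
                continue
            try:
                chrom = int(chrom_key)
                bp1 = int(bp1_s)
                bp2 = int(bp2_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: malformed numeric field"
                ) from None
            if chrom not in AUTOSOMES:
                n_dropped += 1
                if sample_id not in seen:
                    seen.add(sample_id)
                    roster.append(sample_id)
                continue
            if bp2 <= bp1:
                raise ValueError(
                    f"{path}: line {lineno}: BP2 ({bp2}) must exceed BP1 ({bp1})"
                )
            dosage = _parse_dosage(type_s, mode, lineno)
            if sample_id not in seen:
                seen.add(sample_id)
                roster.append(sample_id)
            records.append(CNVRecord(sample_id, chrom, bp1, bp2, dosage))

    if n_dropped:
        logger.warning(
            "%s: dropped %d non-autosomal record(s); only chromosomes 1-22 "
            "are analysed", path, n_dropped,
        )
    if roster_path is not None:
        for sid in read_roster(roster_path):
            if sid not in seen:
                seen.add(sid)
                roster.append(sid)
    return CNVDataset(records, roster, mode)


def read_roster(path: str | Path) -> list[str]:
    """Read a roster file: one sample id per line, '#' comments allowed."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            sid = line.strip()
            if sid and not sid.startswith("#"):
                out.append(sid)
    return out


def write_plink_cnv(
    dataset: CNVDataset,
    path: str | Path,
    roster_path: str | Path | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a dataset back to PLINK ``.cnv`` dialect.

    Sample ids are split at the first underscore into FID and IID (ids
    without an underscore get FID == IID).  SCORE and SITES are emitted as 0
    and 1.  If ``roster_path`` is given, the full roster (including zero-CNV
    samples) is written there.
    """
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        fh.write("FID IID CHR BP1 BP2 TYPE SCORE SITES\n")
        for rec in dataset.records:
            fid, _, iid = rec.sample_id.partition("_")
            iid = iid or fid
            dosage = rec.dosage
            if isinstance(dosage, float) and dosage.is_integer():
                dosage = int(dosage)
            fh.write(f"{fid} {iid} {rec.chrom} {rec.bp1} {rec.bp2} {dosage} 0 1\n")
    if roster_path is not None:
        with open(roster_path, "w") as fh:
            fh.write("\n".join(dataset.roster) + "\n")


def read_regions(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a region file: BED (3+ columns, 0-based half-open) or a 4-column
    named-interval TSV (name, chrom, start, end; 1-based).

    The format is sniffed from the first data line: a leading non-numeric
    first column with 4 fields means named-interval TSV.  Coordinates are
    converted to the internal 1-based half-open convention.
    """
    path = Path(path)
    intervals: list[tuple[int, int, int]] = []
    names: set[str] = set()
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track", "browser")):
                continue
            if len(fields) >= 4 and not fields[0].upper().removeprefix("CHR").isdigit():
                # named-interval TSV: name chrom start end (1-based, closed start)
                rname, chrom_s, start_s, end_s = fields[:4]
                names.add(rname)
                chrom = int(chrom_s.upper().removeprefix("CHR"))
                intervals.append((chrom, int(start_s), int(end_s) + 1))
            else:
                chrom_s, start_s, end_s = fields[:3]
                chrom = int(chrom_s.upper().removeprefix("CHR"))
                # BED 0-based half-open -> 1-based half-open
                intervals.append((chrom, int(start_s) + 1, int(end_s) + 1))
    if name is None:
        name = "+".join(sorted(names)) if names else path.stem
    return RegionSet(name, intervals)


def subset_by_regions(
    dataset: CNVDataset, regions: RegionSet, clip: bool = False
) -> CNVDataset:
    """Keep records overlapping the region union by at least one basepair.

    With ``clip`` set, records are truncated to the intersection with the
    merged region union; a record spanning several disjoint merged intervals
    yields one clipped record per intersected interval.  The roster is
    unchanged, so zero-CNV samples are retained.
    """
    if not regions.intervals:
        raise ValueError("empty RegionSet")
    merged = regions.merged()
    out: list[CNVRecord] = []
    for rec in dataset.records:
        for start, end in merged.get(rec.chrom, ()):
            lo, hi = max(rec.bp1, start), min(rec.bp2, end)
            if hi > lo:  # >= 1 bp overlap
                if clip:
                    out.append(replace(rec, bp1=lo, bp2=hi))
                else:
                    out.append(rec)
                    break
    return CNVDataset(out, list(dataset.roster), dataset.mode)
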