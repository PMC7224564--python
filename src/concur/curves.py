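"""Per-individual copy-number profile curves.

For individual *i* and chromosome *k*, the duplication profile curve
``f_ik^Dup(x)`` is the sum over that individual's duplication events of
``a_Dup(d_q)`` on the event interval ``[bp1_q, bp2_q)``, where
``a_Dup(d) = |d - 2|^c`` for duplications and 0 otherwise; the deletion
curve is defined analogously.  Curves are exactly piecewise constant,
non-negative and finitely supported; no smoothing is applied.

Intervals are half-open so single boundary points carry no area: this is a
measure-zero difference from a closed-indicator convention and cannot change
any common-area value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .cnv_io import DEL, DUP, CNVDataset, DosageMode, classify_event

__all__ = ["DosageTransform", "ProfileCurve", "dosage_amplitude", "build_profile_curves"]


@dataclass(frozen=True)
class DosageTransform:
    """Dosage transform ``a(d) = |d - 2|^c`` mapping copy number to curve
    amplitude, with amplitude 1 for categorical DUP/DEL codes.

    ``c < 1`` down-weights and ``c > 1`` up-weights high-magnitude events;
    ``c = 0`` reduces curves to event-presence indicators.
    """

    exponent_c: float = 1.0
    mode: DosageMode = DosageMode()

    def __post_init__(self) -> None:
        if self.exponent_c < 0:
            raise ValueError("exponent_c must be non-negative")

    @classmethod
    def from_mode(cls, mode: DosageMode) -> "DosageTransform":
        return cls(exponent_c=mode.exponent_c, mode=mode)


def dosage_amplitude(
    dosage: float | str, event_type: str, transform: DosageTransform
) -> float:
    """Amplitude contributed to the ``event_type`` curve by an event.

    Returns ``|d - 2|^c`` when the event's own type (resolved through the
    transform's dosage mode) matches ``event_type``, else 0.  Categorical
    DUP/DEL codes carry amplitude 1.
    """
    if event_type not in (DUP, DEL):
        raise ValueError(f"event_type must be DUP or DEL, got {event_type!r}")
    own_type = classify_event(dosage, transform.mode)
    if own_type != event_type:
        return 0.0
    if isinstance(dosage, str) or transform.mode.kind == "categorical":
        return 1.0
    return float(abs(dosage - 2.0) ** transform.exponent_c)


class ProfileCurve:
    """A canonical piecewise-constant step function on genomic coordinates.

    ``breakpoints`` is a strictly increasing integer array; ``values[t]`` is
    the (non-negative) curve value on ``[breakpoints[t], breakpoints[t+1])``.
    The curve is 0 outside ``[breakpoints[0], breakpoints[-1])``.  Adjacent
    intervals of equal value are merged and zero-valued flanks trimmed, so
    two curves are equal iff their arrays are equal.
    """

    __slots__ = ("breakpoints", "values")

    def __init__(self, breakpoints: Iterable[int], values: Iterable[float]):
        bp = np.asarray(list(breakpoints), dtype=np.int64)
        vals = np.asarray(list(values), dtype=float)
        if bp.size != vals.size + 1 and not (bp.size == 0 and vals.size == 0):
            raise ValueError("need len(breakpoints) == len(values) + 1")
        if bp.size and np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("curve values must be non-negative")
        self.breakpoints, self.values = _canonicalize(bp, vals)

    @classmethod
    def zero(cls) -> "ProfileCurve":
        return cls([], [])

    @classmethod
    def from_events(
        cls,
        starts: Iterable[int],
        ends: Iterable[int],
        amplitudes: Iterable[float],
    ) -> "ProfileCurve":
        """Pointwise sum of ``amp * 1[start, end)`` over events."""
        starts = np.asarray(list(starts), dtype=np.int64)
        ends = np.asarray(list(ends), dtype=np.int64)
        amps = np.asarray(list(amplitudes), dtype=float)
        keep = amps != 0
        starts, ends, amps = starts[keep], ends[keep], amps[keep]
        if starts.size == 0:
            return cls.zero()
        cuts = np.unique(np.concatenate([starts, ends]))
        # accumulate +amp at start, -amp at end, cumulative sum over cuts
        delta = np.zeros(cuts.size, dtype=float)
        np.add.at(delta, np.searchsorted(cuts, starts), amps)
        np.add.at(delta, np.searchsorted(cuts, ends), -amps)
        values = np.cumsum(delta)[:-1]
        return cls(cuts, values)

    @property
    def is_zero(self) -> bool:
        return self.values.size == 0

    def area(self) -> float:
        """Total area under the curve (value x interval length, in bp)."""
        if self.is_zero:
            return 0.0
        return float(np.dot(self.values, np.diff(self.breakpoints)))

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        """Evaluate the curve at position(s) x."""
        x = np.asarray(x)
        if self.is_zero:
            return np.zeros(x.shape)
        idx = np.searchsorted(self.breakpoints, x, side="right") - 1
        inside = (idx >= 0) & (idx < self.values.size)
        out = np.zeros(x.shape)
        out[inside] = self.values[np.clip(idx, 0, self.values.size - 1)][inside]
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileCurve):
            return NotImplemented
        return np.array_equal(self.breakpoints, other.breakpoints) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):  # pragma: no cover - curves are not hashed
        return hash((self.breakpoints.tobytes(), self.values.tobytes()))

    def __repr__(self) -> str:
        if self.is_zero:
            return "ProfileCurve(zero)"
        segs = ", ".join(
            f"[{a},{b}):{v:g}"
            for a, b, v in zip(self.breakpoints[:-1], self.breakpoints[1:], self.values)
        )
        return f"ProfileCurve({segs})"


def _canonicalize(bp: np.ndarray, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge equal-valued adjacent intervals; trim zero flanks and interiors
    that reduce to nothing."""
    if vals.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=float)
    keep = np.ones(vals.size, dtype=bool)
    keep[1:] = vals[1:] != vals[:-1]
    starts = bp[:-1][keep]
    values = vals[keep]
    # run t extends to the start of the next kept run (or the final breakpoint)
    ends = np.append(starts[1:], bp[-1])
    nz = values != 0
    if not nz.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=float)
    return _assemble(starts[nz], ends[nz], values[nz])


def _assemble(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    out_bp: list[int] = [int(starts[0])]
    out_vals: list[float] = []
    for s, e, v in zip(starts, ends, values):
        if int(s) != out_bp[-1]:
            out_vals.append(0.0)
            out_bp.append(int(s))
        out_vals.append(float(v))
        out_bp.append(int(e))
    return np.asarray(out_bp, dtype=np.int64), np.asarray(out_vals, dtype=float)


# keyed by (sample_id, chrom, event_type)
CurveMap = dict[tuple[str, int, str], ProfileCurve]


def build_profile_curves(dataset: CNVDataset, transform: DosageTransform) -> CurveMap:
    """Duplication and deletion profile curves for every sample/chromosome.

    Same-sample overlapping events of the same type sum pointwise.  Only
    non-zero curves are stored; missing keys denote the identically-zero
    curve (use ``.get(key, ProfileCurve.zero())``).  A sample carrying
    overlapping DUP and DEL events triggers a data-quality warning but is
    processed normally (the two event types live on separate curves).
    """
    groups: dict[tuple[str, int, str], list[tuple[int, int, float]]] = {}
    for rec in dataset.records:
        etype = classify_event(rec.dosage, transform.mode)
        if etype not in (DUP, DEL):
            continue
        amp = dosage_amplitude(rec.dosage, etype, transform)
        groups.setdefault((rec.sample_id, rec.chrom, etype), []).append(
            (rec.bp1, rec.bp2, amp)
        )

    _warn_mixed_overlaps(groups)

    out: CurveMap = {}
    for key, events in groups.items():
        starts, ends, amps = zip(*events)
        curve = ProfileCurve.from_events(starts, ends, amps)
        if not curve.is_zero:
            out[key] = curve
    return out


def _warn_mixed_overlaps(
    groups: Mapping[tuple[str, int, str], list[tuple[int, int, float]]]
) -> None:
    import logging

    logger = logging.getLogger(__name__)
    for (sid, chrom, etype) in list(groups):
        if etype != DUP:
            continue
        dels = groups.get((sid, chrom, DEL))
        if not dels:
            continue
        dups = groups[(sid, chrom, DUP)]
        for s1, e1, _ in dups:
            if any(s1 < e2 and s2 < e1 for s2, e2, _ in dels):
                logger.warning(
                    "sample %s chr%d carries overlapping DUP and DEL events; "
                    "they are kept on separate curves", sid, chrom,
                )
                break


def write_bedgraph(curves: CurveMap, directory: str | Path) -> list[Path]:
    """Export curves as one BedGraph track file per (sample, event type).

    Coordinates are converted to BedGraph's 0-based half-open convention.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_track: dict[tuple[str, str], list[tuple[int, ProfileCurve]]] = {}
    for (sid, chrom, etype), curve in sorted(curves.items()):
        by_track.setdefault((sid, etype), []).append((chrom, curve))
    written = []
    for (sid, etype), tracks in by_track.items():
        path = directory / f"{sid}.{etype.lower()}.bedgraph"
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{sid} {etype}"\n')
            for chrom, curve in tracks:
                for a, b, v in zip(
                    curve.breakpoints[:-1], curve.breakpoints[1:], curve.values
                ):
                    if v != 0:
                        fh.write(f"chr{chrom}\t{a - 1}\t{b - 1}\t{v:g}\n")
        written.append(path)
    return written
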