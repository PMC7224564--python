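"""The common-area-under-the-curve (cAUC) similarity kernel.

The cAUC between individuals i and j is

    k(Z_i, Z_j) = sum over chromosomes k of
                  integral of min(f_ik^Dup, f_jk^Dup) + min(f_ik^Del, f_jk^Del)

with respect to the counting measure over basepair positions.  With
half-open event intervals this is exact length arithmetic: each elementary
interval contributes (length in bp) x min of the two curve values.  The
kernel is symmetric and positive semi-definite, and it satisfies
``K[i,j] <= min(K[i,i], K[j,j])`` because the minimum of two curves is
dominated by either curve.

Two computation paths are provided and cross-checked in the test suite:
:func:`cauc_pair` sweeps the merged breakpoints of one pair of samples,
while :func:`cauc_matrix` decomposes the data into elementary segments (cut
at every event endpoint, per chromosome and event type) and accumulates
per-segment pairwise minima over the segment's carriers, which is fast when
CNVs are rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cnv_io import DEL, DUP, CNVDataset, classify_event
from .curves import CurveMap, DosageTransform, ProfileCurve, dosage_amplitude

__all__ = [
    "KernelMatrix",
    "KernelReport",
    "cauc_pair",
    "cauc_matrix",
    "validate_kernel",
    "sample_curves",
]

#: relative eigenvalue tolerance for the PSD check
PSD_RTOL = 1e-8


@dataclass
class KernelMatrix:
    """An n x n cAUC similarity matrix with its sample order."""

    values: np.ndarray
    sample_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_order)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match "
                f"{n} samples"
            )

    @property
    def n(self) -> int:
        return len(self.sample_order)

    def reindex(self, sample_ids: list[str]) -> "KernelMatrix":
        """Reorder/subset rows and columns to the given sample ids."""
        pos = {s: i for i, s in enumerate(self.sample_order)}
        try:
            idx = np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"sample {err.args[0]!r} not in kernel") from None
        return KernelMatrix(self.values[np.ix_(idx, idx)], list(sample_ids))

    def to_tsv(self, path: str | Path) -> None:
        """Write as square TSV with a header row/index of sample ids."""
        pd.DataFrame(
            self.values, index=self.sample_order, columns=self.sample_order
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KernelMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("kernel TSV must be square with matching ids")
        return cls(df.to_numpy(dtype=float), [str(s) for s in df.columns])


def sample_curves(
    dataset: CNVDataset, transform: DosageTransform
) -> dict[str, dict[tuple[int, str], ProfileCurve]]:
    """Group profile curves by sample for pairwise use: sample id ->
    {(chrom, type): curve}."""
    from .curves import build_profile_curves

    curves = build_profile_curves(dataset, transform)
    out: dict[str, dict[tuple[int, str], ProfileCurve]] = {
        s: {} for s in dataset.roster
    }
    for (sid, chrom, etype), curve in curves.items():
        out[sid][(chrom, etype)] = curve
    return out


def _min_integral(a: ProfileCurve, b: ProfileCurve) -> float:
    """Integral of min(a, b) by a sweep over the merged breakpoints."""
    if a.is_zero or b.is_zero:
        return 0.0
    # quick reject: disjoint supports
    if a.breakpoints[-1] <= b.breakpoints[0] or b.breakpoints[-1] <= a.breakpoints[0]:
        return 0.0
    cuts = np.union1d(a.breakpoints, b.breakpoints)
    mids = cuts[:-1]  # value on [cuts[t], cuts[t+1]) is the value at its start
    va = a(mids)
    vb = b(mids)
    return float(np.dot(np.minimum(va, vb), np.diff(cuts)))


def cauc_pair(
    curves_i: Mapping[tuple[int, str], ProfileCurve],
    curves_j: Mapping[tuple[int, str], ProfileCurve],
) -> float:
    """cAUC between two samples given their per-chromosome DUP/DEL curves.

    Both curve maps must come from the same dosage transform; chromosomes or
    types absent from a map denote the zero curve and contribute nothing.
    """
    total = 0.0
    shared = curves_i.keys() & curves_j.keys()
    for key in shared:
        total += _min_integral(curves_i[key], curves_j[key])
    return total


def _event_table(
    dataset: CNVDataset, transform: DosageTransform
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten records into arrays (sample index, chrom+type key, bp1, bp2,
    amplitude), dropping NORMAL calls and zero amplitudes."""
    pos = {s: i for i, s in enumerate(dataset.roster)}
    rows = []
    for rec in dataset.records:
        etype = classify_event(rec.dosage, transform.mode)
        if etype not in (DUP, DEL):
            continue
        amp = dosage_amplitude(rec.dosage, etype, transform)
        if amp == 0.0:
            continue
        key = rec.chrom * 2 + (0 if etype == DUP else 1)
        rows.append((pos[rec.sample_id], key, rec.bp1, rec.bp2, amp))
    if not rows:
        empty_i = np.empty(0, dtype=np.int64)
        return empty_i, empty_i, empty_i, empty_i, np.empty(0)
    return (
        np.array([r[0] for r in rows], dtype=np.int64),
        np.array([r[1] for r in rows], dtype=np.int64),
        np.array([r[2] for r in rows], dtype=np.int64),
        np.array([r[3] for r in rows], dtype=np.int64),
        np.array([r[4] for r in rows], dtype=float),
    )


def cauc_matrix(dataset: CNVDataset, transform: DosageTransform) -> KernelMatrix:
    """Assemble the full n x n cAUC kernel for a dataset.

    Events are cut into elementary segments at every distinct endpoint
    (per chromosome and event type); within a segment each carrier has one
    constant summed amplitude, so the segment contributes
    ``length x min(a_i, a_j)`` to every carrier pair and ``length x a_i`` to
    each carrier's diagonal.  Zero-CNV samples yield all-zero rows and
    columns, diagonal included.
    """
    n = len(dataset.roster)
    K = np.zeros((n, n))
    samp, key, bp1, bp2, amp = _event_table(dataset, transform)
    if samp.size == 0:
        return KernelMatrix(K, list(dataset.roster))

    order = np.lexsort((bp1, key))
    samp, key, bp1, bp2, amp = (a[order] for a in (samp, key, bp1, bp2, amp))
    boundaries = np.flatnonzero(np.diff(key)) + 1
    for s0, s1 in zip(
        np.concatenate([[0], boundaries]), np.concatenate([boundaries, [samp.size]])
    ):
        _accumulate_group(
            K, samp[s0:s1], bp1[s0:s1], bp2[s0:s1], amp[s0:s1]
        )
    return KernelMatrix(K, list(dataset.roster))


def _accumulate_group(
    K: np.ndarray,
    samp: np.ndarray,
    bp1: np.ndarray,
    bp2: np.ndarray,
    amp: np.ndarray,
) -> None:
    """Add one chromosome/type group's contribution to K in place."""
    cuts = np.unique(np.concatenate([bp1, bp2]))
    seg_len = np.diff(cuts).astype(float)
    first = np.searchsorted(cuts, bp1)
    last = np.searchsorted(cuts, bp2)  # exclusive segment index

    # per-segment carrier amplitude: sample x segment sparse accumulation
    seg_events: dict[int, dict[int, float]] = {}
    for i in range(samp.size):
        s = int(samp[i])
        a = float(amp[i])
        for seg in range(first[i], last[i]):
            carriers = seg_events.setdefault(seg, {})
            carriers[s] = carriers.get(s, 0.0) + a

    for seg, carriers in seg_events.items():
        length = seg_len[seg]
        if len(carriers) == 1:
            ((s, a),) = carriers.items()
            K[s, s] += length * a
            continue
        idx = np.fromiter(carriers.keys(), dtype=np.int64, count=len(carriers))
        vals = np.fromiter(carriers.values(), dtype=float, count=len(carriers))
        K[np.ix_(idx, idx)] += length * np.minimum.outer(vals, vals)


@dataclass
class KernelReport:
    """Diagnostics from :func:`validate_kernel`."""

    symmetry_defect: float
    min_eigenvalue: float
    max_eigenvalue: float
    bound_violations: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_psd(self) -> bool:
        return self.min_eigenvalue >= -PSD_RTOL * max(self.max_eigenvalue, 0.0)

    @property
    def ok(self) -> bool:
        return self.symmetry_defect == 0.0 and self.is_psd and not self.bound_violations


def validate_kernel(K: KernelMatrix) -> KernelReport:
    """Check symmetry, positive semi-definiteness and the min-operator bound
    ``K[i,j] <= min(K[i,i], K[j,j])``; diagnostic only, never raises."""
    V = K.values
    defect = float(np.max(np.abs(V - V.T))) if K.n else 0.0
    eigs = np.linalg.eigvalsh((V + V.T) / 2.0) if K.n else np.array([0.0])
    diag = np.diag(V)
    cap = np.minimum.outer(diag, diag)
    tol = 1e-9 * max(float(np.max(np.abs(V))), 1.0)
    bad = np.argwhere(V > cap + tol)
    violations = [(int(i), int(j)) for i, j in bad if i != j]
    return KernelReport(
        symmetry_defect=defect,
        min_eigenvalue=float(eigs[0]),
        max_eigenvalue=float(eigs[-1]),
        bound_violations=violations,
    )
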