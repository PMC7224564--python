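"""Simulation framework for validating the CONCUR test.

The framework mirrors how rare-CNV association simulations are designed in
practice: the observed CNVs of a cohort are cut into *segments* at every
event endpoint (so within a segment each carrier has a constant dosage);
segment-level design matrices Z^Dup, Z^Del and Z^Len code presence/deviation
and segment length in kb; a subset of segments is declared causal with a
deleterious/protective sign mix; and a case-control phenotype is drawn from
the logistic model

    logit P(Y_i = 1) = gamma0 + betaX * X_i
                       + sum_j beta_j^Dup Z_ij^Dup + sum_j beta_j^Del Z_ij^Del
                       + sum_j beta_j^Len Z_ij^Len
                       + sum_j beta_j^Dup*Len Z_ij^Dup Z_ij^Len
                       + sum_j beta_j^Del*Len Z_ij^Del Z_ij^Len

with beta^Len fixed at 0 (length acts as an effect modifier of dosage, not
a main effect).  Defaults gamma0 = -2 and betaX = log(1.1) give a baseline
disease rate of roughly 0.12; gamma0 = -3 gives roughly 0.05.

Two synthetic cohort generators are provided: a TGP-style generator
(integer dosages in {0, 1, 3, 4}, per-locus carrier frequency below 1%,
event lengths above 100 kb, autosomes 1-22) and a TWB-style generator
(continuous dosages with duplications called at >= 2.3 and deletions at
<= 1.7).  They emulate the statistical structure of those cohorts, not the
cohorts themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from .cnv_io import DEL, DUP, CNVDataset, CNVRecord, DosageMode, classify_event

__all__ = [
    "SegmentTable",
    "DesignMatrices",
    "EffectConfig",
    "CausalAssignment",
    "TGPParams",
    "TWBParams",
    "build_segments",
    "design_matrices",
    "select_causal",
    "simulate_phenotype",
    "case_control_sample",
    "perturb_endpoints",
    "generate_tgp_like",
    "generate_twb_like",
]

#: approximate autosome lengths (bp, GRCh37 scale), chromosomes 1-22
CHROM_LENGTHS_BP: dict[int, int] = {
    1: 249_000_000, 2: 243_000_000, 3: 198_000_000, 4: 191_000_000,
    5: 181_000_000, 6: 171_000_000, 7: 159_000_000, 8: 146_000_000,
    9: 141_000_000, 10: 136_000_000, 11: 135_000_000, 12: 134_000_000,
    13: 115_000_000, 14: 107_000_000, 15: 103_000_000, 16: 90_000_000,
    17: 81_000_000, 18: 78_000_000, 19: 59_000_000, 20: 63_000_000,
    21: 48_000_000, 22: 51_000_000,
}


@dataclass
class SegmentTable:
    """CNV segments cut at every observed event endpoint.

    ``segments[j] = (chrom, start, end)``; ``carriers[j]`` maps sample id to
    ``(dup_deviation, del_deviation)`` where a deviation is |d - 2| of the
    carried event (0 when the sample has no event of that type in the
    segment).  Segments are disjoint, sorted, tile the union of observed
    intervals exactly, and each is covered by at least one event.
    """

    segments: list[tuple[int, int, int]]
    carriers: list[dict[str, tuple[float, float]]]
    roster: list[str]

    @property
    def R(self) -> int:
        return len(self.segments)

    def lengths_kb(self) -> np.ndarray:
        return np.array([(e - s) / 1000.0 for _, s, e in self.segments])

    def has_dup(self) -> np.ndarray:
        return np.array([any(d > 0 for d, _ in c.values()) for c in self.carriers])

    def has_del(self) -> np.ndarray:
        return np.array([any(d > 0 for _, d in c.values()) for c in self.carriers])


def build_segments(dataset: CNVDataset, chrom: int | None = None) -> SegmentTable:
    """Cut the union of CNV intervals at every distinct endpoint.

    When a sample carries several same-type events overlapping one segment,
    the largest dosage deviation is kept (dosage is constant within a
    segment by construction; stacked same-sample events are a data quirk).
    """
    records = [r for r in dataset.records if chrom is None or r.chrom == chrom]
    if not records:
        raise ValueError("no CNV records to segment" + (f" on chr{chrom}" if chrom else ""))
    segments: list[tuple[int, int, int]] = []
    carriers: list[dict[str, tuple[float, float]]] = []
    by_chrom: dict[int, list[CNVRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for ck in sorted(by_chrom):
        recs = by_chrom[ck]
        cuts = np.unique(
            np.concatenate([[r.bp1 for r in recs], [r.bp2 for r in recs]])
        )
        nseg = cuts.size - 1
        seg_carr: list[dict[str, tuple[float, float]]] = [dict() for _ in range(nseg)]
        for r in recs:
            etype = classify_event(r.dosage, dataset.mode)
            dev = (
                1.0
                if isinstance(r.dosage, str)
                else abs(float(r.dosage) - 2.0)
            )
            lo = int(np.searchsorted(cuts, r.bp1))
            hi = int(np.searchsorted(cuts, r.bp2))
            for j in range(lo, hi):
                dup_d, del_d = seg_carr[j].get(r.sample_id, (0.0, 0.0))
                if etype == DUP:
                    dup_d = max(dup_d, dev)
                elif etype == DEL:
                    del_d = max(del_d, dev)
                seg_carr[j][r.sample_id] = (dup_d, del_d)
        for j in range(nseg):
            if seg_carr[j]:
                segments.append((ck, int(cuts[j]), int(cuts[j + 1])))
                carriers.append(seg_carr[j])
    return SegmentTable(segments, carriers, list(dataset.roster))


@dataclass
class DesignMatrices:
    """Segment-level design matrices, n samples x R segments.

    Categorical coding puts 1 for presence of a duplication/deletion in the
    segment; continuous coding puts |d - 2|.  ``z_len`` is the segment
    length in kb for carriers (of either type) and 0 otherwise.
    """

    z_dup: np.ndarray
    z_del: np.ndarray
    z_len: np.ndarray
    sample_order: list[str]


def design_matrices(
    segments: SegmentTable, coding: Literal["categorical", "continuous"]
) -> DesignMatrices:
    if coding not in ("categorical", "continuous"):
        raise ValueError(f"unknown coding: {coding!r}")
    n, R = len(segments.roster), segments.R
    pos = {s: i for i, s in enumerate(segments.roster)}
    z_dup = np.zeros((n, R))
    z_del = np.zeros((n, R))
    z_len = np.zeros((n, R))
    len_kb = segments.lengths_kb()
    for j, carr in enumerate(segments.carriers):
        for sid, (dup_d, del_d) in carr.items():
            i = pos[sid]
            if dup_d > 0:
                z_dup[i, j] = 1.0 if coding == "categorical" else dup_d
            if del_d > 0:
                z_del[i, j] = 1.0 if coding == "categorical" else del_d
            z_len[i, j] = len_kb[j]
    return DesignMatrices(z_dup, z_del, z_len, list(segments.roster))


@dataclass
class CausalAssignment:
    """Indices of causal segments and their effect signs (+1 deleterious,
    -1 protective), separately for duplications and deletions."""

    dup_segments: np.ndarray
    dup_signs: np.ndarray
    del_segments: np.ndarray
    del_signs: np.ndarray


def select_causal(
    segments: SegmentTable,
    counts: tuple[int, int],
    dp_mix: tuple[float, float, float, float],
    length_floor: Literal["median_by_type", "none"] = "median_by_type",
    seed: int | np.random.Generator = 0,
) -> CausalAssignment:
    """Randomly pick causal segments and assign deleterious/protective signs.

    ``counts = (n_dup, n_del)`` segments are sampled without replacement
    among segments containing at least one event of the type; with the
    ``median_by_type`` floor, only segments at least as long as the median
    length of all segments of that type are eligible.  ``dp_mix`` gives
    (D_dup, P_dup, D_del, P_del) percentages; each type's pair must sum to
    100 (or both be 0 when that type has no causal segments).  Duplication
    and deletion causal sets may share locations.
    """
    rng = np.random.default_rng(seed)
    n_dup, n_del = counts
    d_dup, p_dup, d_del, p_del = dp_mix
    for label, n_c, (d, p) in (
        ("duplication", n_dup, (d_dup, p_dup)),
        ("deletion", n_del, (d_del, p_del)),
    ):
        if n_c > 0 and not math.isclose(d + p, 100.0):
            raise ValueError(f"{label} D/P percentages must sum to 100, got {d}+{p}")

    len_kb = segments.lengths_kb()

    def pick(mask: np.ndarray, n_c: int, d_pct: float, label: str):
        if n_c == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        eligible = np.flatnonzero(mask)
        if length_floor == "median_by_type" and eligible.size:
            floor = np.median(len_kb[mask])
            eligible = eligible[len_kb[eligible] >= floor]
        if eligible.size < n_c:
            raise ValueError(
                f"only {eligible.size} eligible {label} segments for "
                f"{n_c} requested causal segments"
            )
        chosen = rng.choice(eligible, size=n_c, replace=False)
        n_deleterious = int(round(n_c * d_pct / 100.0))
        signs = np.concatenate(
            [np.ones(n_deleterious, dtype=int), -np.ones(n_c - n_deleterious, dtype=int)]
        )
        rng.shuffle(signs)
        return chosen, signs

    dup_idx, dup_signs = pick(segments.has_dup(), n_dup, d_dup, "duplication")
    del_idx, del_signs = pick(segments.has_del(), n_del, d_del, "deletion")
    return CausalAssignment(dup_idx, dup_signs, del_idx, del_signs)


@dataclass
class EffectConfig:
    """Effect parameters of the logistic phenotype model.

    ``effect_size`` is the magnitude of the causal log-odds ratios: per
    carried segment for a ``dosage`` signal, per kb of carried segment for a
    ``dosage_x_length`` signal (Z^Len is coded in kb).  ``beta_len`` is
    fixed at 0; signs come from the causal assignment's D/P mix.
    """

    gamma0: float = -2.0
    beta_x: float = math.log(1.1)
    effect_size: float = 0.0
    signal: Literal["dosage", "dosage_x_length"] = "dosage_x_length"
    beta_len: float = 0.0


def linear_predictor(
    design: DesignMatrices,
    causal: CausalAssignment,
    config: EffectConfig,
    X: np.ndarray,
) -> np.ndarray:
    """Assemble the logistic model's linear predictor for given covariates."""
    eta = config.gamma0 + config.beta_x * X
    for idx, signs, Z in (
        (causal.dup_segments, causal.dup_signs, design.z_dup),
        (causal.del_segments, causal.del_signs, design.z_del),
    ):
        if idx.size == 0:
            continue
        beta = config.effect_size * signs
        if config.signal == "dosage_x_length":
            eta = eta + (Z[:, idx] * design.z_len[:, idx]) @ beta
        else:
            eta = eta + Z[:, idx] @ beta
    if config.beta_len != 0.0:
        eta = eta + config.beta_len * design.z_len.sum(axis=1)
    return eta


def simulate_phenotype(
    design: DesignMatrices,
    causal: CausalAssignment,
    config: EffectConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (Y, X): X ~ Bernoulli(0.5), Y ~ Bernoulli(expit(eta))."""
    rng = np.random.default_rng(seed)
    n = len(design.sample_order)
    X = rng.binomial(1, 0.5, size=n).astype(float)
    eta = linear_predictor(design, causal, config, X)
    Y = rng.binomial(1, expit(eta)).astype(float)
    return Y, X


def null_disease_rate(gamma0: float, beta_x: float = math.log(1.1)) -> float:
    """Population disease rate of the covariate-only model with
    X ~ Bernoulli(0.5): the average of expit(gamma0) and expit(gamma0 + betaX)."""
    return 0.5 * (expit(gamma0) + expit(gamma0 + beta_x))


def case_control_sample(
    Y: np.ndarray,
    n_case: int,
    n_control: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample exactly ``n_case`` cases and ``n_control`` controls without
    replacement from a simulated population; returns selected indices."""
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y)
    cases = np.flatnonzero(Y == 1)
    controls = np.flatnonzero(Y == 0)
    if cases.size < n_case or controls.size < n_control:
        raise ValueError(
            f"population has {cases.size} cases / {controls.size} controls; "
            f"need {n_case} / {n_control}"
        )
    sel_case = rng.choice(cases, size=n_case, replace=False) if n_case else np.empty(0, int)
    sel_ctrl = (
        rng.choice(controls, size=n_control, replace=False)
        if n_control
        else np.empty(0, int)
    )
    return np.sort(np.concatenate([sel_case, sel_ctrl]).astype(int))


def perturb_endpoints(
    dataset: CNVDataset,
    max_frac: float = 0.025,
    seed: int | np.random.Generator = 0,
) -> CNVDataset:
    """Add independent Uniform(-max_frac*L, +max_frac*L) errors to both
    endpoints of every event (L = event length), rounded to integer bp.

    Emulates endpoint-calling inaccuracy; draws that would invert an
    interval are resampled.  The perturbed copy is meant for kernel
    construction only — phenotypes should always come from the true data.
    """
    if not 0.0 <= max_frac < 0.5:
        raise ValueError("max_frac must lie in [0, 0.5)")
    if max_frac == 0.0:
        return CNVDataset(list(dataset.records), list(dataset.roster), dataset.mode)
    rng = np.random.default_rng(seed)
    out: list[CNVRecord] = []
    for rec in dataset.records:
        L = rec.length
        lim = max_frac * L
        for _ in range(100):
            b1 = rec.bp1 + int(round(rng.uniform(-lim, lim)))
            b2 = rec.bp2 + int(round(rng.uniform(-lim, lim)))
            if b2 > b1 >= 1:
                out.append(replace(rec, bp1=b1, bp2=b2))
                break
        else:  # pragma: no cover - max_frac < 0.5 makes inversion vanishing
            out.append(rec)
    return CNVDataset(out, list(dataset.roster), dataset.mode)


# ---------------------------------------------------------------------------
# synthetic cohort generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TGPParams:
    """Parameters of the TGP-style integer-dosage rare-CNV generator.

    Defaults emulate array-based rare-CNV callsets: ~400 recurrent loci
    across the 22 autosomes (placed proportionally to chromosome length),
    per-locus carrier frequency uniform on (0.002, 0.009) and capped below
    ``max_locus_freq``, event lengths log-uniform on (102 kb, 1 Mb), and
    integer dosages drawn as {1: 0.9, 0: 0.1} at deletion loci and
    {3: 0.9, 4: 0.1} at duplication loci.  Carrier endpoints are jittered
    around the locus centre so events at a locus overlap without
    coinciding.
    """

    n_loci: int = 300
    freq_range: tuple[float, float] = (0.002, 0.009)
    max_locus_freq: float = 0.01
    length_range: tuple[int, int] = (102_000, 1_000_000)
    dup_fraction: float = 0.45
    del_dosage_probs: tuple[tuple[float, float], ...] = ((1.0, 0.9), (0.0, 0.1))
    dup_dosage_probs: tuple[tuple[float, float], ...] = ((3.0, 0.9), (4.0, 0.1))
    chroms: tuple[int, ...] = tuple(range(1, 23))
    centre_jitter_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.length_range[0] >= self.length_range[1]:
            raise ValueError("min length must be below max length")
        if self.length_range[0] <= 100_000:
            raise ValueError("TGP-style events must exceed 100 kb")
        if not 0 < self.max_locus_freq <= 1:
            raise ValueError("max_locus_freq must lie in (0, 1]")


def _place_locus(
    rng: np.random.Generator,
    chrom: int,
    span: int,
    taken: dict[int, list[tuple[int, int]]],
    max_tries: int = 50,
) -> int | None:
    """Draw a locus centre so that loci on a chromosome do not overlap
    (recurrent CNV loci are distinct genomic sites); None when no free
    position is found."""
    occupied = taken.setdefault(chrom, [])
    hi = CHROM_LENGTHS_BP[chrom] - span
    for _ in range(max_tries):
        centre = int(rng.integers(span, hi))
        if all(abs(centre - c) >= 2 * span for c, _ in occupied):
            occupied.append((centre, span))
            return centre
    return None


def _draw_dosages(
    rng: np.random.Generator, probs: tuple[tuple[float, float], ...], size: int
) -> np.ndarray:
    values = np.array([v for v, _ in probs])
    p = np.array([w for _, w in probs], dtype=float)
    return values[rng.choice(len(values), size=size, p=p / p.sum())]


def generate_tgp_like(
    n_samples: int,
    params: TGPParams | None = None,
    seed: int | np.random.Generator = 0,
) -> CNVDataset:
    """Generate an integer-dosage rare-CNV cohort in the TGP style.

    Every emitted event is longer than 100 kb with dosage in {0, 1, 3, 4};
    per-locus carrier counts are capped below ``max_locus_freq`` of the
    cohort (for cohorts of at least ``1 / max_locus_freq`` samples; below
    that a single carrier is allowed so small test datasets are non-empty).
    """
    params = params or TGPParams()
    rng = np.random.default_rng(seed)
    roster = [f"S{i+1}" for i in range(n_samples)]
    records: list[CNVRecord] = []
    chrom_lens = np.array([CHROM_LENGTHS_BP[c] for c in params.chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    cap = max(1, int(np.floor(params.max_locus_freq * n_samples - 1e-9)))
    lo, hi = params.length_range
    span = int(0.6 * hi) + 1
    taken: dict[int, list[tuple[int, int]]] = {}

    for _ in range(params.n_loci):
        chrom = int(rng.choice(list(params.chroms), p=chrom_p))
        is_dup = rng.random() < params.dup_fraction
        freq = rng.uniform(*params.freq_range)
        m = min(int(rng.binomial(n_samples, freq)), cap)
        if m == 0:
            continue
        centre = _place_locus(rng, chrom, span, taken)
        if centre is None:
            continue
        carriers = rng.choice(n_samples, size=m, replace=False)
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m)).astype(np.int64)
        shifts = np.round(
            rng.uniform(-1, 1, size=m) * params.centre_jitter_frac * lengths
        ).astype(np.int64)
        bp1s = np.maximum(1, centre - lengths // 2 + shifts)
        dosages = _draw_dosages(
            rng, params.dup_dosage_probs if is_dup else params.del_dosage_probs, m
        )
        for s, b1, L, dd in zip(carriers, bp1s, lengths, dosages):
            records.append(
                CNVRecord(roster[int(s)], chrom, int(b1), int(b1 + L), float(dd))
            )
    return CNVDataset(records, roster, DosageMode("integer"))


@dataclass(frozen=True)
class TWBParams:
    """Parameters of the TWB-style continuous-dosage generator.

    Defaults emulate an intensity-derived chromosome-1 callset where most
    samples carry at least one event: 300 loci on chromosome 1, continuous
    deletion dosages uniform on (0.5, 1.7) and duplication dosages uniform
    on (2.3, 3.4) (the calling thresholds), lengths log-uniform on
    (20 kb, 800 kb).
    """

    n_loci: int = 250
    freq_range: tuple[float, float] = (0.001, 0.009)
    length_range: tuple[int, int] = (20_000, 800_000)
    dup_fraction: float = 0.4
    del_dosage_range: tuple[float, float] = (0.5, 1.7)
    dup_dosage_range: tuple[float, float] = (2.3, 3.4)
    chroms: tuple[int, ...] = (1,)
    centre_jitter_frac: float = 0.1
    dup_threshold: float = 2.3
    del_threshold: float = 1.7

    def __post_init__(self) -> None:
        if self.del_dosage_range[1] > self.del_threshold:
            raise ValueError(
                "deletion dosage range crosses the deletion calling threshold"
            )
        if self.dup_dosage_range[0] < self.dup_threshold:
            raise ValueError(
                "duplication dosage range crosses the duplication calling threshold"
            )
        if self.length_range[0] >= self.length_range[1]:
            raise ValueError("min length must be below max length")


def generate_twb_like(
    n_samples: int,
    params: TWBParams | None = None,
    seed: int | np.random.Generator = 0,
) -> CNVDataset:
    """Generate a continuous-dosage cohort in the TWB style: every emitted
    dosage is at or below the deletion threshold or at or above the
    duplication threshold."""
    params = params or TWBParams()
    rng = np.random.default_rng(seed)
    roster = [f"S{i+1}" for i in range(n_samples)]
    records: list[CNVRecord] = []
    chrom_lens = np.array([CHROM_LENGTHS_BP[c] for c in params.chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    lo, hi = params.length_range
    span = int(0.6 * hi) + 1

    for _ in range(params.n_loci):
        chrom = int(rng.choice(list(params.chroms), p=chrom_p))
        is_dup = rng.random() < params.dup_fraction
        freq = rng.uniform(*params.freq_range)
        m = int(rng.binomial(n_samples, freq))
        if m == 0:
            continue
        centre = int(rng.integers(span, CHROM_LENGTHS_BP[chrom] - span))
        carriers = rng.choice(n_samples, size=m, replace=False)
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m)).astype(np.int64)
        shifts = np.round(
            rng.uniform(-1, 1, size=m) * params.centre_jitter_frac * lengths
        ).astype(np.int64)
        bp1s = np.maximum(1, centre - lengths // 2 + shifts)
        d_lo, d_hi = params.dup_dosage_range if is_dup else params.del_dosage_range
        dosages = np.round(rng.uniform(d_lo, d_hi, size=m), 3)
        for s, b1, L, dd in zip(carriers, bp1s, lengths, dosages):
            records.append(
                CNVRecord(roster[int(s)], chrom, int(b1), int(b1 + L), float(dd))
            )
    return CNVDataset(
        records,
        roster,
        DosageMode(
            "continuous",
            dup_threshold=params.dup_threshold,
            del_threshold=params.del_threshold,
        ),
    )
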