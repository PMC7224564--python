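import numpy as np
import pytest

from concur.cnv_io import CNVDataset, CNVRecord, DosageMode


@pytest.fixture
def worked_example() -> CNVDataset:
    """The two-individual deletion example: S1 carries one deletion of
    dosage 0 on chr1:[200,400); S2 carries deletions of dosage 0 on
    [100,500) and dosage 1 on [600,800); S3 carries nothing."""
    records = [
        CNVRecord("S1", 1, 200, 400, 0.0),
        CNVRecord("S2", 1, 100, 500, 0.0),
        CNVRecord("S2", 1, 600, 800, 1.0),
    ]
    return CNVDataset(records, ["S1", "S2", "S3"], DosageMode("integer"))


def random_small_dataset(
    rng: np.random.Generator,
    n_samples: int = 2,
    max_records: int = 5,
    max_pos: int = 10_000,
    chroms: tuple[int, ...] = (1,),
) -> CNVDataset:
    """Random integer-dosage profiles with coordinates below ``max_pos``,
    suitable for the per-basepair brute-force oracle."""
    roster = [f"S{i}" for i in range(n_samples)]
    records = []
    for sid in roster:
        for _ in range(rng.integers(0, max_records + 1)):
            chrom = int(rng.choice(chroms))
            bp1 = int(rng.integers(1, max_pos - 1))
            bp2 = int(rng.integers(bp1 + 1, min(bp1 + 2000, max_pos) + 1))
            dosage = float(rng.choice([0, 1, 3, 4]))
            records.append(CNVRecord(sid, chrom, bp1, bp2, dosage))
    return CNVDataset(records, roster, DosageMode("integer"))


def brute_force_cauc(dataset: CNVDataset, transform, sid_i: str, sid_j: str,
                     max_pos: int = 10_000) -> float:
    """Per-basepair oracle: sum over integer positions of the pointwise
    minimum of the two samples' same-type curves (half-open intervals)."""
    from concur.cnv_io import DUP, DEL
    from concur.curves import build_profile_curves

    curves = build_profile_curves(dataset, transform)
    xs = np.arange(1, max_pos + 1)
    total = 0.0
    chroms = sorted({rec.chrom for rec in dataset.records})
    for chrom in chroms:
        for etype in (DUP, DEL):
            a = curves.get((sid_i, chrom, etype))
            b = curves.get((sid_j, chrom, etype))
            if a is None or b is None:
                continue
            total += float(np.sum(np.minimum(a(xs), b(xs))))
    return total
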