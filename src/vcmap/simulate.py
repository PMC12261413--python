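"""Synthetic genomes, barcoded read pairs with ground truth, and scoring.

The generator emulates the ingredients of a single-cell ATAC-seq mapping
experiment at desk scale: an i.i.d. uniform-composition genome with a
tunable family of diverged repeat copies, FR-oriented paired-end
fragments with i.i.d. substitution errors, cell barcodes drawn from a
generated permit list with injected single-base errors, optional
exact-copy fragment duplicates (to exercise deduplication counts) and
optional N-gaps (to exercise contig splitting).  Every record is written
alongside a ground-truth table so mapping accuracy is measurable at
single-base tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .fragments import FragmentRecord
from .refset import ReferenceSet, _open_text
from .io import write_fastq

_BASE_ARR = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass
class SimParams:
    """Synthetic-dataset knobs.

    Defaults describe a modest desk-scale experiment: a 100 kb repeat-free
    genome, 100-base reads from ~250 ± 50 base fragments, a 0.5% per-base
    substitution rate, and 64 cells' worth of 16-base barcodes.
    """

    genome_length: int = 100_000
    n_refs: int = 1
    repeat_count: int = 0            # number of copies of the repeat family
    repeat_length: int = 500
    repeat_divergence: float = 0.0   # per-base mutation rate of copies 2..n vs copy 1
    n_gap_count: int = 0             # optional N runs (exercise contig splitting)
    n_gap_length: int = 50
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    read_length: int = 100
    sub_rate: float = 0.005          # per-base substitution probability in reads
    n_pairs: int = 1000
    barcode_length: int = 16
    n_barcodes: int = 64
    barcode_error_rate: float = 0.0  # probability of one wrong base in R2
    duplicate_rate: float = 0.0      # probability a pair re-emits an earlier fragment
    random_orientation: bool = True  # mate 1 is the reverse mate for ~half the pairs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("repeat_divergence", "sub_rate", "barcode_error_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


class TruthRecord(NamedTuple):
    """Ground truth for one emitted read pair."""

    name: str
    barcode: str      # true (uncorrupted) barcode
    ref: int
    start: int
    end: int
    forward: bool     # orientation of mate 1


@dataclass
class AccuracyReport:
    total: int
    mapped: int
    correct: int
    multimapped: int = 0
    unmapped: int = 0

    @property
    def accuracy(self) -> float:
        return self.correct / self.total if self.total else 0.0

    @property
    def mapping_rate(self) -> float:
        return self.mapped / self.total if self.total else 0.0

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "mapped": self.mapped,
            "correct": self.correct,
            "multimapped": self.multimapped,
            "unmapped": self.unmapped,
            "accuracy": self.accuracy,
            "mapping_rate": self.mapping_rate,
        }


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases i.i.d. at ``rate``, always to a different base."""
    if rate <= 0:
        return codes
    out = codes.copy()
    mask = (rng.random(len(codes)) < rate) & (out < 4)  # never mutate N
    idx = np.nonzero(mask)[0]
    if len(idx):
        shift = rng.integers(1, 4, size=len(idx))
        out[idx] = (out[idx] + shift) % 4
    return out


def make_genome(
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ReferenceSet, list[tuple[int, int]]]:
    """Generate the synthetic genome; returns (refs, repeat placements).

    The genome is uniform i.i.d. ACGT split evenly over ``n_refs``
    references.  A single repeat family of ``repeat_length`` bases is
    written at ``repeat_count`` non-overlapping positions: the first copy
    verbatim, later copies mutated per-base at ``repeat_divergence``.
    Placements are returned as (ref id, start) in insertion order.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if params.n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    per_len = params.genome_length // params.n_refs
    if params.repeat_count and params.repeat_length > per_len:
        raise ValueError("repeat_length exceeds the per-reference length")
    if params.repeat_count * params.repeat_length > params.genome_length:
        raise ValueError("repeat content exceeds the genome length")

    seqs = [rng.integers(0, 4, per_len, dtype=np.uint8) for _ in range(params.n_refs)]

    placements: list[tuple[int, int]] = []
    if params.repeat_count:
        master = rng.integers(0, 4, params.repeat_length, dtype=np.uint8)
        taken: dict[int, list[tuple[int, int]]] = {i: [] for i in range(params.n_refs)}
        for ci in range(params.repeat_count):
            for _ in range(10_000):
                ref = int(rng.integers(0, params.n_refs))
                pos = int(rng.integers(0, per_len - params.repeat_length + 1))
                if all(
                    pos + params.repeat_length <= s or pos >= e
                    for s, e in taken[ref]
                ):
                    break
            else:
                raise ValueError("could not place repeat copies without overlap")
            taken[ref].append((pos, pos + params.repeat_length))
            copy = master if ci == 0 else _mutate(master, params.repeat_divergence, rng)
            seqs[ref][pos : pos + params.repeat_length] = copy
            placements.append((ref, pos))

    for _ in range(params.n_gap_count):
        ref = int(rng.integers(0, params.n_refs))
        pos = int(rng.integers(0, per_len - params.n_gap_length + 1))
        seqs[ref][pos : pos + params.n_gap_length] = _CODE["N"]

    refs = ReferenceSet(
        [f"ref{i}" for i in range(params.n_refs)],
        [_codes_to_str(s) for s in seqs],
    )
    return refs, placements


def make_permit_list(params: SimParams, rng: np.random.Generator) -> list[str]:
    """Generate ``n_barcodes`` distinct random barcodes."""
    seen: dict[str, None] = {}
    while len(seen) < params.n_barcodes:
        bc = _codes_to_str(rng.integers(0, 4, params.barcode_length, dtype=np.uint8))
        seen.setdefault(bc, None)
    return list(seen)


def simulate_pairs(
    refs: ReferenceSet,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str, str, str]], list[TruthRecord], list[str]]:
    """Simulate barcoded FR read pairs with ground truth.

    Fragments are sampled over references proportional to length, with
    Normal(fragment_mean, fragment_sd) lengths clipped to
    [read_length, reference length].  Mate 1 reads the left fragment end
    forward and mate 2 the right end reverse-complemented (roles swapped
    for ~half the pairs when ``random_orientation``).  Returns
    (pairs, truth, permit list) where each pair is
    (name, mate1, observed barcode, mate2).
    """
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    rl = params.read_length
    lengths = np.array(refs.lengths)
    if np.any(lengths < rl):
        raise ValueError("a reference is shorter than the read length")
    n = params.n_pairs
    permit = make_permit_list(params, rng)

    codes = [
        np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        for _, seq in refs
    ]
    for arr in codes:
        for b, c in _CODE.items():
            arr[arr == ord(b)] = c

    # fragment coordinates (drawn independently; duplicates copy earlier slots)
    ref_p = lengths / lengths.sum()
    ref_ids = rng.choice(len(lengths), size=n, p=ref_p)
    flens = np.rint(rng.normal(params.fragment_mean, params.fragment_sd, n)).astype(int)
    flens = np.clip(flens, rl, lengths[ref_ids])
    starts = np.floor(rng.random(n) * (lengths[ref_ids] - flens + 1)).astype(int)
    bc_idx = rng.integers(0, params.n_barcodes, n)
    flip = (
        rng.random(n) < 0.5
        if params.random_orientation
        else np.zeros(n, dtype=bool)
    )
    dup_of = np.full(n, -1)
    if params.duplicate_rate > 0:
        dup_mask = rng.random(n) < params.duplicate_rate
        dup_mask[0] = False
        for j in np.nonzero(dup_mask)[0]:
            src = int(rng.integers(0, j))
            dup_of[j] = src
            ref_ids[j] = ref_ids[src]
            flens[j] = flens[src]
            starts[j] = starts[src]
            bc_idx[j] = bc_idx[src]

    bc_err = rng.random(n) < params.barcode_error_rate

    pairs: list[tuple[str, str, str, str]] = []
    truth: list[TruthRecord] = []
    for j in range(n):
        ref = int(ref_ids[j])
        s = int(starts[j])
        e = s + int(flens[j])
        left = codes[ref][s : s + rl]
        right_rc = codes[ref][e - rl : e][::-1].copy()
        acgt = right_rc < 4
        right_rc[acgt] = 3 - right_rc[acgt]  # complement; N stays N
        r_fwd = _mutate(left, params.sub_rate, rng)
        r_rev = _mutate(right_rc, params.sub_rate, rng)
        if flip[j]:
            m1, m2, fwd1 = r_rev, r_fwd, False
        else:
            m1, m2, fwd1 = r_fwd, r_rev, True
        bc_true = permit[int(bc_idx[j])]
        bc_obs = bc_true
        if bc_err[j]:
            i = int(rng.integers(0, params.barcode_length))
            shift = int(rng.integers(1, 4))
            nb = "ACGT"[( _CODE[bc_true[i]] + shift) % 4]
            bc_obs = bc_true[:i] + nb + bc_true[i + 1 :]
        name = f"pair{j}"
        pairs.append((name, _codes_to_str(m1), bc_obs, _codes_to_str(m2)))
        truth.append(TruthRecord(name, bc_true, ref, s, e, fwd1))
    return pairs, truth, permit


def write_truth(truth: Iterable[TruthRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("name\tbarcode\tref\tstart\tend\tori1\n")
        for t in truth:
            ori = "f" if t.forward else "r"
            fh.write(f"{t.name}\t{t.barcode}\t{t.ref}\t{t.start}\t{t.end}\t{ori}\n")


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.startswith("name\t"):
            raise ValueError(f"{path}: missing truth header")
        for line in fh:
            name, bc, ref, start, end, ori = line.rstrip("\n").split("\t")
            out.append(TruthRecord(name, bc, int(ref), int(start), int(end), ori == "f"))
    return out


def write_dataset(
    outdir: str | Path,
    refs: ReferenceSet,
    pairs: list[tuple[str, str, str, str]],
    truth: list[TruthRecord],
    permit: list[str],
    *,
    gzip_fastq: bool = False,
) -> dict[str, Path]:
    """Write FASTA, the R1/R2/R3 FASTQ triple, permit list and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sfx = ".fastq.gz" if gzip_fastq else ".fastq"
    paths = {
        "fasta": outdir / "genome.fasta",
        "r1": outdir / f"reads_R1{sfx}",
        "r2": outdir / f"reads_R2{sfx}",
        "r3": outdir / f"reads_R3{sfx}",
        "permit": outdir / "permit_list.txt",
        "truth": outdir / "truth.tsv",
    }
    refs.to_fasta(paths["fasta"])
    write_fastq(((n, r1) for n, r1, _, _ in pairs), paths["r1"])
    write_fastq(((n, bc) for n, _, bc, _ in pairs), paths["r2"])
    write_fastq(((n, r2) for n, _, _, r2 in pairs), paths["r3"])
    with _open_text(paths["permit"], "wt") as fh:
        fh.writelines(bc + "\n" for bc in permit)
    write_truth(truth, paths["truth"])
    return paths


def evaluate(
    records: Iterable[FragmentRecord],
    truth: Iterable[TruthRecord],
    tolerance: int = 0,
    *,
    n_multimapped: int = 0,
) -> AccuracyReport:
    """Score mapped fragments against the truth table by pair name.

    A pair is correct when the reported reference matches and both
    fragment ends are within ``tolerance`` bases of the truth.
    Fragment records with unknown names are counted as unmatched
    (ignored), not fatal.
    """
    by_name = {t.name: t for t in truth}
    total = len(by_name)
    mapped = correct = 0
    for r in records:
        t = by_name.get(r.name)
        if t is None:
            continue
        mapped += 1
        if (
            r.ref == t.ref
            and abs(r.start - t.start) <= tolerance
            and abs(r.end - t.end) <= tolerance
        ):
            correct += 1
    return AccuracyReport(
        total=total,
        mapped=mapped,
        correct=correct,
        multimapped=n_multimapped,
        unmapped=total - mapped,
    )


def evaluate_bed(
    bed_records: Iterable,
    truth: Iterable[TruthRecord],
    ref_names: list[str],
    tolerance: int = 0,
) -> AccuracyReport:
    """BED-level scoring: join on (barcode, interval) since names are gone.

    A truth pair counts as correct if any BED line carries its true
    barcode on the right reference with both ends within tolerance.
    """
    intervals: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for b in bed_records:
        intervals.setdefault((b.barcode, b.ref_name), []).append((b.start, b.end))
    truth = list(truth)
    correct = 0
    for t in truth:
        for s, e in intervals.get((t.barcode, ref_names[t.ref]), ()):
            if abs(s - t.start) <= tolerance and abs(e - t.end) <= tolerance:
                correct += 1
                break
    total = len(truth)
    return AccuracyReport(total=total, mapped=correct, correct=correct)
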