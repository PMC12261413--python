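"""Virtual colors: overlapping fixed-extent bins over the references.

Pseudoalignment against whole chromosomes loses positional specificity:
a k-mer hitting two loci 50 Mb apart supports the same color.  Virtual
colors fix this by slicing every reference into bins of stride
``bin_length`` (ℓvcol) where each bin additionally reaches ``ov_length``
bases into its left neighbour, so a read lying across a bin boundary is
fully contained in the right-hand bin.  Bins never span two references.
The scheme is a pure function of the reference lengths and two integers;
it is computed on the fly and never serialized with the index.

Bin ids are global: reference i owns the contiguous id range
``[cb[i], cb[i] + bins[i])`` where ``bins[i] = ceil(L_i / bin_length)``
and ``cb`` is the cumulative bin count.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field


@dataclass
class VirtualColorScheme:
    bin_length: int              # ℓvcol: stride in bases
    ov_length: int               # overlap reaching into the previous bin
    lengths: list[int]           # reference lengths
    bins: list[int] = field(init=False)    # per-reference bin counts B
    cb: list[int] = field(init=False)      # cumulative offsets CB
    total_vcols: int = field(init=False)

    def __post_init__(self) -> None:
        lv = self.bin_length
        self.bins = [-(-L // lv) for L in self.lengths]
        cb = [0]
        for b in self.bins[:-1]:
            cb.append(cb[-1] + b)
        self.cb = cb
        self.total_vcols = cb[-1] + self.bins[-1]

    def ref_of_vid(self, vid: int) -> int:
        if not 0 <= vid < self.total_vcols:
            raise ValueError(f"virtual color id {vid} out of range")
        return bisect_right(self.cb, vid) - 1


def build_scheme(
    lengths: list[int],
    bin_length: int = 1000,
    ov_length: int = 150,
    *,
    read_length: int | None = None,
) -> VirtualColorScheme:
    """Construct the virtual-color scheme for the given reference lengths.

    ``ov_length`` should be at least the read length so that any read
    straddling a bin boundary fits entirely inside the next bin; a warning
    (not an error) is emitted when ``read_length`` is supplied and the
    overlap falls short.  ``ov_length`` may not exceed ``bin_length``:
    beyond that a position would belong to more than two bins, which the
    one-or-two-color assignment rule cannot express.
    """
    if not lengths:
        raise ValueError("empty length list")
    if any(L < 1 for L in lengths):
        raise ValueError("all reference lengths must be >= 1")
    if bin_length <= 0:
        raise ValueError(f"bin_length must be positive, got {bin_length}")
    if ov_length < 0:
        raise ValueError(f"ov_length must be non-negative, got {ov_length}")
    if ov_length > bin_length:
        raise ValueError(
            f"ov_length ({ov_length}) must not exceed bin_length ({bin_length})"
        )
    if read_length is not None and ov_length < read_length:
        warnings.warn(
            f"ov_length={ov_length} is below the read length {read_length}; "
            "reads straddling bin boundaries may be lost"
        )
    return VirtualColorScheme(bin_length, ov_length, list(lengths))


def assign_vcolors(scheme: VirtualColorScheme, ref: int, pos: int) -> tuple[int, ...]:
    """Virtual color id(s) of a k-mer starting at ``pos`` on reference ``ref``.

    The base id is ``cb[ref] + pos // bin_length``; when the position falls
    inside the overlap region of the next bin the next id is assigned as
    well — unless that bin does not exist (last bin of the reference:
    virtual colors never cross into the next reference).
    """
    if not 0 <= ref < len(scheme.lengths):
        raise ValueError(f"reference id {ref} out of range")
    if not 0 <= pos < scheme.lengths[ref]:
        raise ValueError(
            f"position {pos} out of range for reference {ref} "
            f"(length {scheme.lengths[ref]})"
        )
    lv = scheme.bin_length
    b = pos // lv
    vid = scheme.cb[ref] + b
    if pos % lv >= lv - scheme.ov_length and b + 1 < scheme.bins[ref]:
        return (vid, vid + 1)
    return (vid,)


def vcolor_interval(scheme: VirtualColorScheme, vid: int) -> tuple[int, int, int]:
    """Half-open reference interval ``(ref, start, end)`` covered by bin ``vid``.

    The leftmost bin of a reference covers ``bin_length`` bases, interior
    bins ``ov_length + bin_length``, and the rightmost bin ``ov_length + rl``
    where ``rl`` is the length remainder of the reference.
    """
    ref = scheme.ref_of_vid(vid)
    b = vid - scheme.cb[ref]
    lv = scheme.bin_length
    start = max(0, b * lv - scheme.ov_length)
    end = min(scheme.lengths[ref], (b + 1) * lv)
    return ref, start, end
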