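"""Build a de Bruijn graph index over a small genome and query k-mers.

Builds the compacted de Bruijn graph for a 20 kb two-chromosome genome
with a shared duplicated segment, then asks where individual k-mers sit.
Each position is (reference id, 0-based start, orientation): a k-mer from
a duplicated region reports every locus, and querying the reverse
complement returns the same loci with the strand flipped.
"""

import numpy as np

from vcmap import ReferenceSet, build_index, kmer_positions
from vcmap._seq import revcomp

rng = np.random.default_rng(1)
bases = np.frombuffer(b"ACGT", dtype=np.uint8)
chr1 = bases[rng.integers(0, 4, 12_000)].tobytes().decode()
chr2 = list(bases[rng.integers(0, 4, 8_000)].tobytes().decode())
chr2[3000:3400] = chr1[5000:5400]  # duplicate 400 bases of chr1 into chr2
refs = ReferenceSet(["chr1", "chr2"], [chr1, "".join(chr2)])

index = build_index(refs, k=25)
print(f"{index.n_kmers} distinct canonical 25-mers in {index.n_unitigs} unitigs")

unique_kmer = chr1[100:125]
dup_kmer = chr1[5100:5125]
print("unique k-mer:", kmer_positions(index, unique_kmer))
print("duplicated k-mer:", kmer_positions(index, dup_kmer))
print("its reverse complement:", kmer_positions(index, revcomp(dup_kmer)))
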