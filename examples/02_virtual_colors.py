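"""Virtual-color bins: how references are sliced and positions assigned.

A 2.5 kb and a 1.8 kb reference with a 1 kb bin stride and a 100-base
overlap give ceil(2500/1000)=3 and ceil(1800/1000)=2 bins.  A position
inside the overlap region belongs to two bins, so a read crossing the
boundary is never lost; the last bin of a reference never spills into
the next reference.
"""

from vcmap import assign_vcolors, build_scheme, vcolor_interval

scheme = build_scheme([2500, 1800], bin_length=1000, ov_length=100)
print(f"bins per reference: {scheme.bins}, cumulative offsets: {scheme.cb}, "
      f"total virtual colors: {scheme.total_vcols}")

for vid in range(scheme.total_vcols):
    ref, start, end = vcolor_interval(scheme, vid)
    print(f"  bin {vid}: reference {ref}, interval [{start}, {end})")

for ref, pos in [(0, 1500), (0, 950), (0, 2450), (1, 950)]:
    print(f"k-mer at (ref {ref}, pos {pos}) -> bins {assign_vcolors(scheme, ref, pos)}")
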