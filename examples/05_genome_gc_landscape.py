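"""Profile the GC landscape of a phage genome and call low-GC regions.

Uses the synthetic stand-in generator (a 67%-GC genome with two planted
2-kb 50%-GC segments) to show the sliding-window track and region caller.
Point ``read_fasta`` at a real genome FASTA to profile actual phage
sequences the same way.
"""

from phagequant.genome import (gc_fraction, gc_sliding, low_gc_regions,
                               synthetic_genome)

genome = synthetic_genome(40000, gc=0.67,
                          low_gc_segments=((8000, 10000, 0.50),
                                           (26000, 28000, 0.50)), seed=3)
print(f"{genome.identifier}: {genome.length} bp, "
      f"overall GC {gc_fraction(genome) * 100:.1f}%")

track = gc_sliding(genome, window=500, step=100)
regions = low_gc_regions(track, drop_threshold=8.0, min_windows=3)
print(f"{track.n_windows} windows ({track.window} bp, step {track.step} bp)")
print(f"{len(regions)} region(s) at least 8 GC percentage points below the "
      "genome mean:")
for r in regions:
    print(f"  {r.start}-{r.end}: mean GC {r.mean_gc * 100:.1f}% "
          f"({r.depth:.1f} points below genome mean)")
print("such AT-rich islands are candidate nucleoid-protein binding regions")
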