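"""Windowed GC statistics of a genome.

Builds a 1 Mb synthetic genome with a symmetric windowed-GC
distribution and prints the whole-genome mean GC and the standard
deviation of GC over 180-bp sliding windows — the two numbers that
characterize how much raw material a GC bias has to act on.
"""

from gcbias import gc_histogram, gc_summary, skewed_genome, window_gc_profile

genome = skewed_genome("symmetric", 1_000_000, seed=1)
summ = gc_summary(genome, window_size=180)
print(f"genome: {genome.name}, {genome.length:,} bp")
print(f"mean GC          : {summ['mean_gc_percent']}%")
print(f"windowed GC sd   : {summ['sd_gc_percent']}%  ({summ['n_windows']} windows of 180 bp)")

profile = window_gc_profile(genome, 180)
hist = gc_histogram(profile, bin_width=0.05)
peak = max(hist, key=lambda t: t[1])
print(f"modal GC bin     : [{peak[0]:.2f}, {peak[0]+0.05:.2f}) with {peak[1]} windows")
# A wider windowed-GC sd means more genomic sequence sits at extreme GC,
# where a biased library under- or over-samples fragments the most.
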