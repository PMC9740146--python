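"""Why ranked ablation instead of exhaustive subset search, and data rates.

An exhaustive search over electrode subsets is exponential in the
montage size; the ranked ablation needs only one model per channel
count. The data-rate helper quantifies the acquisition load a montage
places on a real-time system.
"""

from eegauth import data_rate, search_space_size

print("exhaustive subset search:")
for n in (8, 14, 32):
    print(f"  {n:2d} channels -> {search_space_size(n):,} candidate subsets")
print("  vs. 32 models for the ranked 32-channel ablation\n")

r14 = data_rate(14, 128)
print(f"14 electrodes at 128 Hz  -> {r14.samples_per_second:,} samples/s")
r64 = data_rate(64, 512, bit_depth=16)
print(f"64 electrodes at 512 Hz  -> {r64.samples_per_second:,} samples/s "
      f"= {r64.bits_per_second:,} bits/s at 16-bit depth")
print("Halving the montage roughly halves the stream a real-time")
print("authenticator must ingest and process.")
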