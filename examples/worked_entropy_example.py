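"""Sleep Temporal Entropy of a four-episode REM night.

A night whose REM sleep splits into episodes of 11, 15, 24 and 32 epochs
(82 epochs of REM in total) has duration proportions ~0.1341, 0.1829,
0.2927, 0.3902. The Shannon entropy of that distribution is the REM STE.
"""

from hypnometrics import shannon_entropy_bits, stage_ste
from hypnometrics.segmentation import Episode

proportions = [0.1341, 0.1829, 0.2927, 0.3902]
print(f"REM STE from printed proportions: {shannon_entropy_bits(proportions):.4f} bits")

episodes, start = [], 0
for d in (11, 15, 24, 32):
    episodes.append(Episode("R", start, d))
    start += d
print(f"REM STE from episode durations:   {stage_ste(episodes, 'R'):.4f} bits")

print("\nFour equal episodes would score log2(4) = 2 bits (maximal");
print("fragmentation for 4 episodes); a single consolidated episode scores 0.")
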