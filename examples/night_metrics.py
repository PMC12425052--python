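"""All per-night metrics for one small hand-written hypnogram.

The record has 90 s of sleep latency, two awakenings and a terminal wake
epoch; classic metrics count epochs, entropy metrics quantify how the
night's time splits across stage episodes.
"""

from hypnometrics import compute_classic, entropy_profile
from hypnometrics.hypnogram import from_stages

stages = "W W W N1 N2 N2 N3 N3 R R W W N2 N2 R R W N2 N2 W".split()
night = from_stages(stages, record_id="demo", epoch_seconds=30.0)

m = compute_classic(night)
print(f"SOL  {m.sol_sec:.0f} s   TST {m.tst_min:.1f} min   TIB {m.tib_min:.1f} min")
print(f"SE   {m.se_fraction:.2f}     WASO {m.waso_min:.1f} min   "
      f"awakenings {m.n_awakenings}   REM latency {m.rem_latency_min:.1f} min")

p = entropy_profile(night)
print(f"\noverall STE {p.overall_ste:.3f} bits   wake TE {p.wake_te:.3f} bits")
print(f"N1 {p.n1_ste:.3f}  N2 {p.n2_ste:.3f}  N3 {p.n3_ste:.3f}  "
      f"REM {p.rem_ste:.3f}  NREM {p.nrem_ste:.3f} bits")
print("\nSingle-episode stages (N1, N3 here) score exactly 0 bits;")
print("a stage absent from the sleep period would be reported as undefined.")
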