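"""Convert mass-spec IMP levels to '1 in N bases' inosine rates.

LC-MS/MS of digested RNA reports inosine as IMP nucleosides per million AMP
nucleosides. Calibrating the A-base fraction from one paired measurement
lets every other level on the same material be expressed as a per-base
frequency.
"""

from inoseq.msquant import MsLevel, calibrate_f_A, fold_ratio, rate_from_level

# Firefly luciferase transcribed in vitro with increasing ITP. The 0.1 mM
# pair (427 IMP per 10^6 AMP <-> 1 inosine in 9379 bases) calibrates the
# A fraction of the transcript.
f_a = calibrate_f_A(427, 9379)
print(f"calibrated A-base fraction: {f_a:.4f}")

for label, level in [("0.1 mM ITP", 427), ("1 mM ITP", 4055), ("10 mM ITP", 21649)]:
    rate = rate_from_level(MsLevel(level), f_a)
    print(f"firefly {label}: {level} IMP/1e6 AMP -> 1 inosine in "
          f"{rate.denominator} bases (freq {rate.freq_per_base:.3e})")

# The Renilla construct misincorporates roughly twice as much at the same
# ITP concentration: the ratio of measured 1 mM levels.
print(f"Renilla/firefly disparity at 1 mM ITP: "
      f"{fold_ratio(8112, 4055):.2f}-fold (~{round(fold_ratio(8112, 4055))}x)")
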