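"""Measure a synthetic brain phantom end to end.

Builds a T1-like phantom with known geometry, runs the full automated
MRPI 2.0 pipeline on it and compares every measured quantity with the
constructed ground truth.
"""

import mrpi2

spec = mrpi2.PhantomSpec(v3_width_mm=8.61, fh_width_mm=39.1)  # PSP-P-like ventricles
volume, truth = mrpi2.generate_phantom(spec)
result = mrpi2.run_subject(volume)

print(f"pipeline status: {result.status}")
m = result.measures
rows = [
    ("midbrain area (mm^2)", m["midbrain_area_mm2"], truth.midbrain_area_mm2),
    ("pons area (mm^2)", m["pons_area_mm2"], truth.pons_area_mm2),
    ("MCP width (mm)", m["mcp_mean_mm"], truth.mcp_width_mm),
    ("SCP width (mm)", m["scp_mean_mm"], truth.scp_width_mm),
    ("3V width (mm)", m["v3_width_mm"], truth.v3_width_mm),
    ("FH width (mm)", m["fh_width_mm"], truth.fh_width_mm),
    ("MRPI", result.mrpi, truth.mrpi),
    ("MRPI 2.0", result.mrpi2, truth.mrpi2),
]
print(f"{'quantity':<22}{'measured':>10}{'truth':>10}")
for name, meas, true in rows:
    print(f"{name:<22}{meas:>10.2f}{true:>10.2f}")
print("\nMRPI 2.0 = (pons/midbrain) x (MCP/SCP) x (3V/FH); values above ~2.5")
print("are in the range reported for PSP-parkinsonism, low values for PD.")
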