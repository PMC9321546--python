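"""Explicit failure semantics under corrupted acquisitions.

Degraded inputs (motion-like ghosting, an unidentifiable aqueduct landmark,
saturated intensities) must yield a failed status naming the broken stage —
never a fabricated index value.
"""

import mrpi2

volume, _ = mrpi2.generate_phantom(mrpi2.PhantomSpec())

print(f"{'corruption':<18}{'status':<9}{'failed stage':<12}{'MRPI 2.0'}")
res = mrpi2.run_subject(volume)
print(f"{'none':<18}{res.status:<9}{res.failure_stage:<12}{res.mrpi2:.3f}")
for mode in ("ghosting", "landmark_dropout", "intensity_clip"):
    bad = mrpi2.corrupt_phantom(volume, mode, seed=1)
    res = mrpi2.run_subject(bad)
    print(f"{mode:<18}{res.status:<9}{res.failure_stage:<12}{res.mrpi2}")
print("\nFailed subjects carry no numeric index; a batch report counts them")
print("per stage, mirroring how unmeasurable scans are excluded in practice.")
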