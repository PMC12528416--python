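"""Extrapolate a torso CT mass to whole-body weight.

A torso scan covers only part of the body; dividing the CT-derived torso
mass by a scaling factor sf (the calibrated torso-to-total mass ratio)
estimates the whole-body weight.  The corrected factor csf additionally
accounts for how much of the body the scan covered:
csf = sf + (scan_length/body_length - x).
"""

from ctweigh import CohortRecord, ScalingConfig, estimate_total_weight

config = ScalingConfig()  # sf overall 0.4182, male 0.4222, female 0.4144, x 0.269
subject = CohortRecord(
    subject_id="demo",
    sex="male",
    torso_weight=33.8,  # kg, from CT volumetry of the torso scan
    reference_weight=80.0,  # kg, measured (for comparison only)
    scan_length=52.0,  # cm, slice count x slice thickness
    body_length=178.0,  # cm
)

w_sf = estimate_total_weight(subject, config, method="sf")
w_csf = estimate_total_weight(subject, config, method="csf")

print(f"torso mass (CT)         : {subject.torso_weight:.1f} kg")
print(f"sf estimate (male sf)   : {w_sf:.2f} kg   = torso / {config.sf_male}")
csf = config.sf_male + (subject.scan_length / subject.body_length - config.offset_x)
print(f"csf estimate            : {w_csf:.2f} kg   = torso / {csf:.4f}")
print(f"measured reference      : {subject.reference_weight:.1f} kg")
print()
print("The csf estimate corrects for this subject's relatively long scan")
print("(52/178 = 0.292 > x = 0.269), lowering the extrapolated weight.")
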