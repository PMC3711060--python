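"""Inverse correctors learning away a 15-degree rotation.

Runs one desk-scale subject in the inverse-only (IM) scheme for six
90-second training trials at a fixed 15-degree anticlockwise bias and
prints the per-trial mean errors. A value of 1.0 means "as wrong as the
bias itself"; the decline shows the agonist/antagonist corrector pairs
building torque corrections from the delayed sensed error.
"""

from cbmsim.protocol import Subject, desk_scale_protocol

protocol = desk_scale_protocol()
subject = Subject(protocol, seed=1)

print("trial  directional  distance   (normalized; 1.0 = unadapted)")
for trial in range(1, 7):
    d, l = subject.run_trial(15.0, "IM")
    print(f"{trial:5d}  {d:11.3f}  {l:8.3f}")
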