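"""Derive the six test parameters from pelvic parameters and incidence angles.

Uses the published 63-subject cohort means of the five independently
measured angles.  Each output is a simple difference of two inputs:
for example thoracic kyphosis is the T1 incidence minus the L1 incidence.
The printed values (TK 37.31, C2-7L 12.90, L1S -12.53, T1S 24.78,
C2S 11.88 degrees) are the cohort-mean test parameters implied by the
equations; negative values indicate lordosis, positive kyphosis.
"""

from spinemetrics import IncidenceAngles, PelvicParameters, derive_test_parameters

pelvic = PelvicParameters(PI=52.16, PT=14.99, SS=52.16 - 14.99)
incidences = IncidenceAngles(L1I=2.46, T1I=39.77, C2I=26.87)

derived = derive_test_parameters(pelvic, incidences)
for name, value in derived.as_dict().items():
    print(f"{name:>6}: {value:8.2f} deg")
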