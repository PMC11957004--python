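"""Estimate a glass nanopore's diameter from its open-pore conductance.

Builds the truncated-cone + access-resistance model for a nanopipette pulled
from a 0.5 mm-bore quartz capillary, evaluates the forward conductance for a
set of pore diameters, and inverts a measured conductance back to a diameter.
"""

from dataclasses import replace

from poreqc import PoreGeometry, conductance_from_geometry, diameter_from_conductance

# the buffer conductivity must come from the experiment; this is a plausible
# value for a concentrated LiCl measurement buffer
SIGMA = 20.0  # S/m

prior = PoreGeometry(None, SIGMA, half_cone_angle_deg=5.0)

print("forward model (half-cone angle 5 deg, sigma = 20 S/m):")
for d in (6.2, 9.7, 12.2, 18.9):
    g = conductance_from_geometry(replace(prior, tip_diameter_nm=d))
    print(f"  d_tip = {d:5.1f} nm  ->  G = {g:6.2f} nS")

measured_nS = 23.5
d_est = diameter_from_conductance(measured_nS, prior)
print(f"\nmeasured G = {measured_nS} nS  ->  estimated d_tip = {d_est:.2f} nm")
print("(the estimate is the unique diameter whose forward conductance matches)")
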