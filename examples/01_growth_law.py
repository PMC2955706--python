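"""Light-driven exponential growth: the growth law and its calibration.

Evaluates V(t) = V(0) e^(mu t), recovers mu from endpoints, and sweeps the
PAR -> mu light response.  The printed factor-of-8 between mu at PAR 200 and
PAR 10 is what makes the interdivision duration 8x longer at the dim end.
"""

from chlamycycle import growth_rate, mu_from_endpoints, volume_at

v0 = 79.7  # typical initial daughter volume, um^3
mu = growth_rate(200.0)  # h^-1 at PAR 200 umol m^-2 s^-1

print(f"mu at PAR 200      : {mu:.4f} /h")
print(f"volume after 10 h  : {volume_at(v0, mu, 10.0):.1f} um^3 "
      f"({volume_at(v0, mu, 10.0) / v0:.2f}x the initial volume)")
print(f"mu from endpoints  : {mu_from_endpoints(v0, volume_at(v0, mu, 10.0), 10.0):.4f} /h")

print("\nPAR (umol m^-2 s^-1) ->  mu (/h)")
for par in (0.2, 10, 20, 40, 100, 200, 300):
    print(f"  {par:6g}             ->  {growth_rate(par):.4f}")
print(f"\nmu(200)/mu(10) = {growth_rate(200) / growth_rate(10):.2f}"
      "  (dim cells take 8x longer to reach the division phase)")
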