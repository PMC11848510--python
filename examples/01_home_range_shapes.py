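"""Equilibrium home ranges on a heterogeneous landscape.

Builds a small binary patch landscape, solves the advection-diffusion
equilibrium for a range of permeability coefficients beta, and prints how
much of the home range sits on the high-permeability patch.  Larger beta
makes the patch easier to move through, so the home range skews into it.
"""
import numpy as np

from adcr import HomeRangeParams, Landscape, build_generator, \
    equilibrium_distribution, hda90

z = np.zeros((21, 21))
z[8:14, 12:17] = 0.5            # a permeable patch east of the activity centre
land = Landscape(21, 21, 1.0, z)
mu = (8.5, 10.5)                # activity centre, world coordinates
patch = land.z[:, 0] > 0

print("beta   patch mass   90% home-range area")
for beta in (-2.0, -1.0, 0.0, 1.0, 2.0):
    gen = build_generator(land, mu, HomeRangeParams(gamma0=1.0, beta=[beta]))
    ud = equilibrium_distribution(gen)
    print(f"{beta:+.1f}   {ud.p[patch].sum():10.4f}   {hda90(ud):10.1f}")

print()
print("patch mass = probability the animal is on the patch at any moment;")
print("it grows with beta because permeable habitat is easier to roam into.")
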