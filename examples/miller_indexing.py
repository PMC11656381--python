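"""Assign Miller indices to a tetragonal powder pattern.

Forward-generates diffraction angles for a handful of (h, k, l) planes
of a tetragonal cell via Bragg's law, then recovers the indices from
the angles alone.  The residual column is |2theta_pred - 2theta_obs| in
degrees; zero means the geometric assignment is exact.
"""

from specdecon import assign_miller, bragg_two_theta, tetragonal_d

A, C = 3.785, 9.514        # tetragonal lattice constants (angstrom)
WAVELENGTH = 1.54          # Cu K-alpha (angstrom)

planes = [(1, 0, 1), (1, 0, 3), (0, 0, 4), (1, 1, 2), (2, 0, 0), (2, 1, 1)]
angles = [bragg_two_theta(tetragonal_d(hkl, A, C), WAVELENGTH)
          for hkl in planes]

print(f"cell a = {A} A, c = {C} A, wavelength {WAVELENGTH} A\n")
print("2theta(deg)    d(A)     assigned hkl   residual(deg)")
for m in assign_miller(angles, WAVELENGTH, A, C, hkl_max=6):
    h, k, l = m.hkl
    print(f"  {m.two_theta:8.3f}  {m.d:7.4f}     ({h} {k} {l})"
          f"       {m.residual:.2e}")
print("\nEach observed angle maps back to the plane that generated it; "
      "h >= k is the canonical representative of the h<->k degeneracy.")
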