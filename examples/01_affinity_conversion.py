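"""Convert dissociation constants to the dissociation free energy target.

The regression target is dG = -RT ln(Kd) in kcal/mol (R = 1.987e-3
kcal/(mol K)).  A Kd of 1 M gives dG = 0; tighter binders (smaller Kd) have
larger dG.
"""

from rnaffinity import delta_g_from_kd, read_affinity_table

for kd, t in [(1.0, 298.15), (1e-6, 298.15), (1e-9, 310.0)]:
    print(f"Kd = {kd:8.1e} M at {t:6.2f} K  ->  "
          f"dG = {delta_g_from_kd(kd, t):6.3f} kcal/mol")

table = (
    "complex_id\tkd_molar\ttemperature_k\tph\n"
    "cplx_a\t2.5e-7\t298.0\t7.4\n"
    "cplx_b\t8.0e-9\t310.0\t6.5\n"
)
print("\nAffinity table rows (dG filled from Kd and T):")
for rec in read_affinity_table(table):
    print(f"  {rec.complex_id}: dG = {rec.delta_g:.3f} kcal/mol "
          f"(Kd = {rec.kd:.2e} M, T = {rec.temperature:.1f} K)")
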