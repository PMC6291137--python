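"""Adduct-ion masses, calibration references and ppm errors.

Computes theoretical m/z for a few metabolite adduct ions, the
gold-cluster lock-mass series, and signed mass errors against
experimental values.
"""

from aurimsi import chem

print("Gold cluster calibration references [Au_n]+ (neutral-sum convention):")
for ref in chem.gold_cluster_series(5):
    print(f"  {ref.label}: {ref.mz:.4f} Da")
for ref in chem.salt_cluster_references():
    print(f"  {ref.label}: {ref.mz:.4f} Da")

print("\nAdduct ion m/z = (M + adduct - z*m_e)/z :")
for name, formula, adduct, observed in [
    ("Citrulline", "C6H13N3O3", "+Na", 198.0864),
    ("Cholesterol", "C27H46O", "+K", 425.3091),
    ("Triacylglycerol(49:5)", "C52H90O6", "+K", 849.6369),
]:
    theo = chem.ion_mz(formula, adduct)
    err = chem.ppm_error(observed, theo)
    print(f"  {name} [{formula}{adduct}]+: calc {theo:.4f} Da, "
          f"observed {observed:.4f} -> {err:+.1f} ppm")

# The ppm errors are signed as (theoretical - observed)/theoretical;
# identifications are accepted when |error| <= 20 ppm.
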