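"""Absolute qPCR quantification from a standard dilution series.

Fits a standard curve from five 10-fold standards (10^3 to 10^7 copies),
then converts a sample Ct into transcript copies per cell using the
extraction bookkeeping: cells-per-100ng = n_cells / total_RNA_ng * 100.
"""

import math

from coloctop import copies_per_cell, copies_to_ct, fit_standard_curve

# an exact 2-fold-per-cycle series: Ct = 40 - log2(copies)
standards = [(c, 40 - math.log2(c)) for c in (1e3, 1e4, 1e5, 1e6, 1e7)]
curve = fit_standard_curve(standards)
print(f"slope      = {curve.slope:.4f} Ct per log10(copies)")
print(f"efficiency = {curve.efficiency:.3f}  (1.0 = perfect doubling)")
print(f"r^2        = {curve.r_squared:.4f}")

# a sample measuring 1e6 copies, extracted from 4e5 cells yielding 400 ng RNA
ct = copies_to_ct(curve, 1e6)
est = copies_per_cell(curve, ct, n_cells=4e5, total_rna_ng=400)
print(f"\nsample Ct = {ct:.2f}")
print(f"copies in reaction  = {est.copies_in_reaction:,.0f}")
print(f"cells per 100 ng    = {est.cells_per_100ng:,.0f}")
print(f"copies per cell     = {est.copies_per_cell:.1f}")
print("\n1e6 copies across the 1e5 cell-equivalents that produced the "
      "100 ng template gives 10 transcript copies per cell.")
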