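"""Metabolite annotation of an experimental peak list.

Matches the bundled table of experimental m/z values against the
bundled HMDB-style metabolite database over the +H/+Na/+K/+NH4 adduct
set within 20 ppm and prints the putative identifications with their
signed mass errors and brain-occurrence flags.
"""

from aurimsi.annotate import annotate, hits_to_frame
from aurimsi.data import load_brain_assignments, load_brain_db

peaks = list(load_brain_assignments()["mz_experimental"])
db = load_brain_db()

hits = annotate(peaks, db, tol_ppm=20.0, tissue="brain")
table = hits_to_frame(hits)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\n{len(hits)} putative hits for {len(peaks)} peaks; "
      f"{int(table.tissue_reported.sum())} involve metabolites previously "
      "reported in brain tissue. All assignments are formula-level "
      "(isomers are indistinguishable at MS1).")
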