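"""Score one pair of conformations with all six similarity measures.

Builds a 36-residue helical Calpha trace and a noisy copy, then prints
every measure side by side. cRMSD/dRMSD are in Angstroms (0 = identical);
TM-score and MaxSub live in (0, 1] and GDT_TS / contact-map overlap in
[0, 100] (identity = 1 or 100).
"""

import numpy as np

import decoyclust as dc

base = dc.make_base_structure(36, "helix")
rng = np.random.default_rng(1)
decoy = dc.StructureModel(model_id="decoy",
                          coords=base.coords + rng.normal(scale=1.0,
                                                          size=base.coords.shape))

print(f"cRMSD  = {dc.crmsd(base.coords, decoy.coords):6.3f} A  "
      "(minimum RMSD over rigid motions, closed form)")
print(f"dRMSD  = {dc.drmsd(base, decoy):6.3f} A  "
      "(distance-matrix deviation, superposition-free)")
print(f"GDT_TS = {dc.gdt_ts(base.coords, decoy.coords):6.1f}    "
      "(mean % of atoms within 1/2/4/8 A over best superpositions)")
print(f"TM     = {dc.tm_score(base.coords, decoy.coords):6.3f}    "
      f"(d0 = {dc.d0_tm(36):.3f} A for 36 residues)")
print(f"MaxSub = {dc.maxsub(base.coords, decoy.coords):6.3f}    "
      "(same functional, fixed d0 = 3.5 A)")
cmo = dc.cmo_sorensen(dc.contact_map(base), dc.contact_map(decoy))
print(f"CMO    = {cmo:6.1f}    (Sorensen overlap of 8 A contact sets, %)")
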