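ligand_id,substrate_id,target_id,K1_uM,Ka_uM,K4_uM,Kb_direct_uM,e_binding_kcal_mol
Betulin,maltose,Rattus alpha-amylase model,427180,13.66,938020,23.36,-6.66
Betulinic acid,maltose,porcine pancreatic alpha-amylase (1.ose),493240,75.66,942460,149.13,-5.62
Bisdemethoxycurcumin,maltose,human alpha-amylase (3.old),791530,45.86,682600,83.49,-5.92
Curcumin,maltose,human alpha-amylase (3.old),791530,260.62,132.63,841.04,-4.89
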