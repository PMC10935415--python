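id,smarts,binding_atom_indices,denticity,provenance,note
hydroxamate,[CX3](=O)[NX3][OX2H1],1;3,bidentate,known,classic bidentate chelator via both oxygens
sulfonamide,[SX4](=O)(=O)[NX3],3,monodentate,known,binds through the sulfonamide nitrogen
urea,[NX3][CX3](=O)[NX3],2,monodentate,known,binds through the carbonyl oxygen
phosphonate,"[PX4](=O)([OX2H1,OX1-])[OX2H1,OX1-]",1,monodentate,known,binds through a phosphoryl oxygen
carboxylate,"[CX3](=O)[OX2H1,OX1-]",1;2,bidentate,known,carboxylate oxygens
thiolate,[SX2H1],0,monodentate,known,free thiol sulfur
sulfonate,"[SX4](=O)(=O)[OX2H1,OX1-]",3,monodentate,known,sulfonate oxygen
imidazole,c1cnc[nH]1,2,monodentate,known,pyridine-type ring nitrogen
catechol,[OX2H1]c1ccccc1[OX2H1],0;7,bidentate,synthetic,best-effort encoding of a vicinal diol chelator
n_hydroxyurea,[NX3][CX3](=O)[NX3][OX2H1],2;4,bidentate,synthetic,best-effort encoding; carbonyl and hydroxyl oxygens
beta_ketoamide,[CX3](=O)[CX4][CX3](=O)[NX3],1;4,bidentate,synthetic,best-effort encoding of a 1.3-dicarbonyl chelator
tetrazole,c1nnn[nH]1,1,monodentate,synthetic,best-effort encoding; ring nitrogen donor
boronic_acid,[BX3]([OX2H1])[OX2H1],1;2,bidentate,synthetic,best-effort encoding; hydroxyl oxygens
hydroxyquinoline,[OX2H1]c1cccc2cccnc12,0;9,bidentate,synthetic,best-effort encoding of an 8-hydroxyquinoline chelator
dithiocarbamate,[NX3][CX3](=S)[SX2],2;3,bidentate,synthetic,best-effort encoding; sulfur donors
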