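# Predefined salt / addend fragments removed during standardization.
# One SMILES per line, optional tab-separated name. Editable: extend this
# list to strip additional counterions. Both neutral and ionic forms of a
# counterion should be listed when they differ. Do not list fragments that
# can themselves be the organic parent of a submission (acetic acid,
# simple alcohols): leave those to charge neutralization instead, or a
# parent-only submission would be mistaken for a salts-only one.
Cl	hydrochloride
[Cl-]	chloride
Br	hydrobromide
[Br-]	bromide
I	hydroiodide
[I-]	iodide
F	hydrofluoride
[F-]	fluoride
[Na+]	sodium
[K+]	potassium
[Li+]	lithium
[Ca+2]	calcium
[Mg+2]	magnesium
[Zn+2]	zinc
[NH4+]	ammonium
N	ammonia
O	water
O=S(=O)(O)O	sulfate
OP(=O)(O)O	phosphate
O=[N+]([O-])O	nitrate
OC(=O)C(=O)O	oxalate
OC(=O)/C=C\C(=O)O	maleate
OC(=O)/C=C/C(=O)O	fumarate
OC(C(O)C(=O)O)C(=O)O	tartrate
OC(=O)CC(O)(CC(=O)O)C(=O)O	citrate
OC(=O)CCC(=O)O	succinate
CS(=O)(=O)O	mesylate
CCS(=O)(=O)O	esylate
Cc1ccc(S(=O)(=O)O)cc1	tosylate
OS(=O)(=O)c1ccccc1	besylate
OCC(O)CO	glycerol
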