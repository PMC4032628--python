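# SYNTHETIC residue-level structural annotations for the bundled variant fixture.
# Constructed so that the default additive rubric reproduces the fixture's printed
# crystal classifications for every assessable residue (<= 451); illustrative of the
# rubric's mechanics only, not a curation of the original structural assessment.
protein_change	residue_index	location	environment_hydrophobic	surface_patch_conserved	size_change	charge_change	hydrophilic_into_hydrophobic	is_truncating
R70C	70	core	true	false	large	true	true	false
L118P	118	core	true	false	large	false	true	false
G243A	243	surface	false	false	moderate	false	false	false
F338S	338	core	true	false	large	false	true	false
F123L	123	core	true	false	large	false	true	false
G216Sfs*12	216	core	false	false	none	false	false	true
K50E	50	surface	false	true	moderate	true	false	false
A321S	321	surface	false	false	none	false	false	false
V337L	337	core	false	false	none	false	false	false
P14R	14	surface	false	false	large	true	false	false
R161*	161	surface	false	true	none	false	false	true
M194V	194	surface	false	false	moderate	false	false	false
E320D	320	surface	false	true	none	false	false	false
N354D	354	surface	false	false	none	true	false	false
T451M	451	surface	false	false	moderate	false	false	false
G55C	55	surface	false	false	moderate	false	false	false
F100L	100	surface	false	true	none	false	false	false
D268G	268	surface	false	false	moderate	false	false	false
I534T	534	core	true	false	moderate	false	true	false
I576_A577insI	576	surface	false	false	moderate	false	false	false
T785A	785	surface	false	false	none	false	false	false
D504G	504	surface	false	true	none	false	false	false
L508P	508	core	true	false	large	false	false	false
I510V	510	core	true	false	none	false	false	false
Q528R	528	surface	false	false	none	true	false	false
M646V	646	core	true	false	none	false	false	false
R532W	532	surface	false	true	large	true	false	false
D570G	570	surface	false	true	moderate	false	false	false
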