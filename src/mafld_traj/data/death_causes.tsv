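chapter	cause_code	description
A	infectious_parasitic	Infectious and parasitic death
B	infectious_parasitic	Infectious and parasitic death
C	malignant_neoplasms	Malignant neoplasms death
D	blood_other_neoplasms	Blood disorders and other neoplasms death
E	endocrine	Endocrine system death
F	mental_behavioural	Mental and behavioural death
G	nervous_system	Nervous system death
H	eye_ear	Eye and ear death
I	cardiovascular	Cardiovascular death
J	respiratory	Respiratory system death
K	digestive	Digestive system death
L	skin	Skin and subcutaneous tissue death
M	musculoskeletal	Musculoskeletal system death
N	genitourinary	Genitourinary system death
Q	congenital	Congenital malformation death
R	ill_defined	Ill-defined conditions death
S	unnatural	Unnatural cause death
T	unnatural	Unnatural cause death
V	unnatural	Unnatural cause death
W	unnatural	Unnatural cause death
X	unnatural	Unnatural cause death
Y	unnatural	Unnatural cause death
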