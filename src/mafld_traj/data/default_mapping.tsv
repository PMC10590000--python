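icd10_code	combined_code	description
A00	A00-A03	bacterial intestinal infections
A01	A00-A03	bacterial intestinal infections
A03	A00-A03	bacterial intestinal infections
A04	A04	other bacterial intestinal infections
A09	A09	infectious gastroenteritis and colitis
A41	A41	sepsis
C18	C18	malignant neoplasm of colon
C78	C77-C79	metastatic cancer
C79	C77-C79	metastatic cancer
D12	D12	benign tumour of colon, rectum and anus
D50	D50	iron deficiency anaemia
E03	E03	hypothyroid conditions
E11	E11	type 2 diabetes mellitus
E66	E66	obesity
E87	E87	disorders of fluid, electrolyte and acid-base balance
F17	F17	tobacco abuse
F32	F32	depressive episode
G47	G47	sleep disorders
I10	I10	essential hypertension
I20	I20	angina pectoris
I21	I21-I22	acute myocardial infarction
I22	I21-I22	acute myocardial infarction
I25	I25	chronic ischaemic heart disease
I48	I48	atrial fibrillation and flutter
I50	I50	heart failure
I95	I95	hypotension
J18	J18	pneumonia
J45	J45	asthma
J96	J96	respiratory failure
K52	K52	noninfective gastroenteritis and colitis
K57	K57	diverticular disease of intestine
K59	K59	functional intestinal disorders
K64	K64	haemorrhoids and perianal venous thrombosis
K75	K75-K76	diseases of the liver
K76	K75-K76	diseases of the liver
M13	M13	inflammatory arthritis
N17	N17	acute renal failure
N39	N39	urinary tract infection
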