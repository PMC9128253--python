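surface_form	cui	preferred_name	tuis
poor eye contact	C7000001	Poor eye contact	T033
avoids eye contact	C7000001	Poor eye contact	T033
limited social interaction	C7000002	Impaired social interaction	T054
social withdrawal	C7000003	Social withdrawal	T054
difficulty with joint attention	C7000004	Joint attention impairment	T048
speech delay	C7000005	Delayed speech development	T048
language delay	C7000006	Delayed language development	T048
nonverbal communication	C7000007	Nonverbal communication	T055
does not respond to name	C7000008	Absent response to name	T033
communication impairment	C7000009	Communication impairment	T048
difficulty making friends	C7000010	Difficulty making friends	T033
poor peer relationships	C7000011	Poor peer relationships	T054
lack of social reciprocity	C7000012	Lack of social reciprocity	T054
prefers to play alone	C7000013	Solitary play preference	T055
insistence on sameness	C7000014	Insistence on sameness	T048
rigid routines	C7000015	Rigid adherence to routines	T055
ritualized behavior	C7000016	Ritualized behavior	T055
difficulty switching between activities	C7000017	Difficulty switching between activities	T033
hand flapping	C7000018	Hand flapping	T033
rocking back and forth	C7000019	Body rocking	T055
repetitive movements	C7000020	Stereotyped repetitive movements	T033
stereotyped phrases	C7000021	Stereotyped phrases	T055
repetitive language	C7000022	Repetitive language	T055
restricted interests	C7000023	Restricted interests	T048
intense preoccupation	C7000024	Intense preoccupation	T041
fascination with spinning objects	C7000025	Fascination with spinning objects	T033
preoccupation with parts of objects	C7000026	Preoccupation with parts of objects	T033
unusual attachment to objects	C7000027	Unusual attachment to objects	T055
sensory sensitivity	C7000028	Sensory sensitivity	T033
covers ears to loud sounds	C7000029	Auditory hypersensitivity behavior	T033
unusual sensory interests	C7000030	Unusual sensory interests	T033
food selectivity	C7000031	Food selectivity	T055
aversion to textures	C7000032	Tactile aversion	T033
autism	C7000033	Autism	T047
autistic behavior	C7000034	Autistic behavior	T048
pervasive developmental disorder	C7000035	Pervasive developmental disorder	T047
asperger syndrome	C7000036	Asperger syndrome	T047
intellectual disability	C7000037	Intellectual disability	T048
sleep disturbance	C7000038	Sleep disturbance	T184
seizure disorder	C7000039	Seizure disorder	T047
aggressive behavior	C7000040	Aggressive behavior	T055
anxiety	C7000041	Anxiety	T048
depressed mood	C7000042	Depressed mood	T048
suicidal ideation	C7000043	Suicidal ideation	T033
hyperactivity	C7000044	Hyperactivity	T184
anger outbursts	C7000045	Anger outbursts	T055
attention difficulties	C7000046	Attention difficulties	T033
well nourished	C7000047	Well nourished	T033
follow up visit	C7000048	Follow-up visit	T058
blood test	C7000049	Blood test	T059
medication refill	C7000050	Medication refill	T061
temper tantrum	C7000051	Temper tantrum	T055
classroom elopement	C7000052	Classroom elopement	T033
fussy eater		Fussy eater
eye contact	C7000001	Poor eye contact	T033
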