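term_id	surface_form	category
S0001	autism	diagnosis
S0002	autistic	diagnosis
S0003	PDD-NOS	diagnosis
S0004	pervasive developmental disorder	diagnosis
S0005	asperger syndrome	diagnosis
S0006	autism spectrum disorder	diagnosis
S0007	poor eye contact	dsm_feature
S0008	speech delay	dsm_feature
S0009	language delay	dsm_feature
S0010	nonverbal communication	dsm_feature
S0011	does not respond to name	dsm_feature
S0012	communication impairment	dsm_feature
S0013	limited social interaction	dsm_feature
S0014	social withdrawal	dsm_feature
S0015	difficulty with joint attention	dsm_feature
S0016	difficulty making friends	dsm_feature
S0017	poor peer relationships	dsm_feature
S0018	lack of social reciprocity	dsm_feature
S0019	prefers to play alone	dsm_feature
S0020	insistence on sameness	dsm_feature
S0021	rigid routines	dsm_feature
S0022	ritualized behavior	dsm_feature
S0023	difficulty switching between activities	dsm_feature
S0024	hand flapping	dsm_feature
S0025	rocking back and forth	dsm_feature
S0026	repetitive movements	dsm_feature
S0027	stereotyped phrases	dsm_feature
S0028	repetitive language	dsm_feature
S0029	restricted interests	dsm_feature
S0030	intense preoccupation	dsm_feature
S0031	fascination with spinning objects	dsm_feature
S0032	preoccupation with parts of objects	dsm_feature
S0033	unusual attachment to objects	dsm_feature
S0034	sensory sensitivity	dsm_feature
S0035	covers ears to loud sounds	dsm_feature
S0036	unusual sensory interests	dsm_feature
S0037	food selectivity	dsm_feature
S0038	aversion to textures	dsm_feature
S0039	toe walking	associated_behavior
S0040	sleep disturbance	associated_behavior
S0041	intellectual disability	associated_behavior
S0042	seizure disorder	associated_behavior
S0043	motor clumsiness	associated_behavior
S0044	attention difficulties	associated_behavior
S0045	autistic behavior	diagnosis
S0046	anxiety	non_asd_psych
S0047	depressed mood	non_asd_psych
S0048	aggressive behavior	non_asd_psych
S0049	suicidal ideation	non_asd_psych
S0050	hyperactivity	non_asd_psych
S0051	anger outbursts	non_asd_psych
S0052	ADHD	non_asd_psych
S0053	epilepsy	non_asd_psych
S0054	emotional stress	non_asd_psych
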