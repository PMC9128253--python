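criterion	display_name	phrase
A1	social interaction	deficits in social emotional reciprocity
A1	social interaction	abnormal social approach
A1	social interaction	poor eye contact
A1	social interaction	limited social interaction
A1	social interaction	difficulty with joint attention
A1	social interaction	social withdrawal
A1	social interaction	reduced sharing of interests and emotions
A2	social communication	deficits in nonverbal communicative behaviors
A2	social communication	nonverbal communication
A2	social communication	speech delay
A2	social communication	language delay
A2	social communication	does not respond to name
A2	social communication	communication impairment
A2	social communication	poorly integrated verbal communication
A3	social relationship	difficulties developing and maintaining relationships
A3	social relationship	difficulty making friends
A3	social relationship	poor peer relationships
A3	social relationship	lack of social reciprocity
A3	social relationship	prefers to play alone
A3	social relationship	absence of interest in peers
B1	repetitive behaviors	stereotyped or repetitive motor movements
B1	repetitive behaviors	repetitive movements
B1	repetitive behaviors	hand flapping
B1	repetitive behaviors	rocking back and forth
B1	repetitive behaviors	stereotyped phrases
B1	repetitive behaviors	repetitive language
B1	repetitive behaviors	echolalia
B1	repetitive behaviors	lining up toys
B2	ritualized behaviors	insistence on sameness
B2	ritualized behaviors	inflexible adherence to routines
B2	ritualized behaviors	rigid routines
B2	ritualized behaviors	ritualized behavior
B2	ritualized behaviors	difficulty switching between activities
B2	ritualized behaviors	distress at small changes
B3	fascination and preoccupation	highly restricted fixated interests
B3	fascination and preoccupation	restricted interests
B3	fascination and preoccupation	intense preoccupation
B3	fascination and preoccupation	fascination with spinning objects
B3	fascination and preoccupation	preoccupation with parts of objects
B3	fascination and preoccupation	unusual attachment to objects
B3	fascination and preoccupation	abnormal intensity of focus
B4	unusual sensory and comorbidities	hyperreactivity or hyporeactivity to sensory input
B4	unusual sensory and comorbidities	sensory sensitivity
B4	unusual sensory and comorbidities	covers ears to loud sounds
B4	unusual sensory and comorbidities	unusual sensory interests
B4	unusual sensory and comorbidities	food selectivity
B4	unusual sensory and comorbidities	aversion to textures
E	ASD and comorbidities	autism
E	ASD and comorbidities	autistic behavior
E	ASD and comorbidities	autism spectrum disorder
E	ASD and comorbidities	pervasive developmental disorder
E	ASD and comorbidities	asperger syndrome
E	ASD and comorbidities	intellectual disability
E	ASD and comorbidities	sleep disturbance
E	ASD and comorbidities	seizure disorder
E	ASD and comorbidities	comorbid neurodevelopmental conditions
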