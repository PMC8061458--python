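category	term	pattern	priority	kind
tissue	blood	\bblood\b	5	presence
tissue	whole blood	\bwhole\s+blood\b	6	presence
tissue	cord blood	\b(cord\s+blood|umbilical)\b	6	presence
tissue	brain	\b(brain|cortex|cerebellum)\b	5	presence
tissue	buccal	\bbuccal\b	5	presence
tissue	nasal	\bnasal\b	5	presence
tissue	adipose	\badipose\b	5	presence
tissue	liver	\bliver\b	5	presence
tissue	sperm	\b(sperm|semen)\b	5	presence
tissue	saliva	\bsaliva\b	5	presence
tissue	placenta	\bplacenta(l)?\b	5	presence
tissue	breast	\bbreast\b	5	presence
tissue	t cell	\bt[- ]cells?\b	5	presence
tissue	muscle	\bmuscle\b	5	presence
tissue	skin	\bskin\b	5	presence
tissue	kidney	\bkidney\b	5	presence
tissue	lung	\blung\b	5	presence
tissue	colon	\b(colon|colorectal|intestine)\b	5	presence
tissue	pancreas	\bpancrea(s|tic)\b	5	presence
tissue	mucosa	\bmucosa\b	5	presence
tissue	epithelial	\bepitheli(al|um)\b	5	presence
disease/group	cancer	\b(cancer|tumou?r|carcinoma|malignan(t|cy))\b	5	presence
disease/group	leukemia	\bleuk(a)?emia\b	6	presence
disease/group	breast cancer	\bbreast\s+(cancer|carcinoma|tumou?r)\b	6	presence
disease/group	colorectal cancer	\bcolorectal\s+(cancer|carcinoma|tumou?r)\b	6	presence
disease/group	prostate cancer	\bprostate\s+(cancer|carcinoma|tumou?r)\b	6	presence
disease/group	brain cancer	\b(brain\s+(cancer|tumou?r)|glioma|medulloblastoma)\b	6	presence
disease/group	normal	\bnormal\b	5	presence
disease/group	control	\bcontrol\b	5	presence
disease/group	healthy	\bhealthy\b	5	presence
disease/group	obese	\bobes(e|ity)\b	5	presence
disease/group	arthritis	\barthritis\b	5	presence
disease/group	parkinson's disease	\bparkinson'?s?(\s+disease)?\b	5	presence
disease/group	diabetes	\bdiabet(es|ic)\b	5	presence
disease/group	alzheimer's disease	\balzheimer'?s?(\s+disease)?\b	5	presence
sex	female	\bfemale\b	5	presence
sex	female	\b(sex|gender)[^:\n]*:\s*f\b	5	presence
sex	male	\bmale\b	4	presence
sex	male	\b(sex|gender)[^:\n]*:\s*m\b	4	presence
age	age	\bage[^:\n]*:\s*([0-9]+(?:\.[0-9]+)?)\s*(years?|yrs?|y\b|months?|mos?\b|weeks?|wks?)?	5	numeric
storage	ffpe	\b(ffpe|formalin[- ]fixed(\s+paraffin[- ]embedded)?)\b	5	presence
storage	frozen	\b(fresh[- ]frozen|frozen|ff)\b	4	presence
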