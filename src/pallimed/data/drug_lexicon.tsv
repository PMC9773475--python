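# Fixture drug lexicon: common ICU / palliative-care agents.
# Columns: surface_form <TAB> canonical <TAB> source_tag
surface_form	canonical	source_tag
albumin	albumin	generic
alprazolam	alprazolam	generic
xanax	alprazolam	brand
amiodarone	amiodarone	generic
cordarone	amiodarone	brand
amphotericin	amphotericin	generic
acetaminophen	acetaminophen	generic
tylenol	acetaminophen	brand
azithromycin	azithromycin	generic
zithromax	azithromycin	brand
bevacizumab	bevacizumab	generic
avastin	bevacizumab	brand
capecitabine	capecitabine	generic
xeloda	capecitabine	brand
caspofungin	caspofungin	generic
cefepime	cefepime	generic
maxipime	cefepime	brand
ceftazidime	ceftazidime	generic
fortaz	ceftazidime	brand
ceftriaxone	ceftriaxone	generic
rocephin	ceftriaxone	brand
ciprofloxacin	ciprofloxacin	generic
cipro	ciprofloxacin	brand
colistin	colistin	generic
dexmedetomidine	dexmedetomidine	generic
precedex	dexmedetomidine	brand
digoxin	digoxin	generic
dobutamine	dobutamine	generic
dopamine	dopamine	generic
enoxaparin	enoxaparin	generic
lovenox	enoxaparin	brand
epinephrine	epinephrine	generic
fentanyl	fentanyl	generic
duragesic	fentanyl	brand
fluconazole	fluconazole	generic
diflucan	fluconazole	brand
furosemide	furosemide	generic
lasix	furosemide	brand
haloperidol	haloperidol	generic
haldol	haloperidol	brand
heparin	heparin	generic
hydrocortisone	hydrocortisone	generic
hydromorphone	hydromorphone	generic
dilaudid	hydromorphone	brand
hydroxychloroquine	hydroxychloroquine	generic
plaquenil	hydroxychloroquine	brand
insulin	insulin	generic
levofloxacin	levofloxacin	generic
levaquin	levofloxacin	brand
lidocaine	lidocaine	generic
linezolid	linezolid	generic
zyvox	linezolid	brand
lorazepam	lorazepam	generic
ativan	lorazepam	brand
meropenem	meropenem	generic
merrem	meropenem	brand
metoclopramide	metoclopramide	generic
reglan	metoclopramide	brand
metronidazole	metronidazole	generic
flagyl	metronidazole	brand
micafungin	micafungin	generic
mycamine	micafungin	brand
midazolam	midazolam	generic
versed	midazolam	brand
morphine	morphine	generic
norepinephrine	norepinephrine	generic
levophed	norepinephrine	brand
omeprazole	omeprazole	generic
prilosec	omeprazole	brand
ondansetron	ondansetron	generic
zofran	ondansetron	brand
oxycodone	oxycodone	generic
pantoprazole	pantoprazole	generic
protonix	pantoprazole	brand
penicillin	penicillin	generic
piperacillin	piperacillin	generic
piperacillin-tazobactam	piperacillin-tazobactam	generic
zosyn	piperacillin-tazobactam	brand
propofol	propofol	generic
diprivan	propofol	brand
rituximab	rituximab	generic
rituxan	rituximab	brand
scopolamine	scopolamine	generic
spironolactone	spironolactone	generic
aldactone	spironolactone	brand
tigecycline	tigecycline	generic
tygacil	tigecycline	brand
vancomycin	vancomycin	generic
vancocin	vancomycin	brand
vasopressin	vasopressin	generic
voriconazole	voriconazole	generic
vfend	voriconazole	brand
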