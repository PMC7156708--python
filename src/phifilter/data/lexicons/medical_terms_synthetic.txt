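# SYNTHETIC fixture: medical vocabulary standing in for terms extracted
# from standard medical word banks and ontologies, plus common clinical
# abbreviations. One token per line.
aspirin
metformin
lisinopril
atorvastatin
amlodipine
metoprolol
omeprazole
losartan
gabapentin
hydrochlorothiazide
sertraline
simvastatin
levothyroxine
azithromycin
amoxicillin
ibuprofen
acetaminophen
tylenol
insulin
warfarin
heparin
prednisone
albuterol
furosemide
pantoprazole
tramadol
oxycodone
morphine
ondansetron
ceftriaxone
vancomycin
ciprofloxacin
doxycycline
clopidogrel
apixaban
rivaroxaban
statin
antibiotic
antibiotics
analgesic
anticoagulant
diuretic
steroid
inhaler
vaccine
vaccination
hypertension
hypertensive
hypotension
diabetes
diabetic
mellitus
asthma
copd
pneumonia
bronchitis
anemia
sepsis
cellulitis
migraine
arthritis
osteoarthritis
osteoporosis
hyperlipidemia
hypothyroidism
hyperthyroidism
depression
anxiety
insomnia
gerd
reflux
ulcer
gastritis
colitis
hepatitis
cirrhosis
pancreatitis
nephropathy
neuropathy
retinopathy
dementia
delirium
stroke
infarction
ischemia
angina
arrhythmia
fibrillation
tachycardia
bradycardia
embolism
thrombosis
dvt
fracture
sprain
strain
laceration
contusion
abrasion
carcinoma
carcinomas
lymphoma
leukemia
melanoma
metastasis
metastatic
tumor
mass
cyst
polyp
nodule
lesion
lesions
head
neck
chest
thorax
abdomen
abdominal
pelvis
pelvic
spine
spinal
lumbar
cervical
thoracic
shoulder
elbow
wrist
hand
finger
fingers
hip
femur
tibia
fibula
ankle
foot
toe
toes
skull
brain
cerebral
heart
cardiac
coronary
lung
lungs
pulmonary
liver
hepatic
spleen
kidney
renal
bladder
colon
bowel
stomach
gastric
esophagus
pancreas
thyroid
adrenal
artery
arterial
vein
venous
vessel
vessels
muscle
muscular
tendon
ligament
joint
joints
bone
bones
rib
ribs
nerve
nerves
skin
dermal
mucosa
lymph
node
nodes
mrn
bp
hr
rr
temp
spo2
sao2
o2
wbc
rbc
hgb
hct
plt
platelets
sodium
potassium
chloride
bicarbonate
bun
creatinine
glucose
a1c
hba1c
inr
tsh
ldl
hdl
ast
alt
troponin
bilirubin
albumin
lactate
bid
tid
qid
qd
qhs
qam
prn
po
iv
im
sq
npo
cbc
bmp
cmp
ekg
ecg
echo
mri
ct
cxr
xray
ultrasound
uti
uri
chf
cad
ckd
esrd
afib
nad
heent
dx
hx
rx
sx
tx
fx
mg
mcg
g
kg
ml
l
cc
meq
mmol
iu
cm
mm
bpm
mmhg
auscultation
palpation
percussion
inspection
edema
erythema
tenderness
distension
guarding
rebound
murmur
rub
gallop
rales
rhonchi
wheezing
wheezes
crackles
stridor
cyanosis
clubbing
icterus
pallor
diaphoresis
pruritus
dyspnea
orthopnea
apnea
syncope
vertigo
tinnitus
diplopia
dysphagia
dysuria
hematuria
polyuria
nocturia
oliguria
melena
hematemesis
hemoptysis
epistaxis
diarrhea
constipation
anorexia
malaise
myalgia
arthralgia
paresthesia
ataxia
aphasia
dysarthria
hemiparesis
seizure
seizures
tremor
rigidity
reflex
reflexes
pupils
sclera
conjunctiva
oropharynx
tympanic
thyromegaly
lymphadenopathy
hepatomegaly
splenomegaly
bruit
pulses
capillary
refill
turgor
afebrile
febrile
tachypneic
bradycardic
normotensive
euvolemic
ambulating
ambulatory
intubated
extubated
sedated
anesthesia
anesthetic
biopsy
excision
resection
debridement
catheter
stent
graft
prosthesis
pacemaker
defibrillator
dialysis
transfusion
infusion
injection
immunization
screening
colonoscopy
endoscopy
bronchoscopy
radiograph
tomography
angiogram
mammogram
densitometry
spirometry
telemetry
titrate
titrated
taper
tapered
wean
weaned
admit
admission
discharge
disposition
transfer
transferred
consult
consultation
referral
referred
dr
drs
mr
mrs
ms
prof
lab
labs
fluid
fluids
gait
exam
exams
fax
id
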