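# Common / trivial chemical and drug names used by the synthetic-corpus
# generator and as a starter lexicon. One name per line.
aspirin
paracetamol
acetaminophen
ibuprofen
naproxen
diclofenac
caffeine
nicotine
morphine
codeine
heroin
cocaine
ethanol
methanol
glycerol
glucose
fructose
sucrose
lactose
maltose
galactose
cholesterol
cortisol
testosterone
estradiol
progesterone
insulin
adrenaline
epinephrine
noradrenaline
dopamine
serotonin
histamine
melatonin
glutamate
glycine
alanine
leucine
isoleucine
valine
proline
serine
threonine
cysteine
methionine
arginine
lysine
histidine
tyrosine
tryptophan
phenylalanine
asparagine
glutamine
urea
creatinine
bilirubin
heparin
warfarin
penicillin
amoxicillin
ampicillin
tetracycline
doxycycline
erythromycin
azithromycin
ciprofloxacin
gentamicin
vancomycin
rifampicin
isoniazid
metformin
glibenclamide
atorvastatin
simvastatin
pravastatin
lovastatin
omeprazole
ranitidine
cimetidine
loratadine
cetirizine
diphenhydramine
prednisone
prednisolone
dexamethasone
hydrocortisone
salbutamol
albuterol
theophylline
propranolol
atenolol
metoprolol
amlodipine
nifedipine
verapamil
diltiazem
captopril
enalapril
lisinopril
losartan
furosemide
hydrochlorothiazide
spironolactone
digoxin
amiodarone
lidocaine
ketamine
propofol
midazolam
diazepam
lorazepam
alprazolam
fluoxetine
sertraline
paroxetine
citalopram
venlafaxine
amitriptyline
imipramine
haloperidol
clozapine
olanzapine
risperidone
quetiapine
lithium
valproate
carbamazepine
phenytoin
lamotrigine
gabapentin
pregabalin
levodopa
methotrexate
cyclophosphamide
doxorubicin
cisplatin
carboplatin
paclitaxel
docetaxel
tamoxifen
gemcitabine
fluorouracil
vincristine
etoposide
imatinib
cyclosporine
tacrolimus
azathioprine
allopurinol
colchicine
chloroquine
quinine
artemisinin
ivermectin
acyclovir
zidovudine
ribavirin
oseltamivir
menthol
camphor
vanillin
capsaicin
curcumin
resveratrol
quercetin
taurine
carnitine
choline
thiamine
riboflavin
niacin
biotin
folate
retinol
tocopherol
ascorbate
calciferol
ubiquinone
lactate
pyruvate
citrate
acetate
oxalate
malate
fumarate
succinate
butyrate
propionate
formate
benzoate
salicylate
ammonia
acetone
benzene
toluene
xylene
phenol
chloroform
formaldehyde
acetaldehyde
glycerin
naphthalene
anthracene
pyridine
pyrimidine
purine
adenine
guanine
cytosine
thymine
uracil
inosine
adenosine
guanosine
cytidine
thymidine
uridine
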