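word,syllables,letters,category
accessibility,6,13,general
acetaminophen,6,13,treatment
activity,4,8,general
acupuncture,4,11,treatment
adjust,2,6,general
advise,2,6,general
affected,3,8,general
arthritis,3,9,general
arthroscopy,4,11,treatment
availability,6,12,general
avoid,2,5,general
awareness,4,9,general
balance,2,7,general
body,2,4,general
brace,1,5,general
bracing,2,7,treatment
cane,1,4,general
capsaicin,3,9,treatment
care,1,4,general
chair,1,5,general
chondroitin,3,11,treatment
cold,1,4,general
comfort,2,7,general
community,4,9,general
condition,3,9,general
consult,2,7,general
continue,2,8,general
cycling,2,7,general
daily,2,5,general
discomfort,3,10,general
discuss,2,7,general
doctor,2,6,general
duloxetine,4,10,treatment
education,4,9,general
evening,3,7,general
exercise,3,8,treatment
firm,1,4,general
flexibility,5,11,general
gentle,2,6,general
glucosamine,4,11,treatment
goals,1,5,general
habits,2,6,general
health,1,6,general
heat,1,4,general
help,1,4,general
hospital,3,8,general
hyaluronate,4,11,treatment
hydrotherapy,5,12,treatment
ibuprofen,4,9,treatment
ice,1,3,general
improve,2,7,general
improvement,4,11,general
individual,4,10,general
individually,5,12,general
inflammation,4,12,general
injection,3,9,general
joint,1,5,general
joints,1,6,general
knee,1,4,general
knees,1,5,general
leg,1,3,general
level,2,5,general
limitation,4,10,general
maintain,2,8,general
manage,2,6,general
management,4,10,general
massage,2,7,treatment
medication,4,10,general
medicine,3,8,general
mild,1,4,general
mobility,4,8,general
monitor,3,7,general
morning,2,7,general
move,1,4,general
muscle,2,6,general
muscles,2,7,general
naproxen,3,8,treatment
opioids,2,7,treatment
pain,1,4,general
painful,2,7,general
participation,5,13,general
patient,2,7,general
plan,1,4,general
posture,2,7,general
practice,2,8,general
prevention,3,10,general
protect,2,7,general
recommendation,5,14,general
recovery,4,8,general
reduce,2,6,general
rehabilitation,6,14,general
relaxation,4,10,general
rest,1,4,general
safe,1,4,general
shoes,1,5,general
sleep,1,5,general
slow,1,4,general
stairs,1,6,general
step,1,4,general
stick,1,5,general
stiff,1,5,general
stiffness,2,9,general
strength,1,8,general
strengthen,2,10,general
stretch,1,7,general
stretching,2,10,treatment
strong,1,6,general
stronger,2,8,general
support,2,7,general
swell,1,5,general
swelling,2,8,general
swimming,2,8,general
symptom,2,7,general
symptoms,2,8,general
therapy,3,7,general
tissue,1,6,general
track,1,5,general
tramadol,3,8,treatment
treatment,2,9,general
treatments,2,10,general
university,5,10,general
walk,1,4,general
walking,2,7,general
warm,1,4,general
water,2,5,general
weekly,2,6,general
weight,1,6,general
yoga,2,4,treatment
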