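term,category
atria ann arbor,INSTITUTION
gilbert residence,INSTITUTION
glacier hills,INSTITUTION
heartland health care center,INSTITUTION
linden square,INSTITUTION
care giver,FORMAL
caregiver,FORMAL
guardian,FORMAL
home care,FORMAL
home health,FORMAL
visiting nurse,FORMAL
daughter,INFORMAL
family,INFORMAL
father,INFORMAL
friend,INFORMAL
husband,INFORMAL
mother,INFORMAL
sister,INFORMAL
son,INFORMAL
spouse,INFORMAL
wife,INFORMAL
patient,PATIENT_TERM
patient's,PATIENT_TERM
pt,PATIENT_TERM
agreed,PATIENT_VERB
asked,PATIENT_VERB
reported,PATIENT_VERB
approve,INSTITUTION_NEGATION
cancel,INSTITUTION_NEGATION
decline,INSTITUTION_NEGATION
discharged from,INSTITUTION_NEGATION
rehab,INSTITUTION_NEGATION
rehabilitation,INSTITUTION_NEGATION
request,INSTITUTION_NEGATION
require,INSTITUTION_NEGATION
return from,INSTITUTION_NEGATION
suggest,INSTITUTION_NEGATION
waiting list,INSTITUTION_NEGATION
visit,VISIT_VARIANT
visiting,VISIT_VARIANT
visited,VISIT_VARIANT
visits,VISIT_VARIANT
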