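vocabulary,code,description,category,disease_domain
snomed,22298006,acute myocardial infarction,diagnosis,CaVD
snomed,194828000,angina pectoris,diagnosis,CaVD
snomed,194842008,unstable angina,diagnosis,CaVD
snomed,84114007,heart failure,diagnosis,CaVD
snomed,42343007,congestive heart failure,diagnosis,CaVD
snomed,29857009,chest pain,symptom,CaVD
snomed,371807002,chest oppression,symptom,CaVD
snomed,53741008,coronary arteriosclerosis,diagnosis,CaVD
snomed,232717009,coronary artery bypass grafting,procedure,CaVD
snomed,41339005,coronary angioplasty,procedure,CaVD
snomed,400047006,peripheral vascular disease,diagnosis,CaVD
snomed,63491006,intermittent claudication,symptom,CaVD
snomed,233958001,aortic aneurysm without rupture,diagnosis,CaVD
snomed,410429000,cardiac arrest,diagnosis,CaVD
snomed,268980006,myocardial ischemia on resting ECG,sign,CaVD
icd10,I21,ST elevation myocardial infarction,diagnosis,CaVD
icd10,I50,heart failure unspecified,diagnosis,CaVD
icd10,I73.9,peripheral vascular disease unspecified,diagnosis,CaVD
icpc2,K74,ischaemic heart disease with angina,diagnosis,CaVD
icpc2,K75,acute myocardial infarction in primary care,diagnosis,CaVD
icpc2,K77,heart failure in primary care,diagnosis,CaVD
icpc2,K92,peripheral vascular disease in primary care,diagnosis,CaVD
local,HIBA-0021,myocardial infarction sequela local term,diagnosis,CaVD
local,HIBA-0055,AMI sequela shorthand,diagnosis,CaVD
local,HIBA-0056,pump failure shorthand,diagnosis,CaVD
local,HIBA-0057,leg artery disease shorthand,diagnosis,CaVD
local,HIBA-0058,heart attack colloquial entry,diagnosis,CaVD
icpc2,K02,pressure or tightness of heart region,symptom,CaVD
snomed,230690007,cerebrovascular accident,diagnosis,CeVD
snomed,266257000,transient ischemic attack,diagnosis,CeVD
snomed,371041009,embolic stroke,diagnosis,CeVD
snomed,274100004,cerebral hemorrhage,diagnosis,CeVD
snomed,432504007,cerebral infarction,diagnosis,CeVD
snomed,371039008,silent cerebral infarct on imaging,sign,CeVD
icd10,I63,cerebral infarction ICD entry,diagnosis,CeVD
icd10,I64,stroke not specified as haemorrhage or infarction,diagnosis,CeVD
icd10,G45,transient cerebral ischaemia,diagnosis,CeVD
icpc2,K90,stroke or cerebrovascular accident primary care,diagnosis,CeVD
icpc2,K89,transient cerebral ischaemia primary care,diagnosis,CeVD
snomed,51416004,carotid artery stenosis,diagnosis,CeVD
snomed,66951008,carotid endarterectomy,procedure,CeVD
snomed,50582007,hemiparesis,sign,CeVD
local,HIBA-0102,stroke sequela local term,diagnosis,CeVD
snomed,8011004,dysarthria,sign,CeVD
snomed,25133001,amaurosis fugax,symptom,CeVD
local,HIBA-0103,ACV sequela shorthand,diagnosis,CeVD
local,HIBA-0104,brain attack colloquial entry,diagnosis,CeVD
snomed,95455008,lacunar syndrome on imaging,sign,CeVD
snomed,38716007,generalized atherosclerosis,diagnosis,both
icd10,I70,atherosclerosis,diagnosis,both
local,HIBA-0300,vascular surgery follow-up local term,procedure,both
snomed,445038001,coronary artery calcification incidental imaging finding,sign,CaVD
snomed,195967001,asthma,diagnosis,none
snomed,44054006,type 2 diabetes mellitus,diagnosis,none
snomed,396275006,osteoarthritis of knee,diagnosis,none
snomed,35489007,depressive disorder,diagnosis,none
icd10,K21,gastro-oesophageal reflux disease,diagnosis,none
icd10,N39.0,urinary tract infection,diagnosis,none
icpc2,L03,low back symptom,symptom,none
snomed,37796009,migraine,diagnosis,none
icpc2,R97,allergic rhinitis,diagnosis,none
icd10,J18,pneumonia unspecified,diagnosis,none
snomed,38341003,hypertensive disorder,diagnosis,none
snomed,13644009,hypercholesterolemia,diagnosis,none
local,HIBA-0900,annual health check,procedure,none
snomed,271737000,anemia,diagnosis,none
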