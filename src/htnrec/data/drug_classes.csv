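code,name,ingredient,drug_class,unit_dose_mg
100001,lisinopril 10 mg tablet,lisinopril,ACEi,10
100002,lisinopril 20 mg tablet,lisinopril,ACEi,20
100003,enalapril 10 mg tablet,enalapril,ACEi,10
100011,losartan 50 mg tablet,losartan,ARB,50
100012,losartan 100 mg tablet,losartan,ARB,100
100013,valsartan 160 mg tablet,valsartan,ARB,160
100021,hydrochlorothiazide 12.5 mg tablet,hydrochlorothiazide,thiazide,12.5
100022,hydrochlorothiazide 25 mg tablet,hydrochlorothiazide,thiazide,25
100023,chlorthalidone 25 mg tablet,chlorthalidone,thiazide,25
100031,amlodipine 5 mg tablet,amlodipine,CCB,5
100032,amlodipine 10 mg tablet,amlodipine,CCB,10
100033,diltiazem 120 mg capsule,diltiazem,CCB,120
100041,metoprolol 50 mg tablet,metoprolol,beta-blocker,50
100042,metoprolol 100 mg tablet,metoprolol,beta-blocker,100
100043,atenolol 50 mg tablet,atenolol,beta-blocker,50
100051,clonidine 0.2 mg tablet,clonidine,other,0.2
100052,hydralazine 50 mg tablet,hydralazine,other,50
100053,doxazosin 4 mg tablet,doxazosin,other,4
100061,lisinopril-hydrochlorothiazide 10-12.5 mg tablet,lisinopril,ACEi,10
100061,lisinopril-hydrochlorothiazide 10-12.5 mg tablet,hydrochlorothiazide,thiazide,12.5
100062,lisinopril-hydrochlorothiazide 20-25 mg tablet,lisinopril,ACEi,20
100062,lisinopril-hydrochlorothiazide 20-25 mg tablet,hydrochlorothiazide,thiazide,25
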