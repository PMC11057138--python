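actor_id,display_code,role,level,organization,university,is_respondent
FA01,FA01,faculty,none,,Tehran UMS,true
FA02,FA02,faculty,none,,Tehran UMS,true
FA03,FA03,faculty,none,,Isfahan UMS,true
FA04,FA04,faculty,none,,Shiraz UMS,true
FA05,FA05,faculty,none,,Mashhad UMS,true
FA06,FA06,faculty,none,,Tabriz UMS,false
PM01,PN01,policymaker,national,MOHME,,false
PM02,PN02,policymaker,national,National Institute of Health Research,,false
PM03,PP01,policymaker,provincial,Provincial Health Center,,false
PM04,PU01,policymaker,university,Tehran UMS,,false
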