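respondent_id,target_id,category,initiator,mode
FA01,PM01,direct_to_pm,policymaker,face_to_face
FA01,PM02,direct_to_pm,researcher,other
FA01,FA02,via_peer,researcher,face_to_face
FA02,PM01,direct_to_pm,policymaker,face_to_face
FA02,FA01,via_peer,third_party,face_to_face
FA03,PM03,direct_to_pm,policymaker,other
FA03,FA06,via_peer,researcher,face_to_face
FA04,PM04,direct_to_pm,policymaker,face_to_face
FA04,FA06,broker_for_peer,researcher,face_to_face
FA05,PM01,direct_to_pm,policymaker,face_to_face
FA05,FA03,broker_for_peer,policymaker,other
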