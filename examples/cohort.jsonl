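{"patient_id":"example-001","visits":[{"date":"2017-03-02","codes":[{"system":"ICD9","value":"64883","modality":"diagnosis"},{"system":"LOINC","value":"18481-2","modality":"lab"}]},{"date":"2017-08-15","codes":[{"system":"ICD9","value":"64403","modality":"diagnosis"},{"system":"NDC","value":"00071015523","modality":"medication"}]},{"date":"2017-10-01","codes":[{"system":"ICD9","value":"64421","modality":"diagnosis"}]}],"delivery_date":"2017-10-01","pregnancy_start_date":"2017-01-04","label":1}
{"patient_id":"example-002","visits":[{"date":"2016-11-20","codes":[{"system":"ICD9","value":"V220","modality":"diagnosis"}]},{"date":"2017-02-08","codes":[{"system":"ICD9","value":"4019","modality":"diagnosis"},{"system":"NDC","value":"00093505698","modality":"medication"}]},{"date":"2017-06-30","codes":[{"system":"ICD9","value":"650","modality":"diagnosis"}]}],"delivery_date":"2017-06-30","pregnancy_start_date":"2016-09-27","label":0}
{"patient_id":"example-003","visits":[{"date":"2018-01-05","codes":[{"system":"ICD9","value":"462","modality":"diagnosis"},{"system":"LOINC","value":"6559-4","modality":"lab"}]},{"date":"2018-05-22","codes":[{"system":"ICD9","value":"64511","modality":"diagnosis"}]}],"delivery_date":"2018-05-22","pregnancy_start_date":"2017-08-25","label":0}
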