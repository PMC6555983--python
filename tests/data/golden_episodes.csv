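patient_id,line,agent,start_date,end_date,coverage_end,n_claims,end_reason
P001,1,sunitinib,2012-03-01,2012-05-30,2012-05-30,3,discontinuation
P002,1,sunitinib,2012-03-01,2012-07-09,2012-07-09,2,discontinuation
P003,1,sunitinib,2012-03-01,2012-03-31,2012-03-31,1,switch
P003,2,sunitinib,2012-07-29,2012-08-28,2012-08-28,1,discontinuation
P004,1,sunitinib,2012-03-01,2012-03-31,2012-03-31,1,switch
P004,2,pazopanib,2012-06-29,2012-08-28,2012-08-28,2,discontinuation
P006,1,pazopanib,2012-03-21,2012-05-20,2012-05-20,2,discontinuation
P007,1,bevacizumab+ifn_alfa,2012-03-01,2012-04-18,2012-04-18,3,discontinuation
P008,1,sunitinib,2012-03-01,2012-09-27,2012-09-27,7,censored
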