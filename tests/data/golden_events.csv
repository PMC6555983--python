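patient_id,endpoint,time_days,event
P001,duration,90,True
P001,tt2t,90,False
P002,duration,130,True
P002,tt2t,130,False
P003,duration,30,True
P003,tt2t,150,True
P004,duration,30,True
P004,tt2t,120,True
P006,duration,60,True
P006,tt2t,60,False
P007,duration,48,True
P007,tt2t,48,False
P008,duration,250,False
P008,tt2t,210,False
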