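patient_id,location,dim_a_cm,dim_b_cm,dim_c_cm,suv_max,suv_mean,visible
ID01,Pubic bone,,,,10.1,5.7,N
ID01,Bladder wall,2.8,1.3,1.7,15.9,9.0,N
ID01,Seminal vesicle,1.2,0.8,1.0,10.6,6.2,N
ID02,Sternum,,,,28.6,14.7,N
ID02,Rib,,,,30.9,20.6,N
ID02,Vertebra,,,,18.9,11.3,N
ID03,"Lymph node, retrocaval",1.1,1.4,1.6,77.4,45.0,Y
ID03,Rib,,,,17.4,11.1,N
ID03,Vertebra,,,,13.6,8.0,N
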