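child_id,age_y,weight_kg,height_cm,ttma_mg_L,below_loq,creatinine_g_L,acr_mg_g,acr_normal
C01,6.0,21.0,116.0,0.0013,True,0.7,12.0,True
C02,7.0,24.2,121.7,0.0039,True,0.72,15.0,True
C03,8.0,27.4,127.4,0.0065,True,0.74,18.0,True
C04,9.0,30.6,133.1,0.0091,True,0.76,21.0,True
C05,10.0,33.8,138.8,0.0117,True,0.78,24.0,True
C06,11.0,37.0,144.5,0.0143,True,0.8,12.0,True
C07,12.0,40.2,150.2,0.017,True,0.82,15.0,True
C08,6.0,21.0,116.0,0.0196,True,0.84,18.0,True
C09,7.0,24.2,121.7,0.0222,True,0.86,21.0,True
C10,8.0,27.4,127.4,0.0248,True,0.88,24.0,True
C11,9.0,30.6,133.1,0.0274,True,0.9,12.0,True
C12,10.0,33.8,138.8,0.03,True,0.92,15.0,True
C13,11.0,37.0,144.5,0.0326,True,0.94,18.0,True
C14,12.0,40.2,150.2,0.0352,True,0.96,21.0,True
C15,6.0,21.0,116.0,0.0378,True,0.98,24.0,True
C16,7.0,24.2,121.7,0.0404,True,1.0,12.0,True
C17,8.0,27.4,127.4,0.043,True,1.02,15.0,True
C18,9.0,30.6,133.1,0.0457,True,1.04,18.0,True
C19,10.0,33.8,138.8,0.0483,True,1.06,21.0,True
C20,11.0,37.0,144.5,0.0509,True,1.08,24.0,True
C21,12.0,40.2,150.2,0.0535,True,0.7,12.0,True
C22,6.0,21.0,116.0,0.0561,True,0.72,15.0,True
C23,7.0,24.2,121.7,0.0587,True,0.74,18.0,True
C24,8.0,27.4,127.4,0.42,False,0.76,75.0,False
C25,9.0,30.6,133.1,0.95,False,0.78,45.0,False
C26,10.0,33.8,138.8,1.6,False,0.8,60.0,False
C27,11.0,37.0,144.5,0.086,False,0.82,15.0,True
C28,12.0,40.2,150.2,0.149,False,0.84,18.0,True
C29,6.0,21.0,116.0,0.203,False,0.86,21.0,True
C30,7.0,24.2,121.7,0.257,False,0.88,24.0,True
C31,8.0,27.4,127.4,0.315,False,0.9,12.0,True
C32,9.0,30.6,133.1,0.377,False,0.92,15.0,True
C33,10.0,33.8,138.8,0.447,False,0.94,18.0,True
C34,11.0,37.0,144.5,0.528,False,0.96,21.0,True
C35,12.0,40.2,150.2,0.623,False,0.98,24.0,True
C36,6.0,21.0,116.0,0.738,False,1.0,12.0,True
C37,7.0,24.2,121.7,0.885,False,1.02,15.0,True
C38,8.0,27.4,127.4,1.082,False,1.04,18.0,True
C39,9.0,30.6,133.1,1.37,False,1.06,21.0,True
C40,10.0,33.8,138.8,1.868,False,1.08,24.0,True
C41,11.0,37.0,144.5,3.221,False,0.7,12.0,True
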