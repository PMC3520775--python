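species,region,variant,ofv,vbr1,vbr2,qin,qout,qbr,resid_brain,eff_se,eff_tq_3,eff_tq_15,eff_tq_2,eff_scan
rat,WB,tq_window_excluded,-604,0.132,2,5.48,3.56,0.115,0.404,1.84,0.219,0.168,,
rat,WB,all_data,-1676,0.132,2,5.62,3.60,0.115,0.382,1.84,0.161,0.135,,1.33
rat,CS,all_data,-1420,0.119,2,2.05,3.45,0.114,0.44,1.88,0.114,0.101,,1.29
rat,EC,all_data,-1652,0.155,2,3.32,3.91,0.111,0.387,1.73,0.233,0.215,,1.37
rat,SHipp,all_data,-1500,0.151,2,2.49,4.56,0.113,0.421,1.86,0.119,0.101,,1.29
rat,THipp,all_data,-954,0.129,2,1.98,2.99,0.108,0.571,2.21,0.15,0.134,,1.25
rat,Th,all_data,-1559,0.156,2,2.43,4.39,0.129,0.016,1.77,0.12,0.103,,1.21
rat,Cer,all_data,-1562,0.192,2,2.44,3.01,0.118,0.407,0.924,0.226,0.148,,1.52
rat,FMC,all_data,-1365,0.088,2,1.79,1.97,0.12,0.454,2.3,0.194,0.155,,1.4
human,WB,tq_window_excluded,7799,2.29,13.0,713,1410,1.26,0.295,,,,0.993,
human,WB,all_data,-357,3.17,18.4,588,1080,1.71,0.27,,,,0.483,2.28
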