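id,age,sex,weight,height,scr,cysc,"aMDRD","CKD-EPI-cr","CKD-EPI-cy","CKD-EPI-cr-cy","Cockcroft-Gault","FAS-cr","FAS-cy","FAS-cr-cy","Lund-Malmö (Rv)","Grubb-2014 (CAPA)","Hoek","Larsson"
P1,35,male,85,182,0.9,0.85,114.6229,131.6188,127.3030,129.5080,137.7315,128.0781,123.5577,125.7773,111.4430,113.4350,107.6780,94.8280
P2,52,female,64,160,1.3,1.4,41.4511,45.4179,46.1246,44.9796,51.1453,48.1694,52.3965,50.1941,44.5458,48.3215,51.1454,50.5109
P3,68,male,78,175,2.8,2.6,25.3327,24.8025,23.6793,23.4842,27.8571,27.5132,26.9959,27.2521,23.3555,24.1292,29.7359,23.1218
P4,29,female,55,152,0.6,0.7,102.8963,107.2338,102.6922,107.5691,120.1215,108.9827,109.4275,109.2046,94.7556,105.6550,96.1697,121.1644
P5,45,male,95,178,5.5,3.9,13.9144,14.1881,16.6839,14.4934,22.7904,20.3550,26.1542,22.8931,16.5164,15.3174,20.0507,13.8593
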