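T_K,P_MPa,rho_kg_m3,y2,sd_y2,S_g_L
308,12,769,8.14e-06,2.1e-07,0.0643
308,15,817,1.266e-05,4.2e-07,0.1060
308,18,849,1.327e-05,1.0e-07,0.1156
308,21,875,1.411e-05,5.1e-07,0.1265
308,24,896,1.501e-05,6.3e-07,0.1378
308,27,914,1.806e-05,7.1e-07,0.1692
318,12,661,7.06e-06,2.3e-07,0.0479
318,15,744,1.182e-05,3.1e-07,0.0901
318,18,791,1.515e-05,3.2e-07,0.1228
318,21,824,1.601e-05,4.1e-07,0.1353
318,24,851,2.040e-05,6.4e-07,0.1812
318,27,872,2.079e-05,9.3e-07,0.1858
328,12,509,6.11e-06,3.1e-07,0.0319
328,15,656,1.044e-05,2.3e-07,0.0702
328,18,725,1.620e-05,3.2e-07,0.1203
328,21,769,1.860e-05,4.2e-07,0.1467
328,24,802,2.248e-05,9.1e-07,0.1849
328,27,829,2.260e-05,2.1e-07,0.1920
338,12,388,5.14e-06,2.3e-07,0.0204
338,15,557,9.28e-06,1.1e-07,0.0530
338,18,652,2.002e-05,1.01e-06,0.1338
338,21,710,2.266e-05,1.12e-06,0.1650
338,24,751,2.637e-05,1.03e-06,0.2030
338,27,783,2.590e-05,9.1e-07,0.2079
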