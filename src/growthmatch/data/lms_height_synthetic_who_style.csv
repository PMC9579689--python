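sex,age_years,L,M,S
M,2,1,87.1,0.03904
M,3,1,96.1,0.03954
M,4,1,103.3,0.04163
M,5,1,110.0,0.04364
M,6,1,116.0,0.04310
M,7,1,121.7,0.04355
M,8,1,127.3,0.04399
M,9,1,132.6,0.04450
M,10,1,137.8,0.04499
M,11,1,143.1,0.04542
M,12,1,149.1,0.04695
M,13,1,156.0,0.04872
M,14,1,163.2,0.04779
M,15,1,169.0,0.04497
M,16,1,172.9,0.04222
M,17,1,175.2,0.04052
M,18,1,176.1,0.03975
M,19,1,176.5,0.03966
M,20,1,176.7,0.03962
M,21,1,176.8,0.03959
F,2,1,85.7,0.04084
F,3,1,95.1,0.04101
F,4,1,102.7,0.04284
F,5,1,109.4,0.04388
F,6,1,115.1,0.04344
F,7,1,120.8,0.04387
F,8,1,126.6,0.04502
F,9,1,132.5,0.04604
F,10,1,138.6,0.04690
F,11,1,145.0,0.04759
F,12,1,151.2,0.04696
F,13,1,156.4,0.04412
F,14,1,159.8,0.04068
F,15,1,161.7,0.03896
F,16,1,162.5,0.03815
F,17,1,162.9,0.03745
F,18,1,163.1,0.03740
F,19,1,163.2,0.03738
F,20,1,163.3,0.03735
F,21,1,163.3,0.03735
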