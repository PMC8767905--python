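genotype,role,Yp,Ys,RDY,RT
P1823-12-4,NIL,13.0,7.5,0.42,73.3
P1823-12-21,NIL,7.5,6.0,0.20,25.0
P1823-12-23,NIL,10.0,4.0,0.60,150.0
P1823-12-32,NIL,8.0,6.5,0.19,23.1
P1823-12-36,NIL,10.5,6.5,0.38,61.5
P1823-12-42,NIL,7.5,5.5,0.27,36.4
P1823-12-44,NIL,8.0,6.0,0.25,33.3
P1823-12-48,NIL,10.5,4.0,0.62,163.0
P1823-12-49,NIL,14.0,8.5,0.39,64.7
P1823-12-50,NIL,13.5,9.0,0.33,50.0
P1823-12-63,NIL,11.5,4.5,0.61,156.0
P1823-12-64,NIL,9.0,3.0,0.67,200.0
P1823-12-65,NIL,11.0,3.0,0.73,267.0
P1823-12-77,NIL,8.5,6.0,0.29,41.7
P1823-12-79,NIL,9.0,8.0,0.11,12.5
P1823-12-80,NIL,7.5,4.0,0.47,87.5
P1823-12-81,NIL,9.5,7.5,0.21,26.7
P1823-12-82,NIL,11.5,8.5,0.26,35.3
P1823-12-84,NIL,9.0,5.0,0.44,80.0
P1823-12-89,NIL,9.5,9.5,0.00,0.0
P1823-12-96,NIL,11.0,8.0,0.27,37.5
P1823-12-98,NIL,12.5,8.5,0.32,47.1
P1823-12-104,NIL,10.0,9.0,0.10,11.1
P1823-12-114,NIL,12.0,5.5,0.54,118.0
P1823-12-118,NIL,8.5,5.5,0.35,54.5
P1823-12-120,NIL,12.0,9.5,0.21,26.3
P1823-12-122,NIL,9.0,8.5,0.06,5.9
P1823-12-123,NIL,11.5,9.0,0.22,27.8
P1823-12-124,NIL,12.5,8.0,0.36,56.3
P1823-12-127,NIL,8.0,4.5,0.44,77.8
P1823-12-130,NIL,8.5,6.5,0.24,30.8
P1823-12-132,NIL,8.5,6.5,0.24,30.8
P1823-12-134,NIL,7.5,6.0,0.20,25.0
P1823-12-141,NIL,8.5,3.6,0.58,136.0
P1823-12-143,NIL,9.0,7.5,0.17,20.0
Pusa 44,RP,8.0,2.3,0.71,256.0
IR81896-B-B-142,DP,8.5,4.3,0.49,100.0
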