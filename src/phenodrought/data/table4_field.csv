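genotype,role,Yp,Ys,TOL,MP,GMP,SSI,STI,YI,YSI
Pusa 44,RP,22.2,10.9,11.4,16.6,15.6,1.6,0.4,0.7,0.5
IR81896-B-B-142,DP,22.4,15.2,7.2,18.8,18.4,1.0,0.6,0.9,0.7
P1823-12-4,NIL,25.2,21.1,4.0,23.2,23.1,0.5,0.9,1.3,0.8
P1823-12-21,NIL,19.5,15.7,3.7,17.6,17.5,0.6,0.5,1.0,0.8
P1823-12-23,NIL,29.0,21.7,7.3,25.3,25.1,0.8,1.0,1.3,0.8
P1823-12-32,NIL,29.6,14.0,15.6,21.8,20.4,1.6,0.7,0.9,0.5
P1823-12-36,NIL,28.7,18.6,10.0,23.6,23.1,1.1,0.9,1.1,0.7
P1823-12-42,NIL,29.6,19.9,9.7,24.8,24.3,1.0,1.0,1.2,0.7
P1823-12-44,NIL,25.8,16.4,9.4,21.1,20.6,1.1,0.7,1.0,0.6
P1823-12-48,NIL,24.0,16.6,7.5,20.3,19.9,1.0,0.7,1.0,0.7
P1823-12-49,NIL,27.6,21.2,6.4,24.4,24.2,0.7,1.0,1.3,0.8
P1823-12-50,NIL,22.9,17.2,5.7,20.1,19.8,0.8,0.7,1.0,0.8
P1823-12-63,NIL,20.8,15.5,5.3,18.2,18.0,0.8,0.5,0.9,0.7
P1823-12-64,NIL,30.7,14.0,16.7,22.3,20.7,1.7,0.7,0.8,0.5
P1823-12-65,NIL,29.6,20.8,8.8,25.2,24.8,0.9,1.0,1.3,0.7
P1823-12-77,NIL,25.3,11.5,13.8,18.4,17.1,1.7,0.5,0.7,0.5
P1823-12-79,NIL,33.6,18.7,15.0,26.2,25.1,1.4,1.0,1.1,0.6
P1823-12-80,NIL,24.3,14.5,9.8,19.4,18.7,1.2,0.6,0.9,0.6
P1823-12-81,NIL,29.5,18.3,11.2,23.9,23.3,1.2,0.9,1.1,0.6
P1823-12-82,NIL,24.5,19.3,5.2,21.9,21.8,0.7,0.8,1.2,0.8
P1823-12-84,NIL,16.5,11.6,4.9,14.01,13.8,0.9,0.3,0.7,0.7
P1823-12-89,NIL,27.8,13.2,14.6,20.5,19.1,1.6,0.6,0.8,0.5
P1823-12-96,NIL,21.4,17.1,4.3,19.2,19.1,0.6,0.6,1.0,0.8
P1823-12-98,NIL,24.2,19.6,4.6,21.9,21.8,0.6,0.8,1.2,0.8
P1823-12-104,NIL,17.5,12.7,4.8,15.1,14.9,0.8,0.4,0.8,0.7
P1823-12-114,NIL,20.0,18.5,1.5,19.2,19.2,0.2,0.6,1.1,0.9
P1823-12-118,NIL,31.0,16.1,14.9,23.5,22.3,1.5,0.8,1.0,0.5
P1823-12-120,NIL,32.2,21.5,10.7,26.83,26.3,1.0,1.1,1.3,0.7
P1823-12-122,NIL,22.6,17.7,4.9,20.1,20.0,0.7,0.7,1.1,0.8
P1823-12-123,NIL,23.8,14.0,9.8,18.9,18.3,1.3,0.6,0.8,0.6
P1823-12-124,NIL,25.1,19.1,6.0,22.1,21.9,0.7,0.8,1.2,0.8
P1823-12-127,NIL,20.0,17.9,2.1,19.0,18.9,0.3,0.6,1.1,0.9
P1823-12-130,NIL,22.2,19.8,2.4,21.0,21.0,0.3,0.7,1.2,0.9
P1823-12-132,NIL,26.8,19.6,7.2,23.2,23.0,0.8,0.9,1.2,0.7
P1823-12-134,NIL,20.4,14.0,6.4,17.2,16.9,1.0,0.5,0.9,0.7
P1823-12-141,NIL,16.8,8.0,8.8,12.4,11.6,1.6,0.2,0.5,0.5
P1823-12-143,NIL,20.5,13.4,7.2,17.0,16.6,1.1,0.5,0.9,0.7
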