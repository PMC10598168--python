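participant,age_years,sex,side,metalwork,prior_operation,interval_days,angle_delta_deg
1,52,Female,Left,No,,122,-12.4
2,69,Female,Left,Yes,Left 1st metatarsophalangeal joint fusion,119,-6.1
3,53,Female,Left,No,,51,5.2
4,53,Female,Right,Yes,Right 1st tarsometatarsal joint fusion,70,3.4
5,29,Female,Right,No,,45,-4.1
6,33,Male,Right,No,,45,0.9
7,58,Female,Left,Opposite,Right talocrural joint fusion,63,-7.9
8,49,Female,Right,Yes,Right calcaneal screw fracture fixation,77,5.8
9,73,Female,Right,No,,83,13.9
10,62,Male,Right,Opposite,Left talonavicular joint fusion,105,-5.8
11,72,Male,Left,Yes,Left calcaneal osteotomy and 1st tarsometatarsal joint fusion,121,-12.7
12,42,Female,Right,No,,98,17.5
13,67,Female,Left,Opposite,Right anterior subtalar facet and naviculocuneiform joint fusions,88,-20.4
14,46,Female,Right,No,,58,16.2
15,74,Female,Right,Yes,Right tarsometatarsal joint fusions,42,-5.9
16,43,Male,Right,Yes,Right distal fibular fixation,93,-1.6
17,48,Female,Left,No,,108,-1.4
18,23,Male,Left,No,,54,2.0
19,52,Male,Left,No,,42,-5.7
20,46,Female,Left,Opposite,Right talocrural joint fusion,15,8.9
21,64,Male,Left,No,,42,-5.4
22,69,Female,Left,Yes,Right naviculocuneiform joint fusion,92,3.1
23,34,Female,Left,No,,70,-2.7
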