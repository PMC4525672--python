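# Conducting-airway geometry and static pressure-area constants per
# generation (symmetric tree, generations 0-16), after Lambert et al.
# l_cm: airway length (cm); d_cm: reference airway diameter (cm);
# alpha0: normalized lumen area at zero transmural pressure;
# alpha0_prime_e3_per_pa: normalized compliance at zero transmural
# pressure (1e-3 / Pa); n1, n2: sigmoid exponents; Am_cm2: maximal lumen
# area summed over the 2^z airways of the generation (cm^2).
z,l_cm,d_cm,alpha0,alpha0_prime_e3_per_pa,n1,n2,Am_cm2
0,12.00,1.671,0.882,1.1,0.5,10.00,2.37
1,4.76,1.1815,0.882,1.1,0.5,10.00,2.37
2,1.90,0.8735,0.686,5.1,0.6,10.00,2.80
3,0.76,0.670,0.546,8.0,0.6,10.00,3.50
4,1.27,0.525,0.450,10.0,0.7,10.00,4.50
5,1.07,0.399,0.370,12.5,0.8,10.00,5.30
6,0.90,0.3095,0.310,14.2,0.9,10.00,6.50
7,0.76,0.241,0.255,15.9,1.00,10.00,8.00
8,0.64,0.192,0.213,17.4,1.00,10.00,10.20
9,0.54,0.151,0.184,18.4,1.00,10.00,12.70
10,0.47,0.119,0.153,19.4,1.00,10.00,15.94
11,0.39,0.096,0.125,20.6,1.00,9.00,20.70
12,0.33,0.080,0.100,21.8,1.00,8.00,28.80
13,0.27,0.070,0.075,22.6,1.00,8.00,44.50
14,0.23,0.0615,0.057,23.3,1.00,8.00,69.40
15,0.20,0.055,0.045,23.9,1.00,7.00,113.00
16,0.17,0.0495,0.039,24.3,1.00,7.00,180.00
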