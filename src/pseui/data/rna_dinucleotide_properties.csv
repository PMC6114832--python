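dinucleotide,free_energy,hydrophilicity,stacking_energy
AA,-0.930,0.040,-13.700
AC,-2.240,0.140,-13.800
AG,-2.080,0.080,-14.000
AU,-1.100,0.140,-15.400
CA,-2.110,0.210,-14.400
CC,-3.260,0.490,-11.100
CG,-2.360,0.350,-15.600
CU,-2.080,0.520,-14.000
GA,-2.350,0.100,-14.200
GC,-3.420,0.260,-16.900
GG,-3.260,0.170,-11.100
GU,-2.240,0.270,-13.800
UA,-1.330,0.210,-16.000
UC,-2.350,0.480,-14.200
UG,-2.110,0.340,-14.400
UU,-0.930,0.440,-13.700
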