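# Group-contribution coefficients for Hildebrand/Hansen solubility parameter
# estimation by the Fedors and Hoftyzer-Van Krevelen (HVK) methods.
# Columns:
#   name    token used by decompositions
#   formula atomic formula contributed by one occurrence (empty for corrections)
#   dEv     Fedors vaporization-energy contribution, J/mol
#   V       molar-volume contribution, cm3/mol (shared by both methods; may be
#           negative for branch/correction entries)
#   Fd      HVK dispersion molar attraction, (J cm3)^0.5 / mol
#   Fp      HVK polar molar attraction, (J cm3)^0.5 / mol
#   Eh      HVK hydrogen-bond energy, J/mol
# Aliphatic/olefinic/aromatic carbon, oxygen, nitrogen and halogen rows carry the
# canonical Fedors (1974) and Hoftyzer-Van Krevelen coefficients.  Rows marked
# "extended" (CF3, SO2, CON<, OH_adj) vary between published compilations; the
# shipped values are the extended-compilation variants consistent with the
# celecoxib / PVP-VA reference parameters (see docs/methods.md).
name,formula,dEv,V,Fd,Fp,Eh
CH3,CH3,4710,33.5,420,0,0
CH2,CH2,4940,16.1,270,0,0
CH,CH,3430,-1.0,80,0,0
C,C,1470,-19.2,-70,0,0
=CH2,CH2,4310,28.5,400,0,0
=CH-,CH,4310,13.5,200,0,0
=C<,C,4310,-5.5,70,0,0
phenyl,C6H5,31940,71.4,1430,110,0
phenylene,C6H4,31940,52.4,1270,110,0
ring5,,1050,16.0,190,0,0
ring6,,1050,16.0,190,0,0
O,O,3350,3.8,100,400,3000
OH,OH,29800,10.0,210,500,20000
OH_adj,OH,21850,13.0,210,500,20000
CO,CO,17370,10.8,290,770,2000
COO,CO2,18000,18.0,390,490,7000
COOH,CO2H,27630,28.5,530,420,10000
N,N,4190,-9.0,20,800,5000
=N-,N,11720,5.0,20,800,5000
NH,NH,8370,4.5,160,210,3100
NH2,NH2,12560,19.2,280,0,8400
CON<,CNO,20640,1.8,400,700,2980
F,F,4190,18.0,220,0,0
Cl,Cl,11550,24.0,450,550,400
S,S,14150,12.0,440,0,0
CF3,CF3,6700,49.5,550,450,0
SO2,SO2,20260,20.5,400,1500,9800
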