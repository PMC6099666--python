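property,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
hydrophobicity,1.8,2.5,-3.5,-3.5,2.8,-0.4,-3.2,4.5,-3.9,3.8,1.9,-3.5,-1.6,-3.5,-4.5,-0.8,-0.7,4.2,-0.9,-1.3
polarity,8.1,5.5,13.0,12.3,5.2,9.0,10.4,5.2,11.3,4.9,5.7,11.6,8.0,10.5,10.5,9.2,8.6,5.9,5.4,6.2
solvation free energy,0.67,0.38,-1.2,-0.76,2.3,0.0,0.64,1.9,-0.57,1.9,2.4,-0.6,1.2,-0.22,-2.1,0.01,0.52,1.5,2.6,1.6
graph shape index,1.28,1.77,1.6,1.56,2.94,0.0,2.99,4.19,1.89,2.59,2.35,1.6,2.67,1.56,2.34,1.31,3.03,3.67,3.21,2.94
transfer free energy,0.31,1.54,-0.77,-0.64,1.79,0.0,0.13,1.8,-0.99,1.7,1.23,-0.6,0.72,-0.22,-1.01,-0.04,0.26,1.22,2.25,0.96
correlation coefficient in regression analysis,0.96,0.42,0.42,0.53,0.59,0.0,0.57,0.84,0.73,0.92,0.86,0.39,0.68,0.8,0.77,0.53,0.54,0.63,0.58,0.72
residue accessible surface area,115.0,135.0,150.0,190.0,210.0,75.0,195.0,175.0,200.0,170.0,185.0,160.0,145.0,180.0,225.0,115.0,140.0,155.0,255.0,230.0
partition coefficient,0.3,1.2,-0.5,-0.7,2.0,0.0,0.15,1.8,-1.1,1.7,1.1,-0.45,0.75,-0.3,-1.4,-0.1,0.2,1.3,2.3,1.0
entropy of formulation,30.88,53.83,40.66,44.98,51.06,24.74,59.64,49.71,63.21,49.77,55.32,41.7,39.21,46.62,68.43,35.65,36.5,43.62,60.0,51.15
protein kinase A,2.34,1.96,1.88,2.19,1.83,2.34,1.82,2.36,2.18,2.36,2.28,2.02,1.99,2.17,2.17,2.21,2.09,2.32,2.83,2.2
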